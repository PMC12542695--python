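"""Synthetic communities and trees with planted ground truth.

Emulates the study design every downstream stage is tested against: 8
habitat samples spanning three growth stages (initial / plateau / last),
a generalist stratum spread near-evenly across all samples, a specialist
stratum confined to one focal sample (with optional 10% spillover into an
adjacent sample), lognormal abundance heterogeneity between OTUs, and
multinomial read sampling per sample.  Trees with binary tip states are
produced by forward (Gillespie) simulation of the BiSSE process.

All randomness flows through one seeded :class:`numpy.random.Generator`;
regenerating with the same seed is bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .bisse import BisseParams
from .otu import OtuTable
from .trees import StatePhylogeny

log = logging.getLogger(__name__)

__all__ = [
    "SyntheticScenario",
    "generate_community",
    "simulate_bisse_tree",
    "simulate_bisse_once",
    "generate_assembly_scenario",
    "DEFAULT_TRUE_BISSE",
]

STAGE_LABELS = ("initial", "plateau", "last")

# moderate, recoverable asymmetry: generalists (state 0) speciate twice as
# fast as specialists, equal extinction, symmetric transitions
DEFAULT_TRUE_BISSE = BisseParams(0.2, 0.1, 0.03, 0.03, 0.05, 0.05)


def _stage_labels(n_samples: int) -> list[str]:
    base, rem = divmod(n_samples, 3)
    sizes = [base + (1 if i >= 3 - rem else 0) for i in range(3)]
    labels = []
    for stage, size in zip(STAGE_LABELS, sizes):
        labels.extend([stage] * size)
    return labels


@dataclass
class SyntheticScenario:
    otu_table: OtuTable
    truth: dict[str, str]  # OTU -> planted class
    tree: StatePhylogeny | None
    true_bisse: BisseParams | None
    seed: int


def generate_community(
    n_generalists: int = 60,
    n_specialists: int = 60,
    n_intermediate: int = 30,
    n_samples: int = 8,
    reads_per_sample: int = 100_000,
    lognormal_sigma: float = 1.0,
    spillover_prob: float = 0.5,
    generalist_evenness: float = 150.0,
    trend_rate_range: tuple[float, float] = (1.2, 1.4),
    with_tree: bool = True,
    true_bisse: BisseParams = DEFAULT_TRUE_BISSE,
    seed: int = 0,
) -> SyntheticScenario:
    """Community with planted generalist / specialist / intermediate strata.

    Generalists receive near-even expected abundance across all samples
    (Dirichlet with concentration ``generalist_evenness`` per sample),
    modulated by a gentle monotone trend across the growth cycle — half
    rise, half decline at a per-sample rate drawn from
    ``trend_rate_range`` — emulating successional dynamics while keeping
    breadth far above the generalist threshold.  Specialists are confined
    to one focal sample, spilling 10% of their expected abundance into an
    adjacent sample with probability ``spillover_prob``; intermediates
    occupy three adjacent samples.  Every OTU carries a lognormal(0, σ)
    relative-mass multiplier, and each sample's reads are a multinomial
    draw from the sample's expected composition.
    """
    if min(n_generalists, n_specialists, n_intermediate) < 0:
        raise ValueError("stratum sizes must be non-negative")
    if n_samples < 2:
        raise ValueError("need at least two samples")
    rng = np.random.default_rng(seed)
    n_otus = n_generalists + n_specialists + n_intermediate
    if n_otus == 0:
        raise ValueError("no OTUs requested")
    otu_ids, truth = [], {}
    for k in range(n_generalists):
        otu_ids.append(f"GEN{k:04d}")
        truth[otu_ids[-1]] = "generalist"
    for k in range(n_specialists):
        otu_ids.append(f"SPC{k:04d}")
        truth[otu_ids[-1]] = "specialist"
    for k in range(n_intermediate):
        otu_ids.append(f"INT{k:04d}")
        truth[otu_ids[-1]] = "intermediate"

    mass = rng.lognormal(0.0, lognormal_sigma, size=n_otus)
    profiles = np.zeros((n_otus, n_samples))
    row = 0
    offsets = np.arange(n_samples) - (n_samples - 1) / 2.0
    for k in range(n_generalists):
        base = rng.dirichlet(np.full(n_samples, generalist_evenness))
        direction = 1.0 if k % 2 == 0 else -1.0
        rate = rng.uniform(*trend_rate_range)
        trend = rate ** (direction * offsets)
        weighted = base * trend
        profiles[row] = weighted / weighted.sum()
        row += 1
    for k in range(n_specialists):
        focal = k % n_samples
        if rng.uniform() < spillover_prob:
            adjacent = (focal + 1) % n_samples
            profiles[row, focal] = 1.0 / 1.1
            profiles[row, adjacent] = 0.1 / 1.1
        else:
            profiles[row, focal] = 1.0
        row += 1
    for k in range(n_intermediate):
        start = k % n_samples
        block = [(start + d) % n_samples for d in range(min(3, n_samples))]
        profiles[row, block] = rng.dirichlet(np.full(len(block), 8.0))
        row += 1

    expected = profiles * mass[:, None]
    counts = np.zeros((n_otus, n_samples), dtype=np.int64)
    for j in range(n_samples):
        col = expected[:, j]
        total = col.sum()
        if total == 0:
            raise ValueError(f"sample {j} has zero expected mass")
        counts[:, j] = rng.multinomial(reads_per_sample, col / total)
    if reads_per_sample < 5 * n_otus:
        log.warning(
            "reads_per_sample=%d is small for %d OTUs; rare taxa may vanish",
            reads_per_sample, n_otus,
        )
    unseen = int((counts.sum(axis=1) == 0).sum())
    if unseen:
        log.warning("%d planted OTUs received zero reads", unseen)

    sample_ids = [f"AP{j + 1}" for j in range(n_samples)]
    table = OtuTable(
        pd.DataFrame(counts, index=otu_ids, columns=sample_ids),
        pd.Series(_stage_labels(n_samples), index=sample_ids),
    )

    tree = None
    if with_tree:
        raw = simulate_bisse_tree(
            true_bisse, max_tips=n_otus, t_max=np.inf, root_state=0,
            seed=int(rng.integers(2**31)),
        )
        tree = _relabel_tree_to_otus(raw, truth, rng)
    return SyntheticScenario(
        otu_table=table, truth=truth, tree=tree,
        true_bisse=true_bisse if with_tree else None, seed=seed,
    )


def _relabel_tree_to_otus(
    raw: StatePhylogeny, truth: dict[str, str], rng: np.random.Generator
) -> StatePhylogeny:
    """Rename simulated tips to OTU ids, matching specialists to state-1
    tips (and everything else to state-0 tips) as far as the simulated
    state counts allow."""
    tips = raw.tip_labels
    states = raw.tip_states
    tips0 = [t for t in tips if states[t] == 0]
    tips1 = [t for t in tips if states[t] == 1]
    spec = [o for o, c in truth.items() if c == "specialist"]
    other = [o for o, c in truth.items() if c != "specialist"]
    rng.shuffle(spec)
    rng.shuffle(other)
    n_otus = len(spec) + len(other)
    if n_otus != len(tips):
        raise ValueError("tree tip count does not match OTU count")
    mapping: dict[str, str] = {}
    for tip, otu in zip(tips1, spec):
        mapping[tip] = otu
    for tip, otu in zip(tips0, other):
        mapping[tip] = otu
    leftover_tips = [t for t in tips if t not in mapping]
    leftover_otus = [o for o in spec + other if o not in set(mapping.values())]
    for tip, otu in zip(leftover_tips, leftover_otus):
        mapping[tip] = otu
    for leaf in raw.tree.leaf_node_iter():
        leaf.taxon.label = mapping[leaf.taxon.label]
    new_states = {mapping[t]: states[t] for t in tips}
    return StatePhylogeny(raw.tree, new_states)


# ---------------------------------------------------------------------------
# BiSSE forward simulation


def simulate_bisse_once(
    params: BisseParams,
    max_tips: int,
    t_max: float,
    root_state: int,
    rng: np.random.Generator,
) -> tuple[StatePhylogeny | None, int]:
    """One unconditioned forward (Gillespie) run from a single lineage.

    A lineage in state s speciates at λ_s, dies at μ_s and flips state at
    the corresponding q.  The run stops when ``max_tips`` lineages are
    alive or time ``t_max`` is reached.  Returns the reconstructed tree of
    extant tips (None if fewer than two survive) and the extant count —
    the raw count is exposed so birth–death expectations can be checked
    without survivorship bias.
    """
    lam = np.array([params.lambda0, params.lambda1])
    mu = np.array([params.mu0, params.mu1])
    q = np.array([params.q01, params.q10])

    tree = dendropy.Tree()
    root = tree.seed_node
    birth_time = {id(root): 0.0}
    alive: list[tuple[dendropy.Node, int]] = [(root, root_state)]
    t = 0.0
    extinct_labels: list[str] = []
    tip_states: dict[str, int] = {}
    counter = 0
    while alive and len(alive) < max_tips:
        states = np.array([s for _, s in alive])
        per = lam[states] + mu[states] + q[states]
        total = per.sum()
        if total <= 0:
            break
        dt = rng.exponential(1.0 / total)
        if t + dt >= t_max:
            t = t_max
            break
        t += dt
        k = rng.choice(len(alive), p=per / total)
        node, s = alive[k]
        u = rng.uniform() * per[k]
        if u < lam[s]:  # speciation
            node.edge.length = t - birth_time[id(node)]
            children = []
            for _ in range(2):
                child = dendropy.Node()
                node.add_child(child)
                birth_time[id(child)] = t
                children.append(child)
            alive.pop(k)
            alive.append((children[0], s))
            alive.append((children[1], s))
        elif u < lam[s] + mu[s]:  # extinction
            node.edge.length = t - birth_time[id(node)]
            counter += 1
            label = f"extinct{counter}"
            node.taxon = tree.taxon_namespace.new_taxon(label=label)
            extinct_labels.append(label)
            alive.pop(k)
        else:  # state flip
            alive[k] = (node, 1 - s)

    n_extant = len(alive)
    if n_extant < 2:
        return None, n_extant
    if t < t_max:
        # stopped by the tip cap: extend to just before the next event so
        # terminal branches are not truncated to zero length
        states = np.array([s for _, s in alive])
        total = (lam[states] + mu[states] + q[states]).sum()
        if total > 0:
            t = min(t + rng.exponential(1.0 / total), t_max)
    for i, (node, s) in enumerate(alive):
        node.edge.length = t - birth_time[id(node)]
        label = f"t{i + 1}"
        node.taxon = tree.taxon_namespace.new_taxon(label=label)
        tip_states[label] = int(s)
    if extinct_labels:
        tree.prune_taxa_with_labels(extinct_labels)
    # drop any residual root unifurcation left by pruning
    tree.suppress_unifurcations()
    seed = tree.seed_node
    if len(seed.child_nodes()) == 1:
        tree.seed_node = seed.child_nodes()[0]
        tree.seed_node.parent_node = None
    return StatePhylogeny(tree, tip_states), n_extant


def simulate_bisse_tree(
    params: BisseParams,
    max_tips: int,
    t_max: float = np.inf,
    root_state: int = 0,
    seed: int = 0,
    max_attempts: int = 1000,
) -> StatePhylogeny:
    """Forward-simulated BiSSE tree of extant tips, conditioned on survival
    (≥ 2 extant lineages) by rejection with an attempt cap."""
    if max_tips < 2:
        raise ValueError("max_tips must be at least 2")
    if not np.isfinite(t_max) and max_tips == np.inf:
        raise ValueError("either max_tips or t_max must be finite")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        phylo, _ = simulate_bisse_once(params, max_tips, t_max, root_state, rng)
        if phylo is not None:
            return phylo
    raise RuntimeError(
        f"whole clade went extinct in every one of {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# assembly scenarios


def generate_assembly_scenario(
    mode: str,
    n_samples: int = 8,
    n_otus: int = 100,
    reads_per_sample: int = 20_000,
    lognormal_sigma: float = 1.0,
    selection_noise: float = 0.25,
    seed: int = 0,
) -> OtuTable:
    """Communities assembled under a known regime, for stress-testing NST.

    ``stochastic``: every sample is an independent multinomial draw from
    one shared regional pool — assembly is pure drift, matching the NST
    null construction.  ``deterministic``: samples are forced toward one
    of two disjoint fixed compositions (alternating), with small lognormal
    jitter — strong selection toward two attractors.  All samples carry
    the single stage label "all" so the whole table forms one group.
    """
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    rng = np.random.default_rng(seed)
    counts = np.zeros((n_otus, n_samples), dtype=np.int64)
    if mode == "stochastic":
        pool = rng.lognormal(0.0, lognormal_sigma, size=n_otus)
        pool /= pool.sum()
        for j in range(n_samples):
            counts[:, j] = rng.multinomial(reads_per_sample, pool)
    elif mode == "deterministic":
        half = n_otus // 2
        targets = np.zeros((2, n_otus))
        targets[0, :half] = rng.lognormal(0.0, lognormal_sigma, size=half)
        targets[1, half:] = rng.lognormal(0.0, lognormal_sigma, size=n_otus - half)
        for j in range(n_samples):
            base = targets[j % 2].copy()
            jitter = rng.lognormal(0.0, selection_noise, size=n_otus)
            w = base * jitter
            counts[:, j] = rng.multinomial(reads_per_sample, w / w.sum())
    else:
        raise ValueError(f"unknown assembly mode {mode!r}")
    sample_ids = [f"S{j + 1}" for j in range(n_samples)]
    return OtuTable(
        pd.DataFrame(counts, index=[f"OTU{i:04d}" for i in range(n_otus)],
                     columns=sample_ids),
        pd.Series(["all"] * n_samples, index=sample_ids),
    )
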