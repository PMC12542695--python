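"""End-to-end orchestration: niche → diversity → MNTD → NST → network → BiSSE.

One YAML config drives a full analysis run.  Each stage writes
tab-separated artifacts plus a machine-readable JSON summary of its
headline statistics into its own subdirectory, so any stage can be rerun
or inspected in isolation.  The global seed fans out deterministically to
per-stage seeds (stage name hashed with the seed), so adding or removing
a stage never perturbs another stage's randomness.  Every threshold
actually applied is logged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as dv
from . import network as net
from . import niche
from .bisse import fit_ml, mcmc, summarize_rates
from .nst import nst
from .otu import OtuTable, read_otu_table, write_otu_table
from .phylo import ses_mntd_table
from .synthetic import generate_community
from .trees import StatePhylogeny, read_newick, read_tip_states, write_newick

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "load_config", "validate_config", "run_all"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "phyconiche_out"
    synthetic: dict | None = None
    inputs: dict | None = None
    niche: dict = field(default_factory=dict)
    diversity: dict = field(default_factory=dict)
    mntd: dict = field(default_factory=dict)
    nst: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    bisse: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def load_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(raw)


def validate_config(config: RunConfig) -> list[str]:
    """Cross-field checks; returns a list of violations (empty = valid)."""
    issues: list[str] = []
    if (config.synthetic is None) == (config.inputs is None):
        issues.append("exactly one of 'synthetic' or 'inputs' must be given")
    if config.inputs is not None:
        for key in ("otu_table", "metadata"):
            if key not in config.inputs:
                issues.append(f"inputs.{key}: required")
        for key, value in config.inputs.items():
            if key in ("otu_table", "metadata", "tree", "tip_states") and not Path(
                str(value)
            ).exists():
                issues.append(f"inputs.{key}: file not found: {value}")
    preset = config.niche.get("preset", "bacteria")
    if preset not in niche.PRESETS:
        issues.append(f"niche.preset: unknown preset {preset!r}")
    b_gen = config.niche.get("b_generalist", niche.PRESETS[preset].b_generalist
                             if preset in niche.PRESETS else 4.0)
    b_spec = config.niche.get("b_specialist", 1.5)
    if b_spec >= b_gen:
        issues.append("niche.b_specialist: must be below niche.b_generalist")
    n_perm = config.diversity.get("n_perm", 999)
    if n_perm < 99:
        issues.append("diversity.n_perm: must be at least 99")
    props_max = config.network.get("attack_proportions_max", 0.8)
    if not 0 < props_max < 1:
        issues.append("network.attack_proportions_max: must lie in (0, 1)")
    return issues


def _stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest, 16) % (2**31)


def _write_summary(stage_dir: Path, summary: dict) -> None:
    with open(stage_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)


def run_all(config: RunConfig, outdir=None) -> dict:
    """Execute all stages in dependency order; returns the merged summary.

    A stage failure raises :class:`StageError` naming the stage; outputs
    from completed stages are left in place.
    """
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    # -- data -------------------------------------------------------------
    stage = "data"
    try:
        tree: StatePhylogeny | None = None
        if config.synthetic is not None:
            scenario = generate_community(
                seed=_stage_seed(config.seed, "synthetic"), **config.synthetic
            )
            table, tree = scenario.otu_table, scenario.tree
            sdir = out / stage
            sdir.mkdir(exist_ok=True)
            write_otu_table(table, sdir / "otu_table.tsv", sdir / "metadata.tsv")
            pd.Series(scenario.truth, name="planted_class").rename_axis(
                "otu_id"
            ).to_csv(sdir / "truth.tsv", sep="\t")
            if tree is not None:
                write_newick(tree, sdir / "tree.nwk", sdir / "tip_states.tsv")
        else:
            table = read_otu_table(
                config.inputs["otu_table"], config.inputs["metadata"]
            )
            if "tree" in config.inputs:
                states = (
                    read_tip_states(config.inputs["tip_states"])
                    if "tip_states" in config.inputs
                    else None
                )
                tree = read_newick(config.inputs["tree"], tip_states=states)
        report["data"] = {
            "n_otus": table.n_otus,
            "n_samples": table.n_samples,
            "has_tree": tree is not None,
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- niche ------------------------------------------------------------
    stage = "niche"
    try:
        preset = config.niche.get("preset", "bacteria")
        base = niche.PRESETS[preset]
        thresholds = niche.NicheThresholds(
            b_generalist=config.niche.get("b_generalist", base.b_generalist),
            b_specialist=config.niche.get("b_specialist", base.b_specialist),
            min_occurrence=config.niche.get("min_occurrence", base.min_occurrence),
            min_mean_abund=config.niche.get("min_mean_abund", base.min_mean_abund),
        )
        log.info("niche thresholds applied: %s", thresholds)
        table = niche.preprocess(table)
        profiles = niche.classify(table, thresholds, preprocessed=True)
        sdir = out / stage
        sdir.mkdir(exist_ok=True)
        profiles.to_csv(sdir / "niche_profiles.tsv", sep="\t")
        class_counts = profiles["niche_class"].value_counts().to_dict()
        _write_summary(sdir, {"thresholds": thresholds.__dict__, **class_counts})
        report["niche"] = class_counts
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- diversity --------------------------------------------------------
    stage = "diversity"
    try:
        sdir = out / stage
        sdir.mkdir(exist_ok=True)
        alpha = dv.alpha_diversity_table(table)
        alpha.to_csv(sdir / "alpha_diversity.tsv", sep="\t")
        metric = config.diversity.get("metric", "ruzicka")
        dist = dv.beta_diversity(table, metric=metric)
        pd.DataFrame(dist.data, index=dist.ids, columns=dist.ids).to_csv(
            sdir / "beta_distances.tsv", sep="\t"
        )
        ordination = dv.pcoa(dist)
        ordination.samples.iloc[:, :4].to_csv(sdir / "pcoa_coordinates.tsv", sep="\t")
        summary = {
            "metric": metric,
            "shannon_mean": float(alpha["shannon"].mean()),
            "chao1_mean": float(alpha["chao1"].mean()),
            "pcoa_prop_explained_1": float(ordination.proportion_explained.iloc[0]),
        }
        if all(len(v) >= 2 for v in table.stage_groups().values()) and len(
            table.stage_groups()
        ) >= 2:
            res = dv.anosim(
                dist,
                table.stages.to_dict(),
                n_perm=config.diversity.get("n_perm", 999),
                seed=_stage_seed(config.seed, "anosim"),
            )
            summary["anosim_r"] = res.r
            summary["anosim_p"] = res.p_value
        _write_summary(sdir, summary)
        report["diversity"] = summary
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- mntd -------------------------------------------------------------
    stage = "mntd"
    if tree is None:
        log.info("no tree in config: skipping MNTD stage")
    else:
        try:
            sdir = out / stage
            sdir.mkdir(exist_ok=True)
            mdf = ses_mntd_table(
                table,
                tree,
                n_null=config.mntd.get("n_null", 999),
                seed=_stage_seed(config.seed, "mntd"),
            )
            mdf.to_csv(sdir / "ses_mntd.tsv", sep="\t", index=False)
            summary = {
                "mean_ses": float(mdf["ses"].mean()) if len(mdf) else float("nan"),
                "n_samples": int(len(mdf)),
            }
            _write_summary(sdir, summary)
            report["mntd"] = summary
        except Exception as exc:
            raise StageError(stage, exc) from exc

    # -- nst --------------------------------------------------------------
    stage = "nst"
    try:
        sdir = out / stage
        sdir.mkdir(exist_ok=True)
        groups = {s: "all" for s in table.sample_ids}
        results = nst(
            table,
            groups=groups,
            n_null=config.nst.get("n_null", 1000),
            seed=_stage_seed(config.seed, "nst"),
        )
        all_pairs = pd.concat(
            [r.pairs.assign(group=g) for g, r in results.items()], ignore_index=True
        )
        all_pairs.to_csv(sdir / "nst_pairs.tsv", sep="\t", index=False)
        summary = {
            g: {"group_mean_nst": r.group_mean_nst, "regime": r.regime}
            for g, r in results.items()
        }
        _write_summary(sdir, summary)
        report["nst"] = summary
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- network ----------------------------------------------------------
    stage = "network"
    try:
        sdir = out / stage
        sdir.mkdir(exist_ok=True)
        r_min = config.network.get("r_min", 0.6)
        alpha_level = config.network.get("alpha", 0.05)
        log.info("network thresholds applied: |rho| > %s, BH p < %s", r_min, alpha_level)
        rel = table.relative_abundance()
        attrs = profiles[["niche_class"]]
        graph = net.spearman_edges(rel, r_min=r_min, alpha=alpha_level, node_attrs=attrs)
        net.write_network(graph, sdir / "edges.tsv", fmt="edgelist")
        summary = {"whole": net.topology(graph)}
        for cls in ("generalist", "specialist"):
            sub = net.induced_subgraph(graph, niche_class=cls)
            summary[cls] = net.topology(sub)
            if sub.number_of_nodes() >= 5:
                pmax = config.network.get("attack_proportions_max", 0.8)
                curve = net.attack_robustness(
                    sub,
                    proportions=np.arange(0.0, pmax + 1e-9, 0.05),
                    n_reps=config.network.get("attack_reps", 50),
                    seed=_stage_seed(config.seed, f"attack:{cls}"),
                )
                curve.as_frame().to_csv(
                    sdir / f"robustness_{cls}.tsv", sep="\t", index=False
                )
                summary[cls]["attack_slope"] = curve.fit.slope
                summary[cls]["attack_r_squared"] = curve.fit.r_squared
        _write_summary(sdir, summary)
        report["network"] = summary
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- bisse ------------------------------------------------------------
    stage = "bisse"
    if tree is None or not config.bisse.get("enabled", True):
        log.info("no tree in config or stage disabled: skipping BiSSE stage")
    else:
        try:
            sdir = out / stage
            sdir.mkdir(exist_ok=True)
            phylo = tree
            if phylo.tip_states is None:
                states = {
                    o: 0 if c == "generalist" else 1
                    for o, c in profiles["niche_class"].items()
                    if c in ("generalist", "specialist")
                }
                keep = [t for t in phylo.tip_labels if t in states]
                pruned = phylo.tree.clone(depth=1)
                pruned.retain_taxa_with_labels(keep)
                phylo = StatePhylogeny(pruned, {t: states[t] for t in keep})
            fit = fit_ml(phylo)
            rates = summarize_rates(fit)
            rates.to_csv(sdir / "rates.tsv", sep="\t")
            n_iter = config.bisse.get("mcmc_iterations", 0)
            summary = {
                "loglik": fit.loglik,
                "converged": fit.converged,
                "rates": rates.to_dict(orient="index"),
            }
            if n_iter:
                trace = mcmc(
                    phylo,
                    n_iter=n_iter,
                    seed=_stage_seed(config.seed, "bisse-mcmc"),
                    start=fit.ml_params,
                )
                trace.to_csv(sdir / "mcmc_trace.tsv", sep="\t", index=False)
                burn = trace.iloc[n_iter // 2:]
                summary["posterior_means"] = (
                    burn.drop(columns="log_posterior").mean().to_dict()
                )
            _write_summary(sdir, summary)
            report["bisse"] = summary
        except Exception as exc:
            raise StageError(stage, exc) from exc

    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
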