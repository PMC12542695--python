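"""Levins niche breadth and generalist/specialist classification.

For OTU j observed across N habitats (samples), the habitat profile
P_·j is the vector of within-sample relative abundances renormalised so
Σ_i P_ij = 1, and the Levins breadth is

    B_j = 1 / Σ_i P_ij²

B ranges from 1 (single habitat) to N (perfectly even habitat use).  OTUs
are classified as generalists when B exceeds a domain threshold (4 for
bacteria, 2.5 for fungi) *and* they occur in at least ``min_occurrence``
samples; as specialists when B < 1.5; otherwise intermediate.  OTUs whose
mean relative abundance falls below 2 × 10⁻⁵ are excluded ("filtered")
before classification so vanishingly rare taxa are not misread as
specialists, and OTUs with fewer than two reads in total are dropped as
likely sequencing errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .otu import OtuTable, OtuTableError

log = logging.getLogger(__name__)

__all__ = [
    "NicheThresholds",
    "PRESETS",
    "preprocess",
    "habitat_profile",
    "levins_breadth",
    "niche_profiles",
    "classify",
]

GENERALIST = "generalist"
SPECIALIST = "specialist"
INTERMEDIATE = "intermediate"
FILTERED = "filtered"


@dataclass(frozen=True)
class NicheThresholds:
    """Classification thresholds.

    b_generalist
        Minimum breadth (exclusive) for generalists.
    b_specialist
        Maximum breadth (exclusive) for specialists; must be < b_generalist.
    min_occurrence
        Minimum number of samples with non-zero counts for a generalist
        (">4 samples" read strictly: occurrence ≥ 5 of N = 8).
    min_mean_abund
        Mean within-sample relative abundance below which an OTU is
        excluded from classification entirely.
    """

    b_generalist: float = 4.0
    b_specialist: float = 1.5
    min_occurrence: int = 5
    min_mean_abund: float = 2e-5

    def __post_init__(self) -> None:
        if self.b_generalist <= 0 or self.b_specialist <= 0:
            raise ValueError("breadth thresholds must be positive")
        if self.b_specialist >= self.b_generalist:
            raise ValueError("b_specialist must be below b_generalist")


PRESETS = {
    "bacteria": NicheThresholds(b_generalist=4.0),
    "fungi": NicheThresholds(b_generalist=2.5),
}


def preprocess(table: OtuTable, min_total_reads: int = 2) -> OtuTable:
    """Drop OTUs with fewer than ``min_total_reads`` reads in total.

    Reads appearing once across the whole experiment are treated as probable
    sequencing errors; an OTU with exactly two reads is retained.
    """
    totals = table.counts.sum(axis=1)
    keep = totals[totals >= min_total_reads].index
    if len(keep) == 0:
        raise OtuTableError("no OTUs left after the minimum-read filter")
    dropped = table.n_otus - len(keep)
    if dropped:
        log.info("preprocess: dropped %d OTUs with < %d reads", dropped, min_total_reads)
    return OtuTable(table.counts.loc[keep].copy(), table.stages.copy())


def habitat_profile(table: OtuTable, otu_id: str) -> np.ndarray:
    """Across-habitat profile of one OTU: within-sample relative abundances
    renormalised to sum to one across the N samples."""
    if otu_id not in table.counts.index:
        raise KeyError(f"unknown OTU {otu_id!r}")
    rel = table.relative_abundance().loc[otu_id].to_numpy(dtype=float)
    total = rel.sum()
    if total == 0:
        raise ValueError(f"OTU {otu_id!r} is absent from every sample")
    return rel / total


def levins_breadth(p: np.ndarray) -> float:
    """Levins breadth B = 1/Σp² of a habitat profile summing to one."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("habitat profile has negative entries")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"habitat profile must sum to 1, got {p.sum()!r}")
    return 1.0 / float(np.sum(p**2))


def niche_profiles(table: OtuTable) -> pd.DataFrame:
    """Per-OTU breadth, occurrence and mean relative abundance (no classes).

    Vectorised over the whole table; breadth is computed from habitat
    profiles so it is invariant to per-sample sequencing depth.
    """
    rel = table.relative_abundance()
    row_sums = rel.sum(axis=1)
    present = row_sums > 0
    profiles = rel.div(row_sums.where(present), axis=0)
    b = 1.0 / (profiles**2).sum(axis=1)
    b[~present] = np.nan
    occurrence = (table.counts > 0).sum(axis=1)
    return pd.DataFrame(
        {
            "otu_id": table.otu_ids,
            "B": b.to_numpy(),
            "occurrence": occurrence.to_numpy(),
            "mean_rel_abund": rel.mean(axis=1).to_numpy(),
        }
    ).set_index("otu_id")


def classify(
    table: OtuTable,
    thresholds: NicheThresholds | str = "bacteria",
    preprocessed: bool = False,
) -> pd.DataFrame:
    """Classify every OTU as generalist / specialist / intermediate / filtered.

    Returns a DataFrame indexed by OTU id with columns
    ``B, occurrence, mean_rel_abund, niche_class``.  Classes are mutually
    exclusive and exhaustive; classification is idempotent and independent
    of OTU order.
    """
    if isinstance(thresholds, str):
        thresholds = PRESETS[thresholds]
    if not preprocessed:
        table = preprocess(table)
    prof = niche_profiles(table)
    classes = pd.Series(INTERMEDIATE, index=prof.index, dtype=object)
    is_gen = (prof["B"] > thresholds.b_generalist) & (
        prof["occurrence"] >= thresholds.min_occurrence
    )
    is_spec = prof["B"] < thresholds.b_specialist
    classes[is_spec] = SPECIALIST
    classes[is_gen] = GENERALIST
    classes[prof["mean_rel_abund"] < thresholds.min_mean_abund] = FILTERED
    prof["niche_class"] = classes
    return prof
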