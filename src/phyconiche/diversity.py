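"""Alpha/beta diversity, ordination and group-comparison statistics.

Alpha diversity: Shannon H, Chao1 richness, Good's coverage, and
rarefaction curves by repeated subsampling without replacement.

Beta diversity: the quantitative Jaccard-type dissimilarity
1 − Σmin(x,y)/Σmax(x,y), known as the Ružička (or "abund-jaccard")
metric, plus Bray–Curtis; classical PCoA (via scikit-bio); rank-based
ANOSIM with a seeded permutation test; a Mantel-style correlation between
two distance matrices; one-way ANOVA with protected LSD pairwise tests;
and ordinary least-squares fits for diversity–diversity correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .otu import OtuTable

__all__ = [
    "shannon",
    "chao1",
    "goods_coverage",
    "rarefaction_curve",
    "ruzicka",
    "abund_jaccard",
    "bray_curtis",
    "beta_diversity",
    "pcoa",
    "anosim",
    "AnosimResult",
    "anova_lsd",
    "AnovaLsdResult",
    "linear_fit",
    "LinearFit",
    "structure_correlation",
    "alpha_diversity_table",
]


# ---------------------------------------------------------------------------
# alpha diversity


def _clean_counts(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if x.sum() == 0:
        raise ValueError("counts sum to zero")
    return x


def shannon(counts, base: float = np.e) -> float:
    """Shannon diversity H = −Σ p log p over non-zero proportions."""
    x = _clean_counts(counts)
    p = x[x > 0] / x.sum()
    return float(-(p * np.log(p)).sum() / np.log(base))


def _require_integer(counts) -> np.ndarray:
    x = np.asarray(counts)
    if not np.allclose(x, np.round(x), rtol=0, atol=0):
        raise ValueError("integer counts required")
    return np.asarray(np.round(x), dtype=np.int64)


def chao1(counts) -> float:
    """Chao1 richness: S_obs + F1²/(2 F2), bias-corrected when F2 = 0."""
    x = _require_integer(counts)
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def goods_coverage(counts) -> float:
    """Good's coverage 1 − F1/N: the chance a new read hits a seen OTU."""
    x = _require_integer(counts)
    n = int(x.sum())
    if n == 0:
        raise ValueError("zero reads")
    f1 = int((x == 1).sum())
    return 1.0 - f1 / n


_METRICS = {
    "shannon": shannon,
    "richness": lambda c: float((np.asarray(c) > 0).sum()),
    "chao1": chao1,
}


def rarefaction_curve(counts, depths, n_reps: int = 10, metric="shannon", seed=None):
    """Mean alpha-diversity metric at each subsampling depth.

    Subsamples reads without replacement (multivariate hypergeometric),
    ``n_reps`` times per depth.  Returns a Series indexed by depth.
    """
    x = _require_integer(counts)
    total = int(x.sum())
    fn = _METRICS[metric] if isinstance(metric, str) else metric
    rng = np.random.default_rng(seed)
    out = {}
    for depth in depths:
        depth = int(depth)
        if depth > total:
            raise ValueError(f"depth {depth} exceeds total reads {total}")
        vals = [
            fn(rng.multivariate_hypergeometric(x, depth)) for _ in range(n_reps)
        ]
        out[depth] = float(np.mean(vals))
    return pd.Series(out, name=metric if isinstance(metric, str) else "metric")


def alpha_diversity_table(table: OtuTable, base: float = np.e) -> pd.DataFrame:
    """Per-sample Shannon, Chao1 and Good's coverage with stage labels."""
    rows = {}
    for s in table.sample_ids:
        c = table.counts[s].to_numpy()
        rows[s] = {
            "shannon": shannon(c, base=base),
            "chao1": chao1(c),
            "goods_coverage": goods_coverage(c),
            "stage": table.stages[s],
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# beta diversity


def ruzicka(x, y) -> float:
    """Quantitative Jaccard dissimilarity 1 − Σmin/Σmax (Ružička)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = np.maximum(x, y).sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return 1.0 - float(np.minimum(x, y).sum() / denom)


abund_jaccard = ruzicka  # the two names denote the same formula


def bray_curtis(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(x - y).sum() / denom)


_BETA = {"ruzicka": ruzicka, "abund_jaccard": ruzicka, "braycurtis": bray_curtis}


def beta_diversity(table: OtuTable, metric="ruzicka") -> DistanceMatrix:
    """Pairwise sample dissimilarity matrix for the chosen metric."""
    fn = _BETA[metric] if isinstance(metric, str) else metric
    ids = table.sample_ids
    n = len(ids)
    mat = np.zeros((n, n))
    cols = table.counts.to_numpy().T
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = fn(cols[i], cols[j])
    return DistanceMatrix(mat, ids)


def pcoa(dist: DistanceMatrix):
    """Classical (metric) multidimensional scaling of a distance matrix.

    Coordinates are built from positive eigenvalues only; negative
    eigenvalues are retained in the result for inspection (no correction).
    """
    return _skbio_pcoa(dist, method="eigh", number_of_dimensions=0)


# ---------------------------------------------------------------------------
# group statistics


@dataclass
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = ranks.size
    return float((ranks[~within].mean() - ranks[within].mean()) / (m / 2.0))


def anosim(dist: DistanceMatrix, groups, n_perm: int = 999, seed=None) -> AnosimResult:
    """Rank-based analysis of similarities.

    R = (mean between-group rank − mean within-group rank) / (M/2) with
    M = n(n−1)/2; the p-value is the one-sided permutation tail
    (1 + #{R_perm ≥ R_obs}) / (n_perm + 1).
    """
    ids = list(dist.ids)
    if isinstance(groups, (dict, pd.Series)):
        labels = np.asarray([groups[s] for s in ids])
    else:
        labels = np.asarray(list(groups))
        if labels.size != len(ids):
            raise ValueError("groups must align with the distance matrix samples")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    if (counts < 2).any():
        raise ValueError(f"singleton group(s): {uniq[counts < 2].tolist()}")
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    d = dist.data[iu]
    ranks = sps.rankdata(d)
    within = labels[iu[0]] == labels[iu[1]]
    r_obs = _anosim_r(ranks, within)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        w = perm[iu[0]] == perm[iu[1]]
        if _anosim_r(ranks, w) >= r_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return AnosimResult(r=r_obs, p_value=p, n_permutations=n_perm)


@dataclass
class AnovaLsdResult:
    f: float
    p_value: float
    ms_error: float
    df_error: int
    pairwise: pd.DataFrame  # group_a, group_b, diff, t, p, significant


def anova_lsd(values, groups, alpha: float = 0.05) -> AnovaLsdResult:
    """One-way ANOVA followed by protected LSD pairwise comparisons.

    Pairwise t-tests use the pooled mean-square error; they are only
    declared significant when the omnibus F test is itself significant at
    ``alpha`` (Fisher's protected LSD).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in uniq]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs at least two observations")
    n = len(values)
    k = len(uniq)
    grand = values.mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b, df_w = k - 1, n - k
    if ss_within == 0:
        raise ValueError("zero within-group variance: ANOVA degenerate")
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    f = ms_b / ms_w
    p = float(sps.f.sf(f, df_b, df_w))
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = samples[i], samples[j]
            diff = a.mean() - b.mean()
            se = np.sqrt(ms_w * (1 / len(a) + 1 / len(b)))
            t = diff / se
            p_ij = float(2 * sps.t.sf(abs(t), df_w))
            rows.append(
                {
                    "group_a": uniq[i],
                    "group_b": uniq[j],
                    "diff": diff,
                    "t": t,
                    "p": p_ij,
                    "significant": bool(p < alpha and p_ij < alpha),
                }
            )
    return AnovaLsdResult(
        f=float(f), p_value=p, ms_error=float(ms_w), df_error=df_w,
        pairwise=pd.DataFrame(rows),
    )


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float


def linear_fit(x, y) -> LinearFit:
    """Ordinary least squares y ~ x with a t-test on the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    res = sps.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
    )


def structure_correlation(
    dist_sub: DistanceMatrix, dist_whole: DistanceMatrix, n_perm: int = 999, seed=None
) -> tuple[float, float]:
    """Mantel-style correlation between two distance matrices.

    Pearson r of the vectorised off-diagonal dissimilarities; the p-value
    permutes sample labels (rows and columns jointly) of the first matrix,
    two-sided on |r|.
    """
    if list(dist_sub.ids) != list(dist_whole.ids):
        raise ValueError("distance matrices cover different samples")
    n = len(dist_sub.ids)
    iu = np.triu_indices(n, k=1)
    a = dist_sub.data
    b_vec = dist_whole.data[iu]
    r_obs = float(np.corrcoef(a[iu], b_vec)[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = np.corrcoef(a[np.ix_(perm, perm)][iu], b_vec)[0, 1]
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return r_obs, p
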