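# Methods

This note records the models, numerical choices and design decisions
behind each module, and what the synthetic-data tests do and do not
establish about real data.

## Data model

An `OtuTable` is an integer OTU × sample count matrix with a mandatory
sample → growth-stage map.  The study design it mirrors has eight samples
(AP1–AP8) in three stages (initial: 2, plateau: 3, last: 3); one
community per time point is assumed (replicate flasks pooled).  Parsing
is strict: negative or fractional cells, duplicate identifiers, or
samples without a stage are errors, and a table that looks transposed
(metadata samples found in rows) is rejected unless `transpose=True` —
silent transposition being the classic microbiome bug.  Trees are plain
Newick with mandatory non-negative branch lengths (zero lengths allowed
but logged) wrapped in `StatePhylogeny` with an optional tip → {0,1}
state map; the convention throughout is state 0 = generalist,
1 = specialist.

## Niche classification

The habitat profile of an OTU is its vector of within-sample relative
abundances renormalised to sum to one across habitats.  This
normalisation (rather than raw relative abundances) is what lets the
Levins breadth B = 1/Σp² attain its full range [1, N]; it also makes B
invariant to per-sample sequencing depth.  Thresholds (defaults):

| parameter | default | meaning |
|---|---|---|
| `b_generalist` | 4.0 (bacteria) / 2.5 (fungi) | B above which an OTU can be a generalist |
| `min_occurrence` | 5 | "more than four of N = 8 samples", read strictly |
| `b_specialist` | 1.5 | B below which an OTU is a specialist |
| `min_mean_abund` | 2 × 10⁻⁵ | mean relative abundance below which an OTU is excluded |
| `min_total_reads` | 2 | OTUs with fewer total reads are dropped as likely errors |

The abundance filter is applied globally before classification (not only
to specialist candidates); this is configurable.  The specialist rule
uses B alone — the observation that specialists sit in one or two samples
is treated as descriptive, not as a rule.  Occurrence is counted on
non-zero cells of the filtered count table.

## Diversity and ordination

Shannon uses natural log by default (base-2 via argument); Chao1 uses the
classic S + F₁²/(2F₂) with the bias-corrected form when F₂ = 0.
"Ružička" and "abundance-based Jaccard" are one formula,
1 − Σmin/Σmax, implemented once under two names.  PCoA is classical
scaling through scikit-bio; negative eigenvalues are reported but not
corrected (no Cailliez), and coordinates come from positive eigenvalues
only.  ANOSIM is implemented in-package (R from rank dissimilarities,
one-sided permutation p with an explicit seed; scikit-bio's R statistic
is an exact cross-check in the tests but does not expose seeded
permutations).  The LSD pairwise tests use the pooled mean-square error
and are protected: declared significant only when the omnibus F is.  The
Mantel-style structure correlation is Pearson on the vectorised
off-diagonals with joint row/column label permutation, two-sided on |r|.

## NST

The null model is proportional–fixed (PF): each null community keeps the
observed richness and read depth of its sample exactly; taxa are drawn
without replacement with probability proportional to regional occurrence
frequency, and reads are allocated one-per-drawn-taxon plus a multinomial
remainder proportional to regional relative abundance.  Per pair, with
Ē the null mean dissimilarity:

    ST  = D/Ē          if D ≤ Ē, else Ē/D
    NST = D/Ē          if D ≤ Ē   (convergent side)
    NST = (1−D)/(1−Ē)  otherwise  (divergent side, using D_max = 1)

clipped to [0, 1].  Fully null-assembled data scores near 1; selection in
either direction (convergence or divergence relative to the null) pushes
NST toward 0, and the conventional 0.5 threshold separates
stochasticity- from determinism-dominated assembly.  The exact
normalisation used by published NST software is not restated in the
methods literature this package follows, so no numeric equality with any
external implementation is claimed: the module's guarantees are range,
seed-stability, null-count stability (200 → 1000 nulls moves a group mean
by < 0.05 on fixtures) and directionality on scenarios with known
assembly regimes.  Results are canonicalised over OTU and sample order so
the seeded null does not depend on storage order.

## ses-MNTD

MNTD is presence/absence by default (abundance weighting behind a flag):
the mean over present taxa of the patristic distance to the nearest other
present taxon.  The null shuffles tip labels over the entire tree —
equivalently, draws uniform random tip subsets of the observed richness —
with 999 draws by default;
ses = (obs − mean)/sd and the two-sided rank p is
min(rank, n+1−rank)·2/(n+1).  A degenerate null (sd = 0) yields NaN with
a log flag rather than an exception.

## Co-occurrence networks

Edges require |ρ| > 0.6 AND BH-adjusted p < 0.05.  The absolute-value
reading of the correlation threshold is deliberate (negative
interactions are reported in this literature even when the threshold is
written r > 0.6); a signed mode is available.  With n ≤ 9 samples the
p-value is exact: the permutation distribution of ρ is enumerated over
all n! orderings (a cached universal distribution when both rank vectors
are tie-free; per-pair enumeration otherwise).  The t-approximation at
n = 8 concentrates spurious mass in the tails and distorts BH, which is
why the exact route is the default and is logged.  Isolated nodes are
excluded from the built network by default (`keep_isolated` retains
them).  "Complexity" is linkage density E/N; average degree 2E/N is
reported alongside.  Modules come from deterministic greedy modularity
maximisation on |ρ| weights with sorted-node tie-breaking.  Natural
connectivity is computed on the unweighted adjacency spectrum as
logsumexp(λ) − ln N; the attack simulation removes the given fraction of
nodes uniformly without replacement per replicate, keeps isolated
survivors in the remnant count, and summarises mean λ̄ versus removal
fraction with an OLS slope.  Slope comparison between two curves uses a
pooled regression with a group × proportion interaction.

A measured caveat: under random attack, a denser random graph shows a
*steeper* absolute (and intact-normalised) λ̄ slope than a sparse graph of
equal size, simply because λ̄ scales with density; what distinguishes the
denser graph is dominance — higher remnant connectivity at every removal
fraction — and that is the property the tests assert.

## BiSSE engine

Likelihood: the standard coupled ODEs for extinction probabilities
E₀, E₁ and data probabilities D₀, D₁ are integrated tipward-to-rootward
along each branch with an adaptive Dormand–Prince RK5(4) scheme
(rtol 1e-9, atol 1e-12 by default — tight enough that the likelihood
matches an independent factorisation oracle to ~1e-9 on 100-tip trees);
daughters combine at nodes as D = λ·D_L·D_R, D is renormalised after
every branch and node with the log-normalisation accumulated, and E is
range-checked ([0,1] within 1e-8, else an error).  E values of sister
lineages are averaged at nodes (they agree on ultrametric trees; on
non-ultrametric inputs this is the usual pragmatic choice).  The root is
resolved, by default, by weighting the two root states by their relative
D (observed-weighting); flat and fixed-state modes are available, and
conditioning on survival (division by the weighted λ(1−E)²) is off by
default.  The core is numba-compiled; one log-likelihood on a 300-tip
tree costs ~1 ms, which is what makes simulation-based calibration of
the fitter affordable.

Fitting: step 1 fits the constrained model (λ₀ = λ₁, μ₀ = μ₁) from a
heuristic birth–death start (net diversification r ≈ ln(n/2)/depth split
as λ = 2r, μ = r, q = r/10); step 2 frees all six rates from the
constrained optimum.  Optimisation is Nelder–Mead on log-rates, which
enforces positivity without explicit bounds and avoids finite-difference
noise near the boundary; since the models are nested the free optimum is
floored at the constrained one.  MCMC is an adaptive random-walk on
log-rates (joint Gaussian proposals, scale adapted toward ~30% acceptance
over the first half of the chain) under independent exponential priors
with mean 2 × the heuristic net-diversification estimate; 200 consecutive
rejections abort with an adaptation-failure error.  "Iterations" is the
reading adopted for the MCMC replicate counts (1,000 / 5,000) quoted in
this literature.

Rates are in events per lineage per unit branch length, so absolute
values are only comparable across trees on the same time scale; analyses
on molecular-distance trees yield rates in per-substitution units.

## Synthetic data

The generator is the test harness's ground truth and emulates the study
conditions: 8 samples in stages 2/3/3, multinomial read sampling at
100,000 reads per sample (the study's per-sample depth is ≈ 77k–80k),
lognormal(0, σ = 1) abundance heterogeneity across OTUs, a generalist
stratum with near-even Dirichlet(150) profiles modulated by a gentle
monotone successional trend (per-sample rate 1.2–1.4, half rising, half
declining — keeping B ≈ 5–7, far above the threshold, while planting the
monotone co-occurrences a correlation network needs at n = 8), a
specialist stratum confined to one focal sample with 10% spillover into
an adjacent sample (probability 0.5), and an intermediate stratum over
three adjacent samples.  Default strata: 60 generalists, 60 specialists,
30 intermediates.

Trees are simulated forward (Gillespie) under true BiSSE rates — default
λ₀ = 0.2, λ₁ = 0.1, μ = 0.03, q = 0.05 both ways, a moderate and
recoverable asymmetry — conditioned on ≥ 2 survivors by rejection (1,000
attempts cap); a run stopped by the tip cap is extended to just before
the next event so terminal branches are not truncated to zero.  Assembly
scenarios: "stochastic" draws every sample from one shared regional pool
(drift only — by construction the NST null); "deterministic" forces
samples toward two disjoint attractor compositions with lognormal(0.25)
jitter.

What passing tests show — and do not.  The generator plants clean,
separable strata; real communities have continuous breadth spectra,
compositional coupling from fixed sequencing depth, PCR/primer biases and
chimeras (explicitly out of scope), and trees inferred from marker genes
rather than known genealogies.  Recovery of planted truth therefore
validates the machinery (thresholds applied as specified, estimators
consistent under their own model), not classification accuracy on field
data.  Likewise the scenario tree's tip states come from the simulated
BiSSE process (specialist OTU ids are matched to state-1 tips as far as
counts allow), so niche truth and tree states are coherent but not
identical by construction.

## Problem sizes used in the test-suite calibrations

Directional NST checks use 10 seeds per regime at 8 samples × 80 OTUs
with 200 nulls; the likelihood-factorisation check uses 50 trees of
20–100 tips at 1e-6 agreement; rate-ordering recovery uses 100 trees of
300 tips; ses-MNTD self-consistency uses 100 random 12-taxon samples on a
64-tip tree with 199 nulls each; the exact-Spearman brute force
enumerates all 8! orders for 20 pairs.  These sizes give comfortable
Monte-Carlo margins for the asserted tolerances while keeping the whole
suite in the minutes range.

## Known limitations

- NST normalisation is one defensible member of a family; only
  directional and range behaviour is guaranteed.
- The BiSSE engine assumes complete extant sampling (no sampling
  fraction), binary states, and a strictly bifurcating rooted tree;
  MuSSE/HiSSE-style extensions are out of scope.
- ANOSIM/PCoA/ANOVA are the classical procedures; no compositional
  corrections (e.g. SparCC-style) are applied to correlations.
- With eight samples the exact Spearman p-value floor is 2/8! ≈ 5e-5, so
  after BH correction across many thousands of pairs only perfectly (or
  near-perfectly) monotone tie-free pairs can form edges; this is a
  property of the design, not of the implementation.
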