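# Methods

## Model and procedure

The method treats a gene as a candidate *source* of dysregulation when two
independent signatures coincide: strong correlation with its network
neighborhood, and differential expression that is concentrated around it and
fades with network distance. Both are assessed at every geodesic radius
`r = 1..D` (D = diameter of the network's largest connected component, LCC)
and combined per radius.

**Network.** The analysis graph is the union of pathway edge sets — any link
present in at least one pathway is an edge — reduced to its LCC. Edges are
undirected and untyped; this ignores interaction direction and type by
design. Nodes on the network but absent from the expression data remain in
the graph: they carry geodesic distance (conduits) but are never scored or
summed. The scored set is `assayed ∩ LCC nodes`. All distances are hop
counts computed by breadth-first search (`scipy.sparse.csgraph`), held as a
full matrix.

**Sphere of influence (competitive null, gene axis).** For center gene *i*,
Spearman correlations `ρ_ij` to every other scored gene are computed on all
samples pooled (midrank ties; zero-variance genes get ρ = 0 with a warning
rather than being dropped, so neighborhood sizes are unaffected). The
observed statistic at radius r is `C_i(r) = Σ_{0<d_ij≤r} |ρ_ij|` over
*assayed* neighbors; its null is the sum of `n_r` draws with replacement
from the gene's own profile `{|ρ_ij| : j ≠ i}`. Empirical p-values use the
add-one estimator `p = (1 + #{null ≥ obs}) / (B + 1)`, which is never zero.
Radii whose assayed neighborhood is empty get p = 1. Radii that add no new
assayed neighbor (including all radii beyond the gene's eccentricity) reuse
the previous null sample: observed statistic and null distribution are
unchanged, so the marginal p-value is identical and recomputation would only
add Monte-Carlo noise.

**Decay of differential expression (self-contained null, sample axis).** The
per-gene association magnitude is `g_j = |t|` from a two-sample t-test
between the phenotype classes — Welch's unequal-variance form by default
(safer for heterogeneous cohorts; a pooled-variance flag is provided). The
statistic is deliberately a magnitude: the decay pattern concerns how much,
not in which direction, neighbors respond. The observed discordance is
Kendall's tau-b between `{g_j}` and `{d_ij}` over the assayed neighborhood;
tie correction matters because distances are small integers. The null
permutes phenotype labels: one shared set of B permuted label vectors is
drawn per run and reused for every center gene and radius — each permutation
recomputes `g*_j` for all genes at once, which leaves every per-gene
marginal null unchanged while reducing the cost from O(B·G·D) to O(B·G)
t-statistic recomputations. Label permutation leaves the expression matrix
untouched, so inter-gene correlations are preserved exactly. The p-value is
lower-tail with add-one smoothing, `p = (1 + #{D* ≤ D_obs}) / (B + 1)`; a
documented flag switches to the strict `<` count. Neighborhoods with fewer
than 3 assayed members, or with the coefficient undefined (all `g` tied, or
a single distance shell), get p = 1 — too small to exhibit a decay either
way; undefined null draws are treated as 0 (no signal).

**Combination and scan.** Per radius, `X² = −2(ln p_S + ln p_D)` is referred
to χ² with 4 df — the two tests permute orthogonal axes (genes vs samples)
and are treated as independent; calibration is verified empirically on null
data rather than analytically. The gene's score `p_GS` is the raw minimum of
`p_Comb(r)` over `r = 1..D`, with the smallest argmin reported as the best
radius. Every gene is scanned over the same grid 1..D even where its
eccentricity is smaller (curves flatten at saturation), keeping the
Bonferroni factor uniform: a gene is called significant when
`p_GS ≤ α / D`. The minimum itself is *not* adjusted — the threshold is.
With add-one estimators the smallest attainable score is
`p_Comb(1/(B+1), 1/(B+1))`, e.g. ≈ 5.4e−5 at B = 500 and ≈ 1.4e−5 at
B = 1000; reported scores at that floor mean "at least this significant".

**Multiplicity across genes** is optionally handled by `genewise_fwer`: a
max-statistic (min-p) permutation scheme that re-runs the whole scan under
outer label permutations and compares each observed `p_GS` to the
distribution of permutation minima. It is off by default and intended for
small studies; the exact historical adjustment scheme is not fully specified
in the literature this follows, so the max-statistic choice is documented
here as this package's.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `b_sphere` | 1000 | resamplings per (gene, distinct radius) for the sphere null |
| `b_decay` | 1000 | shared phenotype-label permutations for the decay null |
| `alpha` | 0.05 | significance level before diameter scaling |
| `missing_thresh` | 0.25 | drop genes, then samples, with a larger missing fraction |
| `t_equal_var` | False | pooled- instead of unequal-variance t statistic |
| `seed` | 17 | root of all randomness (one stream per gene + one for labels) |

Defaults of 10³ resamplings/permutations balance the p-value floor (1.0e−3
per test) against runtime; smaller B is used in tests and evaluation scripts
where only rates or ranks are needed.

## Synthetic data

The generator exists to make every stage verifiable without external data.
It plants a single driver gene and induces *both* signatures jointly through
one latent factor `z ~ N(0,1)` per sample with distance-attenuated loadings:
a gene at distance d ≤ cutoff is
`λ0 γ^d · z + δ0 γ_DE^d · 1[class=high] + ε`, the driver itself is
`z + δ0 · 1[class=high] + ε` (the center of the decaying pattern is itself
differentially expressed), and genes beyond the cutoff are pure noise
(`ε ~ N(0, sd²)`). The factor construction has closed-form moments — with no
class shift, `corr(driver, gene at d) = λ(d)/√((1+sd²)(λ(d)²+sd²))` — used
directly in tests. Defaults: `λ0 = 0.8`, `γ = 0.6`, `δ0 = 1.5`,
`γ_DE = 0.6`, `sd = 1`, cutoff 4, 30 + 30 samples, 75% of nodes assayed
(the network is larger than the measured gene set, as in real studies).

The default planted driver is a node of maximum eccentricity (ties broken by
degree, then lexicographically). A peripheral center keeps the planted
geometry meaningful: its distance shells grow gradually, so the signal
region d ≤ 4 is a proper subgraph and the radius scan has something to
localize. A hub center in a ~200-node scale-free graph would put half the
network within distance 2, saturate both tests' p-value floors immediately,
and collapse the scan.

What the generator does **not** emulate: platform noise models, batch
effects, correlated background modules away from the driver, multiple
interacting drivers, or informative missingness (masking is uniform).
Passing recovery tests therefore shows the statistics behave as designed on
the planted mechanism — not that real cohorts are this clean.

## Numerical and implementation notes

- Spearman profiles are computed by midranking each gene's row once and
  taking normalized inner products; values are clipped to [−1, 1].
- The decay permutation null needs tau-b for B permuted vectors at every
  radius. Because a radius-r neighborhood is a prefix of the distance-sorted
  gene order, one incremental O(n²) pass per gene (a numba kernel
  accumulating concordant-minus-discordant and tie counts as each distance
  shell is appended) yields the statistic at *every* radius for all B rows;
  tie corrections are exact, and the kernel is tested against an O(n²)
  enumeration oracle and `scipy.stats.kendalltau`.
- The permutation |t| matrix is computed with one indicator-matrix product
  per run (class sums and sums of squares), tested per-permutation against
  `scipy.stats.ttest_ind`.
- Determinism: a single `SeedSequence` spawns one label-permutation stream
  and one resampling stream per scored gene (keyed by sorted gene order), so
  identical seeds give byte-identical outputs regardless of gene subsets
  ordering.
- Missing data: genes are filtered before samples (the order changes the
  outcome and is fixed), then survivors are imputed by gene-wise median; a
  `"none"` option leaves NaNs for complete-case handling by the caller.

## Known limitations

- The diameter-scaled threshold corrects the radius scan per gene, not gene
  multiplicity: among hundreds of null genes a handful of nominal calls are
  expected. Use `genewise_fwer` (or an FDR procedure downstream) when
  family-wise control across genes is needed.
- The sphere test is mildly conservative for moderate neighborhoods: the
  observed statistic sums distinct genes' correlations while the null
  resamples with replacement from a finite pool (a without- vs
  with-replacement variance gap). Observed null rejection rates at the 0.05
  level run ≈ 0.02–0.06 in calibration runs.
- Fisher's combination assumes the two per-radius p-values are independent;
  this holds by the orthogonal-axes argument but is verified only
  empirically.
- At the resampling floor, scores tie across radii and the reported best
  radius is the smallest; finer localization requires larger B.
- Edge direction and type are ignored; distances are unweighted hops.
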