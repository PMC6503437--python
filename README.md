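# genesurrounder

Network-based prioritization of genes that are **sources of expression
dysregulation** ("disruptive" genes). Given a gene expression study with a
binary phenotype (e.g. low- vs high-grade tumors) and an undirected gene
interaction network, the method scores every assayed gene on the network by
asking two questions about each geodesic neighborhood radius *r* around it:

1. **Sphere of influence** — is gene *i* more strongly correlated with its
   network neighbors than with a random set of genes? The observed statistic
   is the total absolute Spearman correlation
   `C_i(r) = Σ_{0 < d_ij ≤ r} |ρ_ij|`, compared to sums of `n_r` values
   resampled with replacement from gene *i*'s own correlation profile
   (a *competitive* null on the gene axis), giving `p_S(r)`.
2. **Decay of differential expression** — does differential expression around
   *i* fall off with network distance? The observed statistic is the Kendall
   tau-b discordance `D_i(r) = τ_B({g_j}, {d_ij})` between the per-gene |t|
   statistics and distances over the neighborhood, compared to phenotype-label
   permutations that preserve all inter-gene correlations (a *self-contained*
   null on the sample axis), giving `p_D(r)`.

Because the two nulls permute orthogonal axes, the p-values are combined with
Fisher's method, `X²(r) = −2(ln p_S(r) + ln p_D(r))`, referred to a χ²
distribution with 4 degrees of freedom. The gene's final score is

```
p_GS(i) = min over r = 1..D of p_Comb(i, r)
```

with *D* the network diameter; the significance threshold is Bonferroni-scaled
by *D* (at α = 0.05 and D = 34 that is −log10 p ≥ 2.83). Ranking genes by
`p_GS` prioritizes genes that both influence their neighborhood and sit at the
center of a distance-decaying pattern of differential expression — precise,
experimentally testable targets rather than whole pathways.

The package is aimed at computational biologists doing disease-gene
prioritization: it provides the full scoring pipeline, file-based and
command-line front ends, evaluation utilities (cross-study concordance,
optional gene-level permutation FWER), and a synthetic-data generator with
planted ground truth so every stage is verifiable without external downloads.

## Worked example

`examples/score_synthetic_study.py` builds a 200-node scale-free network,
plants a driver gene whose neighbor correlations and neighbor differential
expression both decay with distance (signal out to distance 4), and scores
all 150 assayed genes:

```
network diameter: 6; scored genes: 150
-log10 significance threshold (alpha/D): 2.08

 gene     p_gs  neglog10_p_gs  best_radius  significant     p_de  degree
G0030 0.000054       4.271496            3         True 0.001873       5
G0098 0.003235       2.490155            2         True 0.632935       6
G0156 0.003765       2.424190            3         True 0.000663       2
...

planted driver G0030 ranked #1 of 150
```

`p_gs` is the minimum combined p-value over radii (here at its B = 500
resampling floor for the driver), `best_radius` the radius attaining it —
close to the planted signal cutoff of 4 — and `significant` the
diameter-scaled Bonferroni call. Other scripts in `examples/` demonstrate
per-radius diagnostic curves, type-I-error calibration on null data,
cross-study concordance, and the file-based pipeline.

## Command line

```sh
genesurrounder simulate --kind scale-free --n-nodes 200 --out data/
genesurrounder run --expr data/expression.tsv --pheno data/phenotype.tsv \
    --network data/network.tsv --out results/ --seed 17
genesurrounder concordance resultsA/results.csv resultsB/results.csv
```

Inputs are plain delimited text: an expression matrix (genes × samples,
first column gene id), a two-column phenotype table (sample, label), and a
network as a two-column edge list or SIF. Outputs are a ranked `results.csv`,
per-gene per-radius `radius_curves.csv`, and a run log recording the seed,
resampling counts, network statistics and the threshold used.

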