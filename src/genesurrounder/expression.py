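"""Expression data container and per-gene statistics.

Two per-gene quantities feed the downstream tests:

* the Spearman rank-correlation profile rho_ij between a center gene i and
  every other assayed on-network gene j, computed on all samples pooled
  (phenotype-independent), and
* the differential-expression magnitude g_j = |t| from a two-sample
  (by default Welch) t-test between the two phenotype classes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


class StudyError(ValueError):
    """Raised for invalid expression-study input."""


@dataclass
class ExpressionStudy:
    """Gene expression matrix (genes x samples) with per-sample class labels.

    ``values`` rows are genes (unique ids), columns are samples; ``phenotype``
    maps every sample to its class label.  The label set is not constrained
    here, but the differential-expression test requires exactly two classes
    with at least two samples each.
    """

    values: pd.DataFrame
    phenotype: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise StudyError(f"duplicate gene ids: {list(dups[:5])}")
        missing = [s for s in self.values.columns if s not in self.phenotype.index]
        if missing:
            raise StudyError(f"samples without phenotype label: {missing[:10]}")
        # align label order to the matrix columns
        self.phenotype = self.phenotype.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def classes(self) -> list:
        return sorted(pd.unique(self.phenotype))

    def class_mask(self) -> np.ndarray:
        """Boolean mask of membership in the (sorted) second class."""
        cls = self.classes()
        if len(cls) != 2:
            raise StudyError(f"expected 2 phenotype classes, found {len(cls)}")
        return (self.phenotype == cls[1]).to_numpy()

    def subset_genes(self, genes) -> "ExpressionStudy":
        keep = [g for g in self.genes if g in set(genes)]
        return ExpressionStudy(self.values.loc[keep], self.phenotype.copy())


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=-1, method="average")


def _normalized_ranks(values: np.ndarray) -> np.ndarray:
    """Center and L2-normalize midranks rowwise; zero-variance rows -> 0."""
    r = _midranks(values)
    r = r - r.mean(axis=-1, keepdims=True)
    norm = np.sqrt((r**2).sum(axis=-1, keepdims=True))
    flat = (norm.squeeze(-1) == 0) if r.ndim > 1 else (norm == 0)
    if np.any(flat):
        log.warning(
            "%d zero-variance gene(s); their correlations are set to 0",
            int(np.sum(flat)),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(norm > 0, r / np.where(norm == 0, 1.0, norm), 0.0)
    return z


def spearman_matrix(study: ExpressionStudy) -> pd.DataFrame:
    """Full gene-by-gene Spearman correlation matrix (midrank ties).

    Zero-variance genes get correlation 0 with everything (warned); the
    diagonal is 1 by convention.
    """
    if study.n_samples < 3:
        raise StudyError("need >= 3 samples for correlation")
    if study.values.isna().any().any():
        raise StudyError("missing values present; filter/impute first")
    z = _normalized_ranks(study.values.to_numpy(float))
    rho = np.clip(z @ z.T, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=study.genes, columns=study.genes)


def spearman_profile(study: ExpressionStudy, gene: str) -> pd.Series:
    """Spearman correlation of ``gene`` with every other gene in the study.

    Computed on all samples pooled, independent of phenotype.
    """
    if gene not in study.genes:
        raise StudyError(f"gene {gene!r} not assayed")
    if study.n_samples < 3:
        raise StudyError("need >= 3 samples for correlation")
    z = _normalized_ranks(study.values.to_numpy(float))
    center = z[study.genes.get_loc(gene)]
    rho = np.clip(z @ center, -1.0, 1.0)
    prof = pd.Series(rho, index=study.genes).drop(gene)
    return prof


def de_statistic(study: ExpressionStudy, equal_var: bool = False) -> pd.DataFrame:
    """Per-gene two-sample t-test between the phenotype classes.

    Returns a frame with columns ``t`` (signed statistic, class2 - class1 in
    sorted label order), ``g`` (its magnitude |t|) and ``p_de`` (two-sided
    p-value).  Welch's unequal-variance form is the default; set
    ``equal_var=True`` for the pooled-variance test.  Genes with zero
    variance in both classes get g = 0 and p = 1 (warned).
    """
    mask = study.class_mask()
    n1, n0 = int(mask.sum()), int((~mask).sum())
    if min(n0, n1) < 2:
        raise StudyError(f"each class needs >= 2 samples (got {n0} and {n1})")
    x = study.values.to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(
            x[:, mask], x[:, ~mask], axis=1, equal_var=equal_var
        )
    bad = ~np.isfinite(t)
    if bad.any():
        log.warning("%d degenerate gene(s) in t-test; g set to 0", int(bad.sum()))
        t = np.where(bad, 0.0, t)
        p = np.where(bad, 1.0, p)
    return pd.DataFrame(
        {"t": t, "g": np.abs(t), "p_de": p}, index=study.genes
    )


def permute_labels(study: ExpressionStudy, seed) -> ExpressionStudy:
    """Return a copy with phenotype labels randomly permuted across samples.

    The label multiset (class sizes) is preserved and the expression matrix
    is untouched; deterministic for a given seed (or Generator).
    """
    rng = np.random.default_rng(seed)
    permuted = rng.permutation(study.phenotype.to_numpy())
    return ExpressionStudy(
        study.values, pd.Series(permuted, index=study.samples)
    )


def welch_t_null(
    values: np.ndarray,
    class_mask: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    equal_var: bool = False,
) -> np.ndarray:
    """|t| statistics for ``n_perm`` label permutations, for every gene.

    Vectorized over permutations: class sums are obtained through one matrix
    product with a (samples x n_perm) indicator matrix.  Returns an array of
    shape ``(n_perm, n_genes)``.  Degenerate (zero-denominator) entries are 0.
    """
    x = np.asarray(values, float)
    n_genes, n_samp = x.shape
    n1 = int(class_mask.sum())
    n0 = n_samp - n1
    ind = np.empty((n_samp, n_perm), dtype=float)
    base = np.asarray(class_mask, float)
    for b in range(n_perm):
        ind[:, b] = base[rng.permutation(n_samp)]
    tot = x.sum(axis=1, keepdims=True)
    tot_sq = (x**2).sum(axis=1, keepdims=True)
    s1 = x @ ind
    q1 = (x**2) @ ind
    s0 = tot - s1
    q0 = tot_sq - q1
    m1, m0 = s1 / n1, s0 / n0
    v1 = np.maximum(q1 - n1 * m1**2, 0.0) / (n1 - 1)
    v0 = np.maximum(q0 - n0 * m0**2, 0.0) / (n0 - 1)
    if equal_var:
        sp = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
        denom = np.sqrt(sp * (1.0 / n1 + 1.0 / n0))
    else:
        denom = np.sqrt(v1 / n1 + v0 / n0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, (m1 - m0) / np.where(denom == 0, 1.0, denom), 0.0)
    return np.abs(t).T
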