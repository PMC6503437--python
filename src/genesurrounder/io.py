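"""Readers, writers and input filtering.

Formats are plain delimited text throughout: expression matrices with genes
in rows (first column = gene id) and samples in columns; phenotype tables
with two columns (sample id, class label); networks as two-column edge lists
or SIF.  Tab is the default delimiter; comma-separated files are detected by
the ``.csv`` extension.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionStudy, StudyError
from .network import GeneNetwork, largest_connected_component

log = logging.getLogger(__name__)


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def load_study(expr_path, pheno_path) -> ExpressionStudy:
    """Load an expression matrix and its phenotype labels.

    Every expression sample must have a phenotype label (missing ones are an
    error naming the ids); phenotype rows for samples not in the matrix are
    dropped with a warning.  Non-numeric expression cells other than the
    usual missing sentinels (empty, NA, NaN) are an error.
    """
    expr = pd.read_csv(expr_path, sep=_sep_for(expr_path), index_col=0, comment="#")
    expr.index = expr.index.astype(str)
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique()
        raise StudyError(f"duplicate gene ids in {expr_path}: {list(dups[:5])}")
    for col in expr.columns:
        if expr[col].dtype == object:
            converted = pd.to_numeric(expr[col], errors="coerce")
            bad = expr[col].notna() & converted.isna()
            if bad.any():
                cells = [(g, col, expr.at[g, col]) for g in expr.index[bad][:3]]
                raise StudyError(f"non-numeric expression cells: {cells}")
            expr[col] = converted
    expr = expr.astype(float)

    pheno = pd.read_csv(
        pheno_path, sep=_sep_for(pheno_path), header=0, comment="#", dtype=str
    )
    if pheno.shape[1] < 2:
        raise StudyError(f"{pheno_path}: expected two columns (sample, label)")
    labels = pd.Series(
        pheno.iloc[:, 1].to_numpy(), index=pheno.iloc[:, 0].astype(str)
    )
    missing = [s for s in expr.columns if s not in labels.index]
    if missing:
        raise StudyError(f"samples missing from phenotype file: {missing}")
    extra = labels.index.difference(expr.columns)
    if len(extra):
        log.warning("dropping %d phenotype rows without expression", len(extra))
    return ExpressionStudy(expr, labels.loc[expr.columns])


def write_study(study: ExpressionStudy, expr_path, pheno_path) -> None:
    """Write a study in the same delimited formats ``load_study`` reads."""
    expr = study.values.copy()
    expr.index.name = "gene"
    expr.to_csv(expr_path, sep=_sep_for(expr_path))
    pheno = study.phenotype.rename("label").rename_axis("sample").reset_index()
    pheno.to_csv(pheno_path, sep=_sep_for(pheno_path), index=False)


def filter_missing(
    study: ExpressionStudy,
    gene_thresh: float = 0.25,
    sample_thresh: float = 0.25,
    impute: str = "median",
) -> ExpressionStudy:
    """Drop genes, then samples, with too much missing data; impute the rest.

    A gene is dropped when its fraction of missing values exceeds
    ``gene_thresh``; the sample filter is applied afterwards on the surviving
    genes (the order matters and is fixed).  Remaining missing cells are
    filled with the gene-wise median (``impute="median"``) or left as NaN
    (``impute="none"``, for complete-case handling downstream).
    """
    if not (0 <= gene_thresh < 1 and 0 <= sample_thresh < 1):
        raise ValueError("thresholds must lie in [0, 1)")
    vals = study.values
    keep_genes = vals.isna().mean(axis=1) <= gene_thresh
    vals = vals.loc[keep_genes]
    keep_samples = vals.isna().mean(axis=0) <= sample_thresh
    vals = vals.loc[:, keep_samples]
    if vals.empty:
        raise StudyError("missing-data filter removed all genes or samples")
    dropped_g = int((~keep_genes).sum())
    dropped_s = int((~keep_samples).sum())
    if dropped_g or dropped_s:
        log.info(
            "missing-data filter dropped %d gene(s), %d sample(s)",
            dropped_g,
            dropped_s,
        )
    if impute == "median":
        med = vals.median(axis=1)
        vals = vals.apply(lambda row: row.fillna(med[row.name]), axis=1)
    elif impute != "none":
        raise ValueError(f"unknown imputation {impute!r}")
    return ExpressionStudy(vals, study.phenotype.loc[vals.columns])


def restrict_to_network(
    study: ExpressionStudy, net: GeneNetwork
) -> tuple[ExpressionStudy, GeneNetwork]:
    """Confine scoring to genes assayed AND on the network's LCC.

    The returned study contains only the scored genes; the returned network
    keeps all LCC nodes (unassayed nodes remain as distance conduits) with
    its assayed mask set to the scored genes.
    """
    lcc = largest_connected_component(net)
    scored = set(study.genes) & lcc.nodes
    if not scored:
        raise StudyError("no assayed gene is on the network's largest component")
    return study.subset_genes(scored), lcc.with_assayed(scored)
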