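"""End-to-end scoring: per-gene curves over all radii, the radius scan, and
the ranked result table.

``score_study`` is the in-memory engine; ``run_pipeline`` is the file-level
front end (load, filter, restrict, score, write).  Both are deterministic
for a given seed: a single ``SeedSequence`` spawns one stream for the shared
phenotype-label permutations and one resampling stream per scored gene
(keyed by position in the sorted gene list).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .decay import decay_pvalue_curve
from .expression import ExpressionStudy, de_statistic, spearman_matrix, welch_t_null
from .io import filter_missing, load_study, restrict_to_network
from .network import GeneNetwork, geodesic_distances, read_edge_list
from .scoring import GeneScore, bonferroni_threshold, rank_genes, scan_radii
from .sphere import sphere_pvalue_curve

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a file-level run."""

    expr_path: str
    pheno_path: str
    network_path: str
    out_dir: str
    b_sphere: int = 1000
    b_decay: int = 1000
    alpha: float = 0.05
    seed: int = 17
    missing_thresh: float = 0.25
    genes: list[str] | None = None  # optional subset of centers to score
    t_equal_var: bool = False

    def __post_init__(self) -> None:
        if self.b_sphere < 1 or self.b_decay < 1:
            raise ValueError("resampling counts must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.missing_thresh < 1:
            raise ValueError("missing threshold must be in [0, 1)")


@dataclass
class StudyResult:
    """Ranked table plus per-radius diagnostics and run metadata."""

    results: pd.DataFrame
    curves: pd.DataFrame
    diameter: int
    n_scored: int
    threshold_neglog10: float


def score_study(
    study: ExpressionStudy,
    net: GeneNetwork,
    b_sphere: int = 1000,
    b_decay: int = 1000,
    alpha: float = 0.05,
    seed=17,
    genes: list[str] | None = None,
    t_equal_var: bool = False,
) -> StudyResult:
    """Score every assayed on-network gene (or the subset ``genes``).

    ``net`` must be connected with its assayed mask equal to the study's
    scored gene set (see :func:`genesurrounder.io.restrict_to_network`).
    For each center gene i the sphere-of-influence and decay curves are
    computed at every radius 1..D, combined with Fisher's method, and the
    minimum combined p over radii is reported with its diameter-scaled
    Bonferroni significance call.
    """
    oracle = geodesic_distances(net)
    diameter = oracle.diameter
    scored = sorted(set(net.assayed) & set(study.genes))
    if not scored:
        raise ValueError("no scored genes; set the network's assayed mask")
    centers = scored if genes is None else sorted(set(genes) & set(scored))
    if genes is not None and not centers:
        raise ValueError("requested genes are not scored genes")

    study = study.subset_genes(scored)
    study = ExpressionStudy(study.values.loc[scored], study.phenotype)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    perm_stream, *gene_streams = ss.spawn(1 + len(centers))

    rho = spearman_matrix(study).to_numpy()
    destats = de_statistic(study, equal_var=t_equal_var)
    g_obs_all = destats["g"].to_numpy()
    g_null_all = welch_t_null(
        study.values.to_numpy(float),
        study.class_mask(),
        b_decay,
        np.random.default_rng(perm_stream),
        equal_var=t_equal_var,
    )

    node_index = {g: k for k, g in enumerate(oracle.nodes)}
    scored_pos = np.array([node_index[g] for g in scored])
    gene_pos = {g: k for k, g in enumerate(scored)}

    scores: list[GeneScore] = []
    curve_frames = []
    thr, thr_neglog10 = bonferroni_threshold(alpha, diameter)
    log.info(
        "scoring %d genes | network: %d nodes, %d edges, diameter %d | "
        "B_sphere=%d B_decay=%d | -log10 threshold %.2f",
        len(centers), net.n_nodes, net.n_edges, diameter,
        b_sphere, b_decay, thr_neglog10,
    )
    for gi, gene in enumerate(centers):
        others = [g for g in scored if g != gene]
        rows = np.array([gene_pos[g] for g in others])
        d_all = oracle.distances_from(gene)
        d_vec = d_all[scored_pos[rows]]
        abs_rho = np.abs(rho[gene_pos[gene], rows])

        sph = sphere_pvalue_curve(
            abs_rho, d_vec, diameter, b_sphere,
            np.random.default_rng(gene_streams[gi]), gene=gene,
        )
        dec = decay_pvalue_curve(
            g_obs_all[rows], g_null_all[:, rows], d_vec, diameter, gene=gene
        )
        score, curve = scan_radii(sph, dec, diameter, alpha)
        scores.append(score)
        curve_frames.append(curve.to_frame())

    degree = pd.Series({g: net.degree(g) for g in centers})
    results = rank_genes(scores, p_de=destats["p_de"], degree=degree)
    curves = pd.concat(curve_frames, ignore_index=True)
    return StudyResult(
        results=results,
        curves=curves,
        diameter=diameter,
        n_scored=len(centers),
        threshold_neglog10=thr_neglog10,
    )


def run_pipeline(config: RunConfig) -> StudyResult:
    """File-level run: load -> filter -> restrict -> score -> write.

    Writes ``results.csv`` (ranked genes), ``radius_curves.csv`` (per-gene
    per-radius diagnostics) and ``run_log.txt`` into ``config.out_dir``.
    Errors from any stage are re-raised with the stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"[{name}] {exc}") from exc

    study = stage("load", load_study, config.expr_path, config.pheno_path)
    study = stage(
        "filter", filter_missing, study,
        config.missing_thresh, config.missing_thresh,
    )
    net = stage("network", read_edge_list, config.network_path)
    study, net = stage("restrict", restrict_to_network, study, net)
    result = stage(
        "score", score_study, study, net,
        b_sphere=config.b_sphere, b_decay=config.b_decay,
        alpha=config.alpha, seed=config.seed, genes=config.genes,
        t_equal_var=config.t_equal_var,
    )

    results_path = out / "results.csv"
    result.results.to_csv(results_path, index=False, float_format="%.10g")
    result.curves.to_csv(out / "radius_curves.csv", index=False, float_format="%.10g")
    with open(out / "run_log.txt", "w") as fh:
        fh.write(
            "seed={s.seed}\nb_sphere={s.b_sphere}\nb_decay={s.b_decay}\n"
            "alpha={s.alpha}\n".format(s=config)
        )
        fh.write(
            f"network_nodes={net.n_nodes}\nnetwork_edges={net.n_edges}\n"
            f"diameter={result.diameter}\nscored_genes={result.n_scored}\n"
            f"bonferroni_neglog10_threshold={result.threshold_neglog10:.4f}\n"
        )
    log.info("wrote %s", results_path)
    return result


def genewise_fwer(
    study: ExpressionStudy,
    net: GeneNetwork,
    b_outer: int = 50,
    b_sphere: int = 200,
    b_decay: int = 200,
    alpha: float = 0.05,
    seed=17,
) -> pd.DataFrame:
    """Max-statistic (min-p) permutation adjustment across genes.  Optional
    and expensive: each of ``b_outer`` outer label permutations re-runs the
    whole scan, and the family-wise adjusted p-value of gene i is the
    add-one fraction of outer minima at or below its observed p_gs.
    """
    ss = np.random.SeedSequence(seed)
    inner, outer = ss.spawn(2)
    observed = score_study(
        study, net, b_sphere=b_sphere, b_decay=b_decay, alpha=alpha, seed=inner
    ).results.set_index("gene")
    outer_rng = np.random.default_rng(outer)
    mins = np.empty(b_outer)
    for b in range(b_outer):
        permuted = ExpressionStudy(
            study.values,
            pd.Series(
                outer_rng.permutation(study.phenotype.to_numpy()),
                index=study.samples,
            ),
        )
        res = score_study(
            permuted, net, b_sphere=b_sphere, b_decay=b_decay,
            alpha=alpha, seed=ss.spawn(1)[0],
        ).results
        mins[b] = res["p_gs"].min()
    adj = [
        (1.0 + np.count_nonzero(mins <= p)) / (b_outer + 1.0)
        for p in observed["p_gs"]
    ]
    out = observed.reset_index()[["gene", "p_gs"]].copy()
    out["p_fwer"] = adj
    return out
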