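"""Evidence combination and the radius scan.

Per radius, the two per-radius p-values (sphere of influence, decay of
differential expression) are combined with Fisher's method,

    X^2(r) = -2 (ln p_S(r) + ln p_D(r)),

referred to a chi-square distribution with 4 degrees of freedom (the tests
permute orthogonal axes — genes vs samples — and are treated as independent).
A gene's final score is the minimum combined p-value over all radii
1..D (D = network diameter), reported raw; the significance call scales the
alpha threshold by D (Bonferroni over the radius scan).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decay import DecayResult
from .sphere import SphereResult


def fisher_combine(p_sphere, p_decay):
    """Fisher's method for two p-values.

    Returns ``(X2, p_comb)`` where ``X2 = -2 (ln p_sphere + ln p_decay)``
    and ``p_comb`` is the upper-tail chi-square(4 df) probability at X2.
    Accepts scalars or arrays; inputs must lie in (0, 1].
    """
    ps = np.asarray(p_sphere, float)
    pd_ = np.asarray(p_decay, float)
    if np.any(ps <= 0) or np.any(pd_ <= 0) or np.any(ps > 1) or np.any(pd_ > 1):
        raise ValueError("p-values must lie in (0, 1]")
    x2 = -2.0 * (np.log(ps) + np.log(pd_))
    p_comb = stats.chi2.sf(x2, df=4)
    if x2.ndim == 0:
        return float(x2), float(p_comb)
    return x2, p_comb


def bonferroni_threshold(alpha: float, diameter: int) -> tuple[float, float]:
    """Radius-scan significance threshold: alpha scaled by the diameter.

    Returns ``(alpha / D, -log10(alpha / D))``; e.g. alpha = 0.05 with
    D = 34 gives a -log10 threshold of 2.83.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if diameter < 1:
        raise ValueError("diameter must be >= 1")
    thr = alpha / diameter
    return thr, -math.log10(thr)


@dataclass
class RadiusCurve:
    """Per-radius diagnostics for one gene (the material of curve plots)."""

    gene: str
    radii: np.ndarray
    n_neighbors: np.ndarray
    c_obs: np.ndarray
    p_sphere: np.ndarray
    d_obs: np.ndarray
    p_decay: np.ndarray
    x2: np.ndarray
    p_comb: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene,
                "radius": self.radii,
                "n_neighbors": self.n_neighbors,
                "c_obs": self.c_obs,
                "p_sphere": self.p_sphere,
                "d_obs": self.d_obs,
                "p_decay": self.p_decay,
                "x2": self.x2,
                "p_comb": self.p_comb,
            }
        )


@dataclass
class GeneScore:
    """A gene's final score: minimum combined p over the radius scan."""

    gene: str
    p_gs: float
    best_radius: int
    significant: bool


def scan_radii(
    sphere: SphereResult,
    decay: DecayResult,
    diameter: int,
    alpha: float = 0.05,
) -> tuple[GeneScore, RadiusCurve]:
    """Combine the two per-radius curves and take the minimum over radii.

    ``p_gs`` is the smallest combined p-value across radii 1..D, ``best
    radius`` the smallest radius attaining it, and ``significant`` the
    diameter-scaled Bonferroni call ``p_gs <= alpha / D``.
    """
    if len(sphere.radii) != diameter or len(decay.radii) != diameter:
        raise ValueError("curves must cover radii 1..diameter")
    x2, p_comb = fisher_combine(sphere.p, decay.p)
    best = int(np.argmin(p_comb))  # np.argmin returns the first minimum
    p_gs = float(p_comb[best])
    thr, _ = bonferroni_threshold(alpha, diameter)
    score = GeneScore(
        gene=sphere.gene,
        p_gs=p_gs,
        best_radius=best + 1,
        significant=p_gs <= thr,
    )
    curve = RadiusCurve(
        gene=sphere.gene,
        radii=sphere.radii,
        n_neighbors=sphere.n_neighbors,
        c_obs=sphere.c_obs,
        p_sphere=sphere.p,
        d_obs=decay.d_obs,
        p_decay=decay.p,
        x2=x2,
        p_comb=p_comb,
    )
    return score, curve


def rank_genes(
    scores: list[GeneScore],
    p_de: pd.Series | None = None,
    degree: pd.Series | None = None,
) -> pd.DataFrame:
    """Result table sorted by ascending p_gs (ties broken by gene id).

    Columns: gene, p_gs, neglog10_p_gs, best_radius, significant, and —
    where provided — the per-gene differential-expression p-value and the
    network degree.
    """
    rows = pd.DataFrame(
        {
            "gene": [s.gene for s in scores],
            "p_gs": [s.p_gs for s in scores],
            "neglog10_p_gs": [-math.log10(s.p_gs) for s in scores],
            "best_radius": [s.best_radius for s in scores],
            "significant": [s.significant for s in scores],
        }
    )
    if p_de is not None:
        rows["p_de"] = rows["gene"].map(p_de).to_numpy()
    if degree is not None:
        rows["degree"] = rows["gene"].map(degree).to_numpy()
    rows = rows.sort_values(["p_gs", "gene"], kind="stable").reset_index(drop=True)
    return rows


@dataclass
class ConcordanceResult:
    """Cross-study rank agreement between two result tables."""

    rho_p_gs: float
    rho_p_de: float | None
    n_shared: int


def concordance(results_a: pd.DataFrame, results_b: pd.DataFrame) -> ConcordanceResult:
    """Spearman correlation between two studies' p_gs vectors (shared genes).

    Also reports, where both tables carry a ``p_de`` column, the matching
    correlation of the single-gene differential-expression p-values as a
    reference point.  Requires >= 3 shared genes.
    """
    a = results_a.set_index("gene")
    b = results_b.set_index("gene")
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need >= 3")
    rho_gs = stats.spearmanr(a.loc[shared, "p_gs"], b.loc[shared, "p_gs"]).statistic
    rho_de = None
    if "p_de" in a.columns and "p_de" in b.columns:
        rho_de = float(
            stats.spearmanr(a.loc[shared, "p_de"], b.loc[shared, "p_de"]).statistic
        )
    return ConcordanceResult(float(rho_gs), rho_de, int(len(shared)))
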