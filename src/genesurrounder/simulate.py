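"""Synthetic networks and two-class expression studies with planted structure.

The generator plants a single "driver" gene whose two defining signatures
both decay with geodesic distance d from it:

* correlation with the driver, via a shared latent factor z ~ N(0,1) with
  distance-attenuated loading lambda(d) = lambda0 * gamma**d, and
* differential expression, via a class mean shift delta(d) = delta0 *
  gamma_de**d added to one phenotype class.

A gene at distance d <= cutoff is  lambda(d) * z + delta(d) * c + noise
(c the class indicator); the driver itself is  z + delta0 * c + noise;
genes beyond the cutoff are pure noise.  The latent-factor construction
gives closed-form moments: with no class shift, the population correlation
between the driver and a gene at distance d is

    corr(d) = lambda(d) / sqrt((1 + sd^2) * (lambda(d)^2 + sd^2)).

Only a fraction of the network's nodes are "assayed" (measured), mirroring
real studies where the network is larger than the profiled gene set; the
driver is always assayed, and unassayed nodes stay on the network as
distance conduits.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionStudy
from .network import GeneNetwork, geodesic_distances

NETWORK_KINDS = ("path", "star", "small-world", "scale-free")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth of a synthetic study."""

    driver: str
    lambda0: float = 0.8
    gamma: float = 0.6
    delta0: float = 1.5
    gamma_de: float = 0.6
    noise_sd: float = 1.0
    cutoff: int = 4
    n_per_class: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.gamma < 1 and 0 < self.gamma_de < 1):
            raise ValueError("decay rates must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be positive")
        # implied correlations stay inside (-1, 1) automatically:
        # |corr| <= |lambda(d)| / sqrt(lambda(d)^2 + sd^2) < 1 for sd > 0
        if self.n_per_class < 2:
            raise ValueError("need >= 2 samples per class")

    def loading(self, d: int) -> float:
        return self.lambda0 * self.gamma**d

    def shift(self, d: int) -> float:
        return self.delta0 * self.gamma_de**d


def make_network(kind: str, n_nodes: int, seed: int = 0) -> GeneNetwork:
    """Connected undirected test network of a named family.

    ``path`` and ``star`` are deterministic; ``small-world`` is a connected
    Watts-Strogatz graph (k=4, p=0.1) and ``scale-free`` a Barabasi-Albert
    graph (m=2).  Nodes are named G0000, G0001, ...
    """
    if n_nodes < 4:
        raise ValueError("need n_nodes >= 4")
    if kind == "path":
        g = nx.path_graph(n_nodes)
    elif kind == "star":
        g = nx.star_graph(n_nodes - 1)
    elif kind == "small-world":
        g = nx.connected_watts_strogatz_graph(n_nodes, 4, 0.1, seed=seed)
    elif kind == "scale-free":
        g = nx.barabasi_albert_graph(n_nodes, 2, seed=seed)
    else:
        raise ValueError(f"unknown network kind {kind!r}; use one of {NETWORK_KINDS}")
    mapping = {i: f"G{i:04d}" for i in g.nodes}
    return GeneNetwork(nx.relabel_nodes(g, mapping))


def default_driver(net: GeneNetwork) -> str:
    """Pick a planted driver: a node of maximum eccentricity (ties broken by
    higher degree, then lexicographically).

    A peripheral center keeps the geometry of the planted decay meaningful:
    its distance shells grow gradually, so the signal region d <= cutoff is a
    proper subgraph rather than the whole network — the situation the method
    is designed for, where a gene's extent of influence is localized.  A hub
    center would put most of the graph within distance 2 and collapse the
    radius scan.
    """
    ecc = nx.eccentricity(net.graph)
    return sorted(net.nodes, key=lambda g: (-ecc[g], -net.degree(g), g))[0]


def make_study(
    net: GeneNetwork,
    truth: SyntheticTruth,
    assayed_fraction: float = 0.75,
) -> tuple[ExpressionStudy, GeneNetwork]:
    """Generate a two-class expression study with the planted driver.

    Returns the study (rows = assayed genes only) and the network with its
    assayed mask set.  Class labels are "low" / "high"; the shift is added
    to the "high" class.  Deterministic for a given ``truth.seed``.
    """
    if truth.driver not in net.nodes:
        raise ValueError(f"driver {truth.driver!r} is not on the network")
    if not 0 < assayed_fraction <= 1:
        raise ValueError("assayed_fraction must be in (0, 1]")
    rng = np.random.default_rng(truth.seed)
    nodes = sorted(net.nodes)
    n_nodes = len(nodes)
    n = 2 * truth.n_per_class
    labels = np.array(["low"] * truth.n_per_class + ["high"] * truth.n_per_class)
    c = (labels == "high").astype(float)

    oracle = geodesic_distances(net)
    d_from_driver = {g: oracle.distance(truth.driver, g) for g in nodes}

    z = rng.standard_normal(n)
    x = np.empty((n_nodes, n))
    for k, g in enumerate(nodes):
        d = d_from_driver[g]
        noise = rng.standard_normal(n) * truth.noise_sd
        if d == 0:
            x[k] = z + truth.shift(0) * c + noise
        elif d <= truth.cutoff:
            x[k] = truth.loading(d) * z + truth.shift(d) * c + noise
        else:
            x[k] = noise

    n_assayed = max(1, round(assayed_fraction * n_nodes))
    others = [g for g in nodes if g != truth.driver]
    chosen = list(rng.choice(others, size=n_assayed - 1, replace=False))
    assayed = sorted([truth.driver] + chosen)

    samples = [f"S{j:04d}" for j in range(n)]
    values = pd.DataFrame(x, index=nodes, columns=samples).loc[assayed]
    study = ExpressionStudy(values, pd.Series(labels, index=samples))
    return study, net.with_assayed(assayed)


def make_null_study(
    net: GeneNetwork,
    n_per_class: int = 20,
    sd: float = 1.0,
    seed: int = 0,
    assayed_fraction: float = 1.0,
) -> tuple[ExpressionStudy, GeneNetwork]:
    """All-noise study: every gene i.i.d. N(0, sd^2), labels uninformative.

    Used for type-I-error calibration of the per-radius and combined tests.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes)
    n = 2 * n_per_class
    n_assayed = max(1, round(assayed_fraction * len(nodes)))
    assayed = sorted(rng.choice(nodes, size=n_assayed, replace=False))
    samples = [f"S{j:04d}" for j in range(n)]
    labels = np.array(["low"] * n_per_class + ["high"] * n_per_class)
    x = rng.standard_normal((n_assayed, n)) * sd
    study = ExpressionStudy(
        pd.DataFrame(x, index=assayed, columns=samples),
        pd.Series(labels, index=samples),
    )
    return study, net.with_assayed(assayed)


def mask_missing(study: ExpressionStudy, rate: float, seed: int = 0) -> ExpressionStudy:
    """Uniform random masking: set a fraction ``rate`` of cells to NaN."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    vals = study.values.to_numpy(float).copy()
    mask = rng.random(vals.shape) < rate
    vals[mask] = np.nan
    return ExpressionStudy(
        pd.DataFrame(vals, index=study.genes, columns=study.samples),
        study.phenotype,
    )


def write_truth(truth: SyntheticTruth, path) -> None:
    """Write the planted truth as a two-column key/value TSV sidecar."""
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        for k, v in asdict(truth).items():
            fh.write(f"{k}\t{v}\n")


def read_truth(path) -> SyntheticTruth:
    """Re-read a truth sidecar written by :func:`write_truth`."""
    tab = pd.read_csv(path, sep="\t", index_col=0)["value"]
    return SyntheticTruth(
        driver=str(tab["driver"]),
        lambda0=float(tab["lambda0"]),
        gamma=float(tab["gamma"]),
        delta0=float(tab["delta0"]),
        gamma_de=float(tab["gamma_de"]),
        noise_sd=float(tab["noise_sd"]),
        cutoff=int(tab["cutoff"]),
        n_per_class=int(tab["n_per_class"]),
        seed=int(tab["seed"]),
    )
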