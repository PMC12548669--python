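"""Outlier-attack stability protocol and distance measures.

A network's stability is probed by transplanting rows from the other
diagnostic groups into the group table that produced it (an *outlier attack*:
cross-group metabolic patterns differ subtly in absolute value, so these rows
are realistic spurious data points that outlier screening would miss), then
recomputing the network and measuring how far it moved.  Four distances are
reported per attack:

* ``dF`` — Frobenius norm of the weight-matrix difference;
* ``dH`` — Hausdorff distance between the two matrices viewed as sets of row
  vectors (max over rows of the distance to the nearest row of the other
  matrix, symmetrized);
* ``dE`` / ``dC`` — Euclidean / Canberra distance between the 6-component
  graph-feature vectors f = [ge, ac, ad, as, d, acc] (global efficiency,
  assortativity, average degree, average strength, density, average
  clustering).

Lower values mean higher stability; all four are zero for an unperturbed
network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import canberra, cdist, euclidean

from ._seeds import child_seed, rng_for
from .construction import (
    apply_pmap_threshold,
    build_ensemble,
    compute_pmap,
    conventional_mbn,
    fdr_correct,
    pearson_adjacency,
    select_representative_index,
)
from .datasets import SUVRDataset, WeightedNetwork
from .synthetic import append_rows, select_outliers

__all__ = [
    "GraphFeatures",
    "AttackConfig",
    "StabilityReport",
    "attack_dataset",
    "outlier_count",
    "perturbed_network",
    "graph_features",
    "matrix_distance",
    "feature_distance",
    "run_attack_experiment",
    "size_sweep",
]

METHODS = ("conventional", "ms_bootstrap", "ms_subsample")
METRICS = ("dF", "dH", "dE", "dC")


# ---------------------------------------------------------------------------
# graph features
# ---------------------------------------------------------------------------


@dataclass
class GraphFeatures:
    """The six graph-theoretic summaries used for feature-space stability."""

    global_efficiency: float
    assortativity: float
    avg_degree: float
    avg_strength: float
    density: float
    avg_clustering: float
    assortativity_defined: bool = True

    @property
    def vector(self) -> np.ndarray:
        """Canonical ordering f = [ge, ac, ad, as, d, acc]."""
        return np.array(
            [
                self.global_efficiency,
                self.assortativity,
                self.avg_degree,
                self.avg_strength,
                self.density,
                self.avg_clustering,
            ]
        )


def _weights_of(net) -> np.ndarray:
    return net.weights if isinstance(net, WeightedNetwork) else np.asarray(net, float)


def graph_features(net: WeightedNetwork) -> GraphFeatures:
    """Compute f = [ge, ac, ad, as, d, acc] for a symmetric weighted network.

    Global efficiency uses shortest paths on edge lengths 1/|w| (signed
    weights enter through their magnitude); degree, clustering and
    assortativity are computed on the binarized nonzero-edge graph; strength
    sums |w| per node.  An undefined assortativity (no degree variance, e.g.
    empty or regular graphs) is reported as 0 with
    ``assortativity_defined=False`` and a warning.
    """
    W = _weights_of(net)
    d = W.shape[0]
    if d < 2:
        raise ValueError("graph features need at least 2 nodes")
    A = W != 0
    np.fill_diagonal(A, False)
    degrees = A.sum(axis=0)
    n_edges = degrees.sum() / 2
    density = n_edges / (d * (d - 1) / 2)
    avg_degree = degrees.mean()
    avg_strength = np.abs(W).sum(axis=0).mean()

    if n_edges:
        lengths = np.zeros_like(W)
        lengths[A] = 1.0 / np.abs(W[A])
        D = shortest_path(csr_matrix(lengths), method="D", directed=False)
        with np.errstate(divide="ignore"):
            inv = 1.0 / D
        np.fill_diagonal(inv, 0.0)
        inv[np.isinf(D)] = 0.0
        ge = inv.sum() / (d * (d - 1))
    else:
        ge = 0.0

    G = nx.from_numpy_array(A.astype(int))
    acc = nx.average_clustering(G) if n_edges else 0.0

    ac, ac_defined = 0.0, False
    if n_edges:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                ac = nx.degree_assortativity_coefficient(G)
            except Exception:
                ac = np.nan
        if np.isfinite(ac):
            ac_defined = True
        else:
            ac = 0.0
    if not ac_defined:
        warnings.warn(
            "degree assortativity undefined (no degree variance); reported as 0",
            RuntimeWarning,
        )
    return GraphFeatures(
        global_efficiency=float(ge),
        assortativity=float(ac),
        avg_degree=float(avg_degree),
        avg_strength=float(avg_strength),
        density=float(density),
        avg_clustering=float(acc),
        assortativity_defined=ac_defined,
    )


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def matrix_distance(M, M_tilde, metric: str = "frobenius") -> float:
    """Distance between two adjacency matrices.

    ``frobenius``: entrywise 2-norm of the difference.  ``hausdorff``: the
    matrices are read as collections of row vectors m_1..m_d; the directional
    distance h(M, M~) = max_i min_j ||m_i - m~_j||_2 is symmetrized by taking
    the larger direction.  Hausdorff is zero iff the two row sets coincide,
    so it ignores row (node) reordering.
    """
    A, B = _weights_of(M), _weights_of(M_tilde)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    if metric == "frobenius":
        return float(np.linalg.norm(A - B, "fro"))
    if metric == "hausdorff":
        D = cdist(A, B)
        h_ab = D.min(axis=1).max()
        h_ba = D.min(axis=0).max()
        return float(max(h_ab, h_ba))
    raise ValueError(f"unknown matrix metric {metric!r}")


def feature_distance(f, f_tilde, metric: str = "euclidean") -> float:
    """Distance between two graph-feature vectors (Euclidean or Canberra).

    Canberra terms sum |f_i - f~_i| / (|f_i| + |f~_i|); coordinates where
    both entries are zero contribute nothing.
    """
    a = f.vector if isinstance(f, GraphFeatures) else np.asarray(f, float)
    b = f_tilde.vector if isinstance(f_tilde, GraphFeatures) else np.asarray(
        f_tilde, float
    )
    if a.shape != b.shape:
        raise ValueError("feature vectors must have equal length")
    if metric == "euclidean":
        return float(euclidean(a, b))
    if metric == "canberra":
        return float(canberra(a, b))
    raise ValueError(f"unknown feature metric {metric!r}")


# ---------------------------------------------------------------------------
# attacks
# ---------------------------------------------------------------------------


def outlier_count(n_subjects: int, p_o: float) -> int:
    """Outliers implied by a percentage: L = round(p_o/100 * N), at least 1
    whenever p_o > 0."""
    if p_o < 0 or p_o >= 100:
        raise ValueError("outlier percentage must lie in [0, 100)")
    if p_o == 0:
        return 0
    return max(1, round(p_o / 100 * n_subjects))


def attack_dataset(
    target: SUVRDataset,
    donor_a: SUVRDataset,
    donor_b: SUVRDataset,
    p_o: float,
    rng: np.random.Generator,
) -> SUVRDataset:
    """One outlier attack: append L = round(p_o/100 * N) donor rows to the
    target table, split half/half across the two donor groups (odd L resolved
    by a seeded draw)."""
    L = outlier_count(target.n_subjects, p_o)
    return append_rows(target, select_outliers([donor_a, donor_b], L, rng))


def perturbed_network(
    source: SUVRDataset,
    outliers: Sequence[tuple[SUVRDataset, int]],
    alpha: float,
) -> WeightedNetwork:
    """Recompute a network after appending outlier rows to its source table
    (Pearson + FDR at the same alpha; no resampling, no new ensemble)."""
    return fdr_correct(pearson_adjacency(append_rows(source, outliers)), alpha)


@dataclass
class AttackConfig:
    """Settings of one attack experiment."""

    p_o: float = 2.0
    q_attacks: int = 256
    method: str = "ms_bootstrap"
    ns: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_o < 100):
            raise ValueError("p_o must lie in [0, 100)")
        if self.q_attacks < 1:
            raise ValueError("q_attacks must be >= 1")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.ns is not None and self.ns < 3:
            raise ValueError("ns must be >= 3")


@dataclass
class StabilityReport:
    """Per-attack distances plus the configuration that produced them."""

    records: pd.DataFrame
    config: AttackConfig
    target: str
    alpha: float
    n_samples: int
    criterion: str
    apply_pmap: bool

    def summary(self) -> pd.DataFrame:
        """Mean and standard deviation of each distance over attacks."""
        return self.records[list(METRICS)].agg(["mean", "std"])

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def run_attack_experiment(
    groups: Mapping[str, SUVRDataset],
    target: str,
    donors: Sequence[str],
    config: AttackConfig,
    alpha: float = 0.01,
    n_samples: int = 500,
    criterion: str = "mean",
    subsample_fraction: float = 0.8,
    apply_pmap: bool = True,
) -> StabilityReport:
    """Build the unperturbed group network once, then run ``q_attacks``
    independent outlier attacks against it.

    For the MS methods the representative's own source sample Y^q receives
    the outliers and only Pearson + FDR is recomputed; when ``apply_pmap`` is
    set, the probability-map mask derived from the *unperturbed* ensemble is
    applied to both the representative and every perturbed network, so the
    comparison is between the same network object before and after the
    attack.  For the conventional method the same outlier rows are appended
    to the full table X.  Outlier draws depend only on (seed, attack index),
    so runs that differ only in ``method`` see identical outlier rows —
    matched perturbation pairs.

    ``config.ns`` optionally subsamples the target group to a fixed size
    before anything else (size-sweep experiments).
    """
    for label in (target, *donors):
        if label not in groups:
            raise ValueError(f"group {label!r} missing from input")
    if len(donors) != 2:
        raise ValueError("exactly two donor groups are required")
    X = groups[target]
    if config.ns is not None:
        if config.ns > X.n_subjects:
            raise ValueError("ns exceeds the target group size")
        keep = rng_for(config.seed, "ns-subset").choice(
            X.n_subjects, size=config.ns, replace=False
        )
        X = X.subset(np.sort(keep))
    donor_sets = [groups[d] for d in donors]

    mode = {"ms_bootstrap": "bootstrap", "ms_subsample": "subsample"}.get(config.method)
    if config.method == "conventional":
        base = X
        net0 = conventional_mbn(X, alpha)
        pmap = None
    else:
        ens = build_ensemble(
            X,
            n=n_samples,
            alpha=alpha,
            mode=mode,
            fraction=subsample_fraction,
            seed=child_seed(config.seed, "ensemble-build"),
        )
        idx = select_representative_index(ens, criterion)
        base = ens.materialize_sample(X, idx)
        rep = ens.networks[idx]
        pmap = compute_pmap(ens)
        net0 = (
            apply_pmap_threshold(rep, pmap, 1 - alpha) if apply_pmap else rep
        )

    f0 = _quiet_features(net0)
    L = outlier_count(base.n_subjects, config.p_o)
    rows = []
    for q in range(config.q_attacks):
        rng = rng_for(config.seed, "attack", q)
        picks = select_outliers(donor_sets, L, rng)
        net_q = perturbed_network(base, picks, alpha)
        if config.method != "conventional" and apply_pmap:
            net_q = apply_pmap_threshold(net_q, pmap, 1 - alpha)
        f_q = _quiet_features(net_q)
        rows.append(
            {
                "attack": q,
                "dF": matrix_distance(net0, net_q, "frobenius"),
                "dH": matrix_distance(net0, net_q, "hausdorff"),
                "dE": feature_distance(f0, f_q, "euclidean"),
                "dC": feature_distance(f0, f_q, "canberra"),
                # provenance of the transplanted rows, so matched attacks can
                # be verified across construction methods
                "outliers": ";".join(
                    f"{donor.group}|{donor.subject_ids[i]}" for donor, i in picks
                ),
            }
        )
    return StabilityReport(
        records=pd.DataFrame(rows),
        config=config,
        target=target,
        alpha=alpha,
        n_samples=n_samples,
        criterion=criterion,
        apply_pmap=apply_pmap,
    )


def _quiet_features(net: WeightedNetwork) -> GraphFeatures:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return graph_features(net)


def size_sweep(
    groups: Mapping[str, SUVRDataset],
    target: str,
    donors: Sequence[str],
    ns_grid: Sequence[int],
    config: AttackConfig,
    **kwargs,
) -> pd.DataFrame:
    """Mean attack distances as a function of the target-group size.

    Reruns :func:`run_attack_experiment` for each size in ``ns_grid``
    (default grid in the field protocol: 10, 15, ..., 200) and returns one
    row per (ns, method) with the per-metric means.
    """
    from dataclasses import replace

    rows = []
    for ns in ns_grid:
        rep = run_attack_experiment(
            groups, target, donors, replace(config, ns=int(ns)), **kwargs
        )
        means = rep.records[list(METRICS)].mean()
        rows.append({"ns": int(ns), "method": config.method, **means.to_dict()})
    return pd.DataFrame(rows)
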