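"""Ensemble-size selection by Bhattacharyya-distance convergence.

The multiple-sampling scheme has one free parameter: the number of resampled
networks ``n``.  As ``n`` grows, the ensemble's degree distribution
stabilizes, so the Bhattacharyya distance (dB) between the degree
distributions of ensembles built at ``n = k`` and ``n = k + step`` decays
towards zero.  ``tune_n`` walks a grid of ``k`` values, records this dB
trace, and returns the ``k`` with the smallest dB (ties to the smallest
``k``).

Histograms: degree distributions share integer bins 0..d-1 so traces are
comparable across runs; weight distributions use 100 equal bins on [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .construction import build_ensemble, select_representative
from .datasets import SUVRDataset, WeightedNetwork

__all__ = [
    "DistributionHistogram",
    "ensemble_degree_distribution",
    "degree_distribution",
    "weight_distribution",
    "bhattacharyya_distance",
    "TuningResult",
    "tune_n",
    "DEFAULT_K_GRID",
]

#: dB values for histograms with disjoint support are capped here (-log of
#: the smallest positive double is ~708) so traces stay finite and plottable.
DB_CAP = 700.0

DEFAULT_K_GRID = tuple(range(100, 10000, 100))
WEIGHT_BINS = 100


@dataclass
class DistributionHistogram:
    """A normalized histogram (degree or weight distribution)."""

    bin_edges: np.ndarray
    probabilities: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.bin_edges) != len(self.probabilities) + 1:
            raise ValueError("need one more bin edge than probability")
        if (self.probabilities < 0).any():
            raise ValueError("probabilities must be non-negative")
        if abs(self.probabilities.sum() - 1) > 1e-12:
            raise ValueError("probabilities must sum to 1")
        if self.kind == "weight" and len(self.probabilities) != WEIGHT_BINS:
            raise ValueError(f"weight histograms use exactly {WEIGHT_BINS} bins")


def degree_distribution(net: WeightedNetwork) -> DistributionHistogram:
    """Normalized histogram of binary node degrees over bins 0..d-1."""
    d = net.n_nodes
    degrees = net.edge_mask().sum(axis=0)
    counts = np.bincount(degrees, minlength=d)[:d]
    return DistributionHistogram(
        bin_edges=np.arange(d + 1) - 0.5,
        probabilities=counts / counts.sum(),
        kind="degree",
    )


def weight_distribution(net: WeightedNetwork) -> DistributionHistogram:
    """Normalized 100-bin histogram on [-1, 1] of surviving edge weights
    (upper triangle, nonzero only)."""
    iu = np.triu_indices(net.n_nodes, k=1)
    w = net.weights[iu]
    w = w[w != 0]
    if w.size == 0:
        raise ValueError("network has no surviving edges; weight distribution empty")
    counts, edges = np.histogram(w, bins=WEIGHT_BINS, range=(-1, 1))
    return DistributionHistogram(
        bin_edges=edges, probabilities=counts / counts.sum(), kind="weight"
    )


def bhattacharyya_distance(
    p: DistributionHistogram, q: DistributionHistogram
) -> float:
    """dB = -ln sum_i sqrt(p_i q_i); zero iff the histograms coincide,
    capped at ``DB_CAP`` for disjoint supports."""
    if len(p.probabilities) != len(q.probabilities) or not np.allclose(
        p.bin_edges, q.bin_edges
    ):
        raise ValueError("histograms must share binning")
    bc = np.sqrt(p.probabilities * q.probabilities).sum()
    if bc <= 0:
        return DB_CAP
    return float(min(-np.log(min(bc, 1.0)), DB_CAP))


@dataclass
class TuningResult:
    """Selected ensemble size and the full dB-versus-k trace."""

    selected_n: int
    trace: pd.DataFrame  # columns: k, db


def ensemble_degree_distribution(ens) -> DistributionHistogram:
    """Degree distribution pooled over every network of an ensemble (one
    degree observation per node per member), on shared bins 0..d-1."""
    d = ens.n_nodes
    degrees = np.concatenate(
        [(net.weights != 0).sum(axis=0) for net in ens.networks]
    )
    counts = np.bincount(degrees, minlength=d)[:d]
    return DistributionHistogram(
        bin_edges=np.arange(d + 1) - 0.5,
        probabilities=counts / counts.sum(),
        kind="degree",
    )


def tune_n(
    X: SUVRDataset,
    k_grid: Sequence[int] | None = None,
    alpha: float = 0.0001,
    criterion: str = "mean",
    seed: int = 0,
    step: int = 100,
    mode: str = "bootstrap",
    fraction: float = 0.8,
    distribution: str = "pooled",
) -> TuningResult:
    """Select the ensemble size by degree-distribution convergence.

    For each ``k`` in the grid, ensembles are built at ``n = k`` and
    ``n = k + step`` (fresh child seeds of ``seed``) and the Bhattacharyya
    distance between their degree distributions is recorded; the returned
    ``selected_n`` is the ``k`` minimizing dB (ties to the smallest ``k``).

    ``distribution`` picks what "the ensemble's degree distribution" means:
    ``pooled`` (default) pools node degrees over every member, which
    converges at the ensemble's own Monte-Carlo rate and yields the
    asymptotic dB decay the convergence criterion relies on;
    ``representative`` uses only the selected representative network, whose
    fluctuations shrink far more slowly with ``n``.
    """
    if k_grid is None:
        k_grid = DEFAULT_K_GRID
    k_grid = [int(k) for k in k_grid]
    if not k_grid:
        raise ValueError("k_grid must not be empty")
    if sorted(k_grid) != k_grid:
        raise ValueError("k_grid must be ascending")
    if distribution not in ("pooled", "representative"):
        raise ValueError(f"unknown distribution kind {distribution!r}")
    rows = []
    for k in k_grid:
        dists = []
        for which, n in enumerate((k, k + step)):
            ens = build_ensemble(
                X,
                n=n,
                alpha=alpha,
                mode=mode,
                fraction=fraction,
                seed=child_seed(seed, "tune", k, which),
            )
            if distribution == "pooled":
                dists.append(ensemble_degree_distribution(ens))
            else:
                dists.append(
                    degree_distribution(select_representative(ens, criterion))
                )
        rows.append({"k": k, "db": bhattacharyya_distance(*dists)})
    trace = pd.DataFrame(rows)
    selected = int(trace.loc[trace["db"].idxmin(), "k"])
    return TuningResult(selected_n=selected, trace=trace)
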