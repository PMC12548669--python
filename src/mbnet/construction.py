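"""Metabolic brain network construction.

Two routes to a group network:

* **conventional** — one Pearson intersubject correlation matrix on the full
  group table, corrected for multiple comparisons with Benjamini–Hochberg
  FDR;
* **multiple sampling (MS)** — ``n`` resampled datasets (bootstrap draws of
  size N, or subsamples without replacement), one FDR-corrected network per
  draw, a *representative* member selected from the ensemble (closest to the
  elementwise mean or median matrix, or the maximum-density member), and an
  optional second, occurrence-based threshold: the probability map (Pmap)
  records for every edge the fraction of ensemble networks in which it
  survived FDR, and only edges with occurrence strictly above
  ``theta = 1 - alpha`` are retained (Hadamard mask on the representative).

Edge weights are signed correlations in [-1, 1]; p-values come from the exact
t-transform of Pearson's r with N - 2 degrees of freedom (two-sided).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from ._seeds import rng_for
from .datasets import SUVRDataset, WeightedNetwork

__all__ = [
    "NetworkEnsemble",
    "ProbabilityMap",
    "MSResult",
    "pearson_adjacency",
    "fdr_correct",
    "build_ensemble",
    "select_representative",
    "select_representative_index",
    "compute_pmap",
    "apply_pmap_threshold",
    "conventional_mbn",
    "ms_network",
    "residualize_covariates",
]

CRITERIA = ("mean", "median", "mode")
SAMPLING_MODES = ("bootstrap", "subsample")


# ---------------------------------------------------------------------------
# single-network primitives
# ---------------------------------------------------------------------------


def pearson_adjacency(dataset: SUVRDataset) -> WeightedNetwork:
    """All-pairs Pearson correlation network of one dataset.

    Requires N >= 3 subjects (otherwise the p-value is undefined) and no
    zero-variance column.  The diagonal is set to zero: self-correlations are
    not edges.
    """
    X = dataset.values
    n, d = X.shape
    if n < 3:
        raise ValueError("need at least 3 subjects for correlation p-values")
    sd = X.std(axis=0)
    if (sd == 0).any():
        voi = dataset.voi_names[int(np.argmax(sd == 0))]
        raise ValueError(f"zero-variance column for VOI {voi!r}")
    r = np.corrcoef(X, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    r = (r + r.T) / 2  # exact symmetry against float noise
    with np.errstate(divide="ignore"):
        t = np.abs(r) * np.sqrt((n - 2) / np.maximum(1 - r * r, 0))
    p = 2 * stats.t.sf(t, df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    np.fill_diagonal(p, 1.0)
    p = (p + p.T) / 2
    return WeightedNetwork(weights=r, pvalues=p, voi_names=list(dataset.voi_names))


def fdr_correct(net: WeightedNetwork, alpha: float) -> WeightedNetwork:
    """Benjamini–Hochberg correction over the d(d-1)/2 upper-triangle edge
    p-values; weights of non-surviving edges are zeroed."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    d = net.n_nodes
    iu = np.triu_indices(d, k=1)
    reject, _, _, _ = multipletests(net.pvalues[iu], alpha=alpha, method="fdr_bh")
    keep = np.zeros((d, d), dtype=bool)
    keep[iu] = reject
    keep |= keep.T
    weights = np.where(keep, net.weights, 0.0)
    return WeightedNetwork(
        weights=weights,
        pvalues=net.pvalues,
        voi_names=list(net.voi_names),
        alpha_applied=alpha,
        theta_applied=net.theta_applied,
    )


def conventional_mbn(dataset: SUVRDataset, alpha: float) -> WeightedNetwork:
    """Single-pass network: Pearson adjacency on the full table + FDR."""
    return fdr_correct(pearson_adjacency(dataset), alpha)


def residualize_covariates(dataset: SUVRDataset) -> SUVRDataset:
    """Regress each VOI column on the covariates (plus intercept) and keep
    the residuals, with the column mean added back so the SUVR scale — and
    positivity — is preserved."""
    if dataset.covariates is None:
        raise ValueError("dataset has no covariates to residualize")
    n = dataset.n_subjects
    design = np.column_stack([np.ones(n), dataset.covariates])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(design, dataset.values, rcond=None)
    resid = dataset.values - design @ beta
    values = resid + dataset.values.mean(axis=0)
    return SUVRDataset(
        values=values,
        subject_ids=list(dataset.subject_ids),
        voi_names=list(dataset.voi_names),
        group=dataset.group,
        covariates=dataset.covariates.copy(),
        covariate_names=list(dataset.covariate_names),
    )


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------


@dataclass
class NetworkEnsemble:
    """Ordered collection of FDR-corrected resampled networks plus the row
    indices of the draw that produced each one."""

    networks: list[WeightedNetwork]
    sample_indices: list[np.ndarray]
    sampling_mode: str
    subsample_fraction: float
    alpha: float
    seed: int

    def __post_init__(self) -> None:
        if not self.networks:
            raise ValueError("ensemble must contain at least one network")
        if len(self.networks) != len(self.sample_indices):
            raise ValueError("one index list per network required")
        names = self.networks[0].voi_names
        if any(net.voi_names != names for net in self.networks):
            raise ValueError("all ensemble networks must share VOI names")

    def __len__(self) -> int:
        return len(self.networks)

    @property
    def voi_names(self) -> list[str]:
        return self.networks[0].voi_names

    @property
    def n_nodes(self) -> int:
        return self.networks[0].n_nodes

    def weights_stack(self) -> np.ndarray:
        """n x d x d array of ensemble weights."""
        return np.stack([net.weights for net in self.networks])

    def mean_matrix(self) -> np.ndarray:
        return self.weights_stack().mean(axis=0)

    def median_matrix(self) -> np.ndarray:
        return np.median(self.weights_stack(), axis=0)

    def materialize_sample(self, X: SUVRDataset, k: int) -> SUVRDataset:
        """The dataset Y^k that produced ensemble member ``k``."""
        return X.subset(self.sample_indices[k])


def build_ensemble(
    X: SUVRDataset,
    n: int,
    alpha: float,
    mode: str = "bootstrap",
    fraction: float = 0.8,
    seed: int = 0,
    max_redraws: int = 100,
) -> NetworkEnsemble:
    """Build ``n`` resampled FDR-corrected networks from one group table.

    Bootstrap draws have size N with replacement ("duplicate rows of the
    original dataset"); subsample draws take ``round(fraction * N)`` rows
    without replacement.  A draw whose materialized table has a zero-variance
    column (possible only for tiny N) is redrawn up to ``max_redraws`` times
    so the ensemble size is preserved without biasing typical draws.
    """
    if n < 1:
        raise ValueError("ensemble size n must be >= 1")
    if mode not in SAMPLING_MODES:
        raise ValueError(f"unknown sampling mode {mode!r}")
    if mode == "subsample":
        if not (0 < fraction < 1):
            raise ValueError("subsample fraction must lie in (0, 1)")
        size = max(3, round(fraction * X.n_subjects))
    else:
        size = X.n_subjects
    if (X.values.std(axis=0) == 0).any():
        voi = X.voi_names[int(np.argmax(X.values.std(axis=0) == 0))]
        raise ValueError(f"zero-variance column for VOI {voi!r} in input dataset")
    rng = rng_for(seed, "ensemble")
    networks: list[WeightedNetwork] = []
    indices: list[np.ndarray] = []
    redraws = 0
    for _ in range(n):
        for attempt in range(max_redraws + 1):
            if mode == "bootstrap":
                idx = rng.integers(0, X.n_subjects, size=X.n_subjects)
            else:
                idx = rng.choice(X.n_subjects, size=size, replace=False)
            sample = X.values[idx]
            if (sample.std(axis=0) > 0).all():
                break
            redraws += 1
        else:
            raise ValueError(
                f"could not draw a non-degenerate sample in {max_redraws} tries"
            )
        net = fdr_correct(pearson_adjacency(X.subset(idx)), alpha)
        networks.append(net)
        indices.append(np.asarray(idx))
    if redraws:
        warnings.warn(f"{redraws} degenerate draws were redrawn", RuntimeWarning)
    return NetworkEnsemble(
        networks=networks,
        sample_indices=indices,
        sampling_mode=mode,
        subsample_fraction=fraction if mode == "subsample" else 1.0,
        alpha=alpha,
        seed=seed,
    )


def select_representative_index(ens: NetworkEnsemble, criterion: str = "mean") -> int:
    """Index of the representative ensemble member.

    ``mean`` / ``median``: the member with the smallest Frobenius distance to
    the elementwise mean / median matrix.  ``mode``: the member of maximum
    estimated density in matrix space, where density is scored as the
    (negative) mean Frobenius distance to the ceil(sqrt(n)) nearest other
    members — a k-NN surrogate for the mode of the network distribution.
    Ties break to the lowest index.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; choose from {CRITERIA}")
    stack = ens.weights_stack()
    flat = stack.reshape(len(ens), -1)
    if criterion in ("mean", "median"):
        center = ens.mean_matrix() if criterion == "mean" else ens.median_matrix()
        dists = np.linalg.norm(flat - center.ravel(), axis=1)
        return int(np.argmin(dists))
    if len(ens) == 1:
        return 0
    pair = squareform(pdist(flat))
    k = min(int(np.ceil(np.sqrt(len(ens)))), len(ens) - 1)
    np.fill_diagonal(pair, np.inf)
    knn_mean = np.sort(pair, axis=1)[:, :k].mean(axis=1)
    return int(np.argmin(knn_mean))


def select_representative(
    ens: NetworkEnsemble, criterion: str = "mean"
) -> WeightedNetwork:
    """The representative network itself — always an ensemble *member*, never
    a synthetic average."""
    return ens.networks[select_representative_index(ens, criterion)]


# ---------------------------------------------------------------------------
# probability maps
# ---------------------------------------------------------------------------


@dataclass
class ProbabilityMap:
    """Per-edge occurrence frequencies across an ensemble: entry (p, q) is
    the fraction of FDR-corrected ensemble networks in which edge (p, q)
    survived.  Entries are exact counts over ``n``."""

    probs: np.ndarray
    n: int
    voi_names: list[str]
    theta: float | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        d = self.probs.shape[0]
        if self.probs.shape != (d, d):
            raise ValueError("probability map must be square")
        if not np.allclose(self.probs, self.probs.T):
            raise ValueError("probability map must be symmetric")
        if self.probs.min() < 0 or self.probs.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        counts = self.probs * self.n
        if not np.allclose(counts, np.round(counts), atol=1e-9):
            raise ValueError("entries must be integer counts over n")

    @property
    def n_nodes(self) -> int:
        return self.probs.shape[0]


def compute_pmap(ens: NetworkEnsemble) -> ProbabilityMap:
    """Edge-occurrence probability map of an ensemble."""
    occ = (ens.weights_stack() != 0).mean(axis=0)
    np.fill_diagonal(occ, 0.0)
    return ProbabilityMap(probs=occ, n=len(ens), voi_names=list(ens.voi_names))


def apply_pmap_threshold(
    net: WeightedNetwork, pmap: ProbabilityMap, theta: float
) -> WeightedNetwork:
    """Keep only edges whose occurrence probability is strictly above
    ``theta`` (Hadamard product with the binary threshold matrix).  With
    ``theta = 1 - alpha`` this is the second stage of the FDR + Pmap
    correction."""
    if net.n_nodes != pmap.n_nodes:
        raise ValueError(
            f"network has {net.n_nodes} nodes but pmap has {pmap.n_nodes}"
        )
    if not (0 <= theta <= 1):
        raise ValueError("theta must lie in [0, 1]")
    mask = pmap.probs > theta
    weights = np.where(mask, net.weights, 0.0)
    np.fill_diagonal(weights, 0.0)
    return WeightedNetwork(
        weights=weights,
        pvalues=net.pvalues,
        voi_names=list(net.voi_names),
        alpha_applied=net.alpha_applied,
        theta_applied=theta,
    )


# ---------------------------------------------------------------------------
# full MS pipeline
# ---------------------------------------------------------------------------


@dataclass
class MSResult:
    """Output of the full multiple-sampling construction."""

    network: WeightedNetwork
    ensemble: NetworkEnsemble
    pmap: ProbabilityMap
    representative_index: int
    criterion: str


def ms_network(
    X: SUVRDataset,
    n: int,
    alpha: float,
    criterion: str = "mean",
    mode: str = "bootstrap",
    fraction: float = 0.8,
    seed: int = 0,
    apply_pmap: bool = True,
) -> MSResult:
    """End-to-end MS construction: ensemble, representative selection,
    probability map, and (by default) the Pmap threshold at
    ``theta = 1 - alpha``."""
    ens = build_ensemble(X, n=n, alpha=alpha, mode=mode, fraction=fraction, seed=seed)
    idx = select_representative_index(ens, criterion)
    rep = ens.networks[idx]
    pmap = compute_pmap(ens)
    net = apply_pmap_threshold(rep, pmap, 1 - alpha) if apply_pmap else rep
    return MSResult(
        network=net,
        ensemble=ens,
        pmap=pmap,
        representative_index=idx,
        criterion=criterion,
    )
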