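"""Core containers and delimited-text I/O for SUVR tables and networks.

The two central objects are :class:`SUVRDataset` (a subjects x VOIs matrix of
standardized uptake value ratios for one diagnostic group) and
:class:`WeightedNetwork` (a symmetric VOI x VOI matrix of intersubject
correlation weights with a companion p-value matrix).  Everything downstream —
ensemble construction, probability maps, outlier attacks — consumes and
produces these types.

File formats are deliberately plain: CSV with a header row of VOI names and a
first column of subject identifiers for datasets; a labelled square CSV plus a
p-value CSV and a JSON metadata sidecar for networks.  ``read_*`` inverts
``write_*`` exactly (floats are written in shortest-repr form, which round
trips IEEE doubles losslessly).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SUVRDataset",
    "WeightedNetwork",
    "read_suvr_table",
    "write_suvr_table",
    "read_network",
    "write_network",
]


def _as_float_matrix(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D array, got shape {arr.shape}")
    return arr


@dataclass
class SUVRDataset:
    """One group's PET SUVR table: N subjects by d volumes of interest.

    SUVR values are dimensionless ratios (regional uptake over a reference
    region) and must be finite and strictly positive.  Optional per-subject
    covariates (e.g. age in years, sex coded 0/1) ride along for
    residualization.
    """

    values: np.ndarray
    subject_ids: list[str]
    voi_names: list[str]
    group: str
    covariates: np.ndarray | None = None
    covariate_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = _as_float_matrix(self.values, "values")
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.voi_names = [str(v) for v in self.voi_names]
        n, d = self.values.shape
        if n < 2 or d < 2:
            raise ValueError(f"need at least 2 subjects and 2 VOIs, got {n}x{d}")
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match number of rows")
        if len(self.voi_names) != d:
            raise ValueError("voi_names length does not match number of columns")
        if len(set(self.voi_names)) != d:
            raise ValueError("duplicate VOI names")
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject ids")
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite SUVR value at subject {self.subject_ids[i]!r}, "
                f"VOI {self.voi_names[j]!r}"
            )
        nonpos = self.values <= 0
        if nonpos.any():
            i, j = np.argwhere(nonpos)[0]
            raise ValueError(
                f"non-positive SUVR value at subject {self.subject_ids[i]!r}, "
                f"VOI {self.voi_names[j]!r}"
            )
        if self.covariates is not None:
            self.covariates = _as_float_matrix(self.covariates, "covariates")
            if self.covariates.shape[0] != n:
                raise ValueError("covariates row count does not match subjects")
            if not np.isfinite(self.covariates).all():
                raise ValueError("non-finite covariate value")
            if self.covariate_names is None:
                self.covariate_names = [
                    f"cov{k}" for k in range(self.covariates.shape[1])
                ]
            if len(self.covariate_names) != self.covariates.shape[1]:
                raise ValueError("covariate_names length mismatch")
            spans = self.covariates.max(axis=0) - self.covariates.min(axis=0)
            if (spans == 0).any():
                k = int(np.argmax(spans == 0))
                raise ValueError(
                    f"covariate {self.covariate_names[k]!r} is constant"
                )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_vois(self) -> int:
        return self.values.shape[1]

    def subset(self, indices: Sequence[int]) -> "SUVRDataset":
        """Row subset / resample.  Repeated indices get ``#k`` id suffixes so
        subject ids stay unique in bootstrap-materialized datasets."""
        indices = np.asarray(indices, dtype=int)
        seen: dict[str, int] = {}
        ids = []
        for i in indices:
            base = self.subject_ids[i]
            k = seen.get(base, 0)
            seen[base] = k + 1
            ids.append(base if k == 0 else f"{base}#{k}")
        cov = None if self.covariates is None else self.covariates[indices]
        return SUVRDataset(
            values=self.values[indices],
            subject_ids=ids,
            voi_names=list(self.voi_names),
            group=self.group,
            covariates=cov,
            covariate_names=None if cov is None else list(self.covariate_names),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.subject_ids, columns=self.voi_names)
        df.index.name = "subject_id"
        if self.covariates is not None:
            for k, name in enumerate(self.covariate_names):
                df[name] = self.covariates[:, k]
        return df


@dataclass
class WeightedNetwork:
    """Symmetric weighted adjacency of intersubject correlations.

    ``weights`` lies in [-1, 1] with a zero diagonal (self-correlations are
    not edges); ``pvalues`` holds the matching two-sided p-values.  After a
    multiple-comparisons correction, zeroed off-diagonal weights mark rejected
    edges and ``alpha_applied`` records the level used.  ``theta_applied``
    records a probability-map threshold when one was applied on top.
    """

    weights: np.ndarray
    pvalues: np.ndarray
    voi_names: list[str]
    alpha_applied: float | None = None
    theta_applied: float | None = None

    def __post_init__(self) -> None:
        self.weights = _as_float_matrix(self.weights, "weights")
        self.pvalues = _as_float_matrix(self.pvalues, "pvalues")
        self.voi_names = [str(v) for v in self.voi_names]
        d = self.weights.shape[0]
        if self.weights.shape != (d, d) or self.pvalues.shape != (d, d):
            raise ValueError("weights and pvalues must be square and congruent")
        if len(self.voi_names) != d:
            raise ValueError("voi_names length does not match matrix size")
        if len(set(self.voi_names)) != d:
            raise ValueError("duplicate VOI names")
        if not np.allclose(self.weights, self.weights.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if not np.allclose(self.pvalues, self.pvalues.T, atol=1e-12):
            raise ValueError("pvalues must be symmetric")
        if np.abs(np.diag(self.weights)).max(initial=0.0) != 0.0:
            raise ValueError("weights diagonal must be zero (no self-edges)")
        if np.abs(self.weights).max(initial=0.0) > 1 + 1e-9:
            raise ValueError("weights must lie in [-1, 1]")
        if self.pvalues.min(initial=0.0) < 0 or self.pvalues.max(initial=0.0) > 1:
            raise ValueError("pvalues must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def edge_mask(self) -> np.ndarray:
        """Boolean d x d matrix of surviving (nonzero, off-diagonal) edges."""
        mask = self.weights != 0
        np.fill_diagonal(mask, False)
        return mask

    def edge_set(self) -> set[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.edge_mask(), 1))
        return set(zip(i.tolist(), j.tolist()))

    def density(self) -> float:
        d = self.n_nodes
        return self.edge_mask().sum() / 2 / (d * (d - 1) / 2)

    def with_weights(self, weights: np.ndarray, **meta) -> "WeightedNetwork":
        return replace(self, weights=weights, **meta)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_suvr_table(
    path: str | Path,
    group: str,
    voi_list: str | Path | None = None,
    id_column: str = "subject_id",
    covariate_columns: Sequence[str] = (),
) -> SUVRDataset:
    """Read a subjects-by-VOIs CSV into a validated :class:`SUVRDataset`.

    The header row names the VOIs; ``id_column`` (first column by convention)
    holds subject identifiers; columns listed in ``covariate_columns`` are
    split off as covariates.  ``voi_list`` optionally restricts and orders the
    VOI columns (plain text, one name per line).  Missing or non-numeric cells
    are rejected with the offending cell named.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if id_column in df.columns:
        df = df.set_index(id_column)
    else:
        df.index = [f"s{i}" for i in range(len(df))]
    cov = None
    cov_names: list[str] | None = None
    covariate_columns = list(covariate_columns)
    if covariate_columns:
        missing = [c for c in covariate_columns if c not in df.columns]
        if missing:
            raise ValueError(f"covariate columns not found in {path}: {missing}")
        cov_df = df[covariate_columns]
        df = df.drop(columns=covariate_columns)
        cov = cov_df.to_numpy(dtype=float)
        cov_names = covariate_columns
    if voi_list is not None:
        wanted = [
            line.strip()
            for line in Path(voi_list).read_text().splitlines()
            if line.strip()
        ]
        missing = [v for v in wanted if v not in df.columns]
        if missing:
            raise ValueError(f"VOIs from {voi_list} not found in {path}: {missing}")
        df = df[wanted]
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"non-numeric cell at subject {row!r}, VOI {col!r} in {path}"
            )
        if numeric.isna().any():
            row = df.index[numeric.isna().to_numpy().argmax()]
            raise ValueError(
                f"missing SUVR value at subject {row!r}, VOI {col!r} in {path}"
            )
    return SUVRDataset(
        values=df.to_numpy(dtype=float),
        subject_ids=[str(i) for i in df.index],
        voi_names=[str(c) for c in df.columns],
        group=group,
        covariates=cov,
        covariate_names=cov_names,
    )


def write_suvr_table(dataset: SUVRDataset, path: str | Path) -> None:
    """Write a dataset as CSV (inverse of :func:`read_suvr_table`)."""
    dataset.to_frame().to_csv(Path(path))


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}.pvalues.csv"), Path(f"{stem}.meta.json")


def write_network(
    net: WeightedNetwork,
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write a network as a labelled square CSV plus p-value and metadata
    sidecars (``<stem>.pvalues.csv``, ``<stem>.meta.json``)."""
    path = Path(path)
    try:
        pd.DataFrame(net.weights, index=net.voi_names, columns=net.voi_names).to_csv(
            path
        )
        pval_path, meta_path = _sidecar_paths(path)
        pd.DataFrame(net.pvalues, index=net.voi_names, columns=net.voi_names).to_csv(
            pval_path
        )
        meta = {
            "n_nodes": net.n_nodes,
            "alpha": net.alpha_applied,
            "theta": net.theta_applied,
        }
        if metadata:
            meta.update(metadata)
        meta_path.write_text(json.dumps(meta, indent=2, default=str))
    except OSError as exc:
        raise OSError(f"failed writing network to {path}: {exc}") from exc


def read_network(path: str | Path) -> tuple[WeightedNetwork, dict]:
    """Read a network written by :func:`write_network`; returns the network
    and its metadata dict."""
    path = Path(path)
    wdf = pd.read_csv(path, index_col=0, float_precision="round_trip")
    pval_path, meta_path = _sidecar_paths(path)
    pdf = pd.read_csv(pval_path, index_col=0, float_precision="round_trip")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    net = WeightedNetwork(
        weights=wdf.to_numpy(dtype=float),
        pvalues=pdf.to_numpy(dtype=float),
        voi_names=[str(c) for c in wdf.columns],
        alpha_applied=meta.get("alpha"),
        theta_applied=meta.get("theta"),
    )
    return net, meta
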