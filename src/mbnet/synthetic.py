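"""Synthetic SUVR cohort generator and outlier transplantation.

Emulates group-structured FDG-PET SUVR tables so every stage of the pipeline
is testable without clinical data.  The generative family is a multivariate
normal with a block-constant correlation matrix: VOIs are partitioned into
modules (think lobes / functional communities) with within-block correlation
``rho_in`` and between-block correlation ``rho_out``.  Pearson-correlation
networks are exactly parameterized by this family, which is what makes
parameter-recovery tests possible.  Diagnostic groups share the correlation
structure and differ in per-block mean offsets (graded hypometabolism),
mirroring the observation that group metabolic patterns differ subtly in
absolute value — which is exactly what makes transplanted cross-group rows
realistic outliers.

SUVR positivity is obtained by adding a baseline level (default 1.2, a
plausible pons-referenced scale) rather than truncating, since truncation
would distort the correlations the tests recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._seeds import rng_for
from .datasets import SUVRDataset

__all__ = [
    "CohortSpec",
    "example_cohort_spec",
    "generate_cohort",
    "select_outliers",
    "append_rows",
    "inject_outliers",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic multi-group SUVR cohort.

    ``group_effects`` maps each group label to per-block mean offsets (same
    length as ``block_sizes``); groups absent from the mapping get zeros.
    The implied covariance is ``noise_sd**2 *`` the block-constant correlation
    matrix, which is positive definite whenever ``0 <= rho_out <= rho_in < 1``.
    """

    n_subjects: Mapping[str, int]
    d: int = 72
    block_sizes: tuple[int, ...] = (12, 12, 12, 12, 12, 12)
    rho_in: float = 0.75
    rho_out: float = 0.25
    group_effects: Mapping[str, Sequence[float]] = field(default_factory=dict)
    noise_sd: float = 0.12
    baseline: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_subjects:
            raise ValueError("n_subjects must name at least one group")
        for g, n in self.n_subjects.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs at least 2 subjects")
        if sum(self.block_sizes) != self.d:
            raise ValueError(
                f"block sizes {self.block_sizes} do not sum to d={self.d}"
            )
        if not (0 <= self.rho_out <= self.rho_in < 1):
            raise ValueError("require 0 <= rho_out <= rho_in < 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for g, eff in self.group_effects.items():
            if len(eff) != len(self.block_sizes):
                raise ValueError(
                    f"group_effects[{g!r}] must give one offset per block"
                )

    @property
    def block_labels(self) -> np.ndarray:
        """Block index of each VOI."""
        return np.repeat(np.arange(len(self.block_sizes)), self.block_sizes)

    def correlation_matrix(self) -> np.ndarray:
        """The target VOI x VOI correlation matrix."""
        lbl = self.block_labels
        same = lbl[:, None] == lbl[None, :]
        corr = np.where(same, self.rho_in, self.rho_out)
        np.fill_diagonal(corr, 1.0)
        return corr

    def group_means(self, group: str) -> np.ndarray:
        mean = np.full(self.d, self.baseline)
        eff = self.group_effects.get(group)
        if eff is not None:
            mean += np.repeat(np.asarray(eff, dtype=float), self.block_sizes)
        return mean

    def voi_names(self) -> list[str]:
        lbl = self.block_labels
        counters: dict[int, int] = {}
        names = []
        for b in lbl:
            counters[b] = counters.get(b, 0) + 1
            names.append(f"VOI_b{b + 1}_{counters[b]}")
        return names


def example_cohort_spec(
    n_subjects: Mapping[str, int] | None = None,
    d: int = 72,
    seed: int = 0,
    **overrides,
) -> CohortSpec:
    """A three-group cohort emulating an AD-continuum study.

    Defaults to the canonical imbalanced group sizes (CU 352 / MCI 641 /
    AD 234), six equal VOI blocks, and graded hypometabolism: MCI lowered by
    0.05 SUVR in the first two blocks, AD by 0.12 in the first three.
    ``d`` must be divisible by 6.
    """
    if n_subjects is None:
        n_subjects = {"CU": 352, "MCI": 641, "AD": 234}
    if d % 6 != 0:
        raise ValueError("example spec uses 6 equal blocks; d must be divisible by 6")
    b = d // 6
    effects = {
        "CU": (0.0,) * 6,
        "MCI": (-0.05, -0.05, 0.0, 0.0, 0.0, 0.0),
        "AD": (-0.12, -0.12, -0.12, 0.0, 0.0, 0.0),
    }
    params = dict(
        n_subjects=dict(n_subjects),
        d=d,
        block_sizes=(b,) * 6,
        group_effects={g: effects.get(g, (0.0,) * 6) for g in n_subjects},
        seed=seed,
    )
    params.update(overrides)
    return CohortSpec(**params)


def generate_cohort(spec: CohortSpec) -> dict[str, SUVRDataset]:
    """Draw one dataset per group; deterministic under ``spec.seed``."""
    cov = spec.noise_sd**2 * spec.correlation_matrix()
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by spec
        raise ValueError("implied covariance is not positive definite") from exc
    vois = spec.voi_names()
    out: dict[str, SUVRDataset] = {}
    for group in spec.n_subjects:
        # per-group child seed: a group's data does not depend on the sizes
        # or order of the other groups
        rng = rng_for(spec.seed, "cohort", group)
        n = spec.n_subjects[group]
        z = rng.standard_normal((n, spec.d))
        values = spec.group_means(group) + z @ chol.T
        out[group] = SUVRDataset(
            values=values,
            subject_ids=[f"{group}{i:04d}" for i in range(n)],
            voi_names=vois,
            group=group,
        )
    return out


def select_outliers(
    donors: Sequence[SUVRDataset], L: int, rng: np.random.Generator
) -> list[tuple[SUVRDataset, int]]:
    """Pick ``L`` donor rows, split as evenly as possible across donors.

    With two donor groups and even ``L`` the split is exactly half/half; an
    odd remainder goes to donors chosen by a seeded draw.  Rows are sampled
    without replacement within each donor.  Returns (donor, row) pairs.
    """
    if L < 0:
        raise ValueError("L must be non-negative")
    if not donors:
        raise ValueError("need at least one donor dataset")
    k = len(donors)
    alloc = np.full(k, L // k)
    rem = L - alloc.sum()
    if rem:
        for idx in rng.choice(k, size=rem, replace=False):
            alloc[idx] += 1
    picks: list[tuple[SUVRDataset, int]] = []
    for donor, count in zip(donors, alloc):
        if count > donor.n_subjects:
            raise ValueError(
                f"donor group {donor.group!r} has {donor.n_subjects} rows, "
                f"cannot supply {count} outliers"
            )
        for i in rng.choice(donor.n_subjects, size=count, replace=False):
            picks.append((donor, int(i)))
    return picks


def append_rows(
    target: SUVRDataset, picks: Sequence[tuple[SUVRDataset, int]]
) -> SUVRDataset:
    """Return ``target`` with the picked donor rows appended (inputs are
    never mutated).  Appended subject ids carry a ``<donor group>|`` prefix
    as a provenance tag."""
    if not picks:
        return target.subset(range(target.n_subjects))
    rows = np.vstack([donor.values[i] for donor, i in picks])
    ids = list(target.subject_ids)
    for donor, i in picks:
        base = f"{donor.group}|{donor.subject_ids[i]}"
        tag, k = base, 1
        while tag in ids:
            tag = f"{base}#{k}"
            k += 1
        ids.append(tag)
    cov = None
    cov_names = None
    if target.covariates is not None and all(
        donor.covariate_names == target.covariate_names for donor, _ in picks
    ):
        cov = np.vstack(
            [target.covariates] + [donor.covariates[i : i + 1] for donor, i in picks]
        )
        cov_names = list(target.covariate_names)
    return SUVRDataset(
        values=np.vstack([target.values, rows]),
        subject_ids=ids,
        voi_names=list(target.voi_names),
        group=target.group,
        covariates=cov,
        covariate_names=cov_names,
    )


def inject_outliers(
    target: SUVRDataset,
    donors: Sequence[SUVRDataset],
    L: int,
    rng: np.random.Generator,
) -> SUVRDataset:
    """Append ``L`` cross-group rows to ``target`` (the perturbed dataset has
    N + L rows).  See :func:`select_outliers` for the donor split rule."""
    return append_rows(target, select_outliers(donors, L, rng))
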