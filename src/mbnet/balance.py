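"""Group-size balancing: random undersampling and ADASYN oversampling.

Diagnostic cohorts are rarely balanced (MCI groups are typically the
largest), and intersubject-correlation p-values shrink with N, so group
networks built at unequal sizes are corrected at effectively different
stringencies.  Two standard remedies are provided: removing rows from the
larger groups until all match the smallest (undersampling), and growing the
smaller groups with adaptive synthetic rows until they approximate the
largest (ADASYN).

ADASYN is implemented from its published rule: each minority point x_i gets a
generation budget proportional to the fraction of out-of-group points among
its k nearest neighbours in the pooled data (hard-to-learn regions get more
synthetic mass), and each synthetic row is x_i + lambda * (x_z - x_i) with
lambda ~ U(0, 1) and x_z a random one of x_i's k nearest *within-group*
neighbours — so every synthetic row lies on a segment between two original
same-group rows.  Neighbour search is delegated to scikit-learn.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .datasets import SUVRDataset

__all__ = ["undersample_groups", "adasyn_oversample", "SYNTHETIC_PREFIX"]

SYNTHETIC_PREFIX = "syn|"


def undersample_groups(
    groups: Mapping[str, SUVRDataset], rng: np.random.Generator
) -> dict[str, SUVRDataset]:
    """Randomly drop rows (without replacement) from every group larger than
    the smallest, so all groups end up at the minimum size.  Groups already
    at the minimum are returned unchanged."""
    if len(groups) < 2:
        raise ValueError("need at least two groups to balance")
    sizes = {g: ds.n_subjects for g, ds in groups.items()}
    m = min(sizes.values())
    out: dict[str, SUVRDataset] = {}
    for g, ds in groups.items():
        if ds.n_subjects == m:
            out[g] = ds
        else:
            keep = np.sort(rng.choice(ds.n_subjects, size=m, replace=False))
            out[g] = ds.subset(keep)
    return out


def adasyn_oversample(
    groups: Mapping[str, SUVRDataset],
    k_neighbors: int = 5,
    rng: np.random.Generator | None = None,
) -> dict[str, SUVRDataset]:
    """Grow every minority group towards the majority size with ADASYN
    synthetic rows.

    Per-point budgets are apportioned by largest remainder, so each minority
    group reaches the majority size exactly.  Synthetic subject ids are
    flagged with the ``syn|`` prefix.  Groups whose size already equals the
    majority are returned unchanged.
    """
    if rng is None:
        rng = np.random.default_rng()
    if len(groups) < 2:
        raise ValueError("need at least two groups to balance")
    sizes = {g: ds.n_subjects for g, ds in groups.items()}
    n_max = max(sizes.values())
    pooled = np.vstack([ds.values for ds in groups.values()])
    labels = np.concatenate(
        [[g] * ds.n_subjects for g, ds in groups.items()]
    )
    nn_all = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(pooled)

    out: dict[str, SUVRDataset] = {}
    for g, ds in groups.items():
        deficit = n_max - ds.n_subjects
        if deficit == 0:
            out[g] = ds
            continue
        if ds.n_subjects <= k_neighbors:
            raise ValueError(
                f"group {g!r} has {ds.n_subjects} rows; ADASYN needs more than "
                f"k_neighbors={k_neighbors}"
            )
        # adaptive budgets: fraction of out-of-group points among the k
        # nearest pooled neighbours of each minority row
        _, nbr = nn_all.kneighbors(ds.values)
        nbr = nbr[:, 1:]  # drop self
        r = (labels[nbr] != g).mean(axis=1)
        if r.sum() == 0:
            # perfectly separated group: fall back to a uniform budget
            share = np.full(ds.n_subjects, 1 / ds.n_subjects)
        else:
            share = r / r.sum()
        # largest-remainder apportionment: budgets sum exactly to the deficit
        raw = share * deficit
        budget = np.floor(raw).astype(int)
        short = deficit - budget.sum()
        if short > 0:
            order = np.argsort(-(raw - budget), kind="stable")
            budget[order[:short]] += 1

        nn_in = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(ds.values)
        _, in_nbr = nn_in.kneighbors(ds.values)
        in_nbr = in_nbr[:, 1:]
        synth_rows = []
        for i in np.nonzero(budget)[0]:
            for _ in range(budget[i]):
                z = in_nbr[i, rng.integers(0, k_neighbors)]
                lam = rng.uniform()
                synth_rows.append(ds.values[i] + lam * (ds.values[z] - ds.values[i]))
        if not synth_rows:
            out[g] = ds
            continue
        synth = np.vstack(synth_rows)
        ids = list(ds.subject_ids) + [
            f"{SYNTHETIC_PREFIX}{g}{j:04d}" for j in range(len(synth))
        ]
        out[g] = SUVRDataset(
            values=np.vstack([ds.values, synth]),
            subject_ids=ids,
            voi_names=list(ds.voi_names),
            group=g,
        )
    return out
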