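"""Patient-level data splitting: held-out test set and cross-validation folds.

The cohort is split 80/20 into a development set and an untouched test set,
stratified by acquisition site; within each site the training side receives
the ceiling of the fractional count.  For the three-site composition of the
emulated cohort (305/384/846 patients) this yields 1229 development and 306
test patients.  The development set is then partitioned into disjoint
cross-validation folds.
"""

from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np
import pandas as pd

__all__ = ["split_train_test", "assign_folds", "make_split_manifest"]


def split_train_test(
    patient_ids: Sequence[str],
    sites: Sequence[str] | None = None,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Site-stratified train/test split; train takes the per-site ceiling."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("patient_ids must be unique")
    if sites is None:
        sites = ["all"] * len(ids)
    if len(sites) != len(ids):
        raise ValueError("sites must align with patient_ids")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for site in sorted(set(sites)):
        members = [i for i, s in zip(ids, sites) if s == site]
        order = rng.permutation(len(members))
        n_train = math.ceil(train_fraction * len(members))
        for rank, idx in enumerate(order):
            (train if rank < n_train else test).append(members[idx])
    return sorted(train), sorted(test)


def assign_folds(
    train_ids: Sequence[str], n_folds: int = 5, seed: int = 0
) -> dict[str, int]:
    """Partition the development patients into disjoint validation folds."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    ids = list(train_ids)
    if len(ids) < n_folds:
        raise ValueError("fewer patients than folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    return {ids[idx]: int(rank % n_folds) for rank, idx in enumerate(order)}


def make_split_manifest(
    patient_ids: Sequence[str],
    sites: Sequence[str] | None = None,
    train_fraction: float = 0.8,
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy manifest: one row per patient with role (train/test) and fold."""
    train, test = split_train_test(patient_ids, sites, train_fraction, seed)
    folds = assign_folds(train, n_folds, seed)
    site_of = (
        dict(zip(patient_ids, sites)) if sites is not None else {i: "all" for i in patient_ids}
    )
    rows = [
        {"patient_id": pid, "site": site_of[pid], "role": "train", "fold": folds[pid]}
        for pid in train
    ] + [
        {"patient_id": pid, "site": site_of[pid], "role": "test", "fold": -1}
        for pid in test
    ]
    return pd.DataFrame(rows).sort_values("patient_id").reset_index(drop=True)
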