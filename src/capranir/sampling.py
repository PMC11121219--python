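"""Replicate-aware Kennard-Stone partitioning into calibration and prediction sets.

The Kennard-Stone algorithm is the deterministic max-min design used in
chemometrics to pick a space-filling calibration subset: it seeds with the
two mutually farthest samples (Euclidean metric) and then repeatedly adds
the candidate whose minimum distance to the already-selected set is
largest.  Partitioning runs at the *sample* level; all replicate spectra of
a sample inherit its assignment so no sample straddles the split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .spectra import DegenerateInputError, ParameterError, SpectraSet

__all__ = ["PartitionResult", "kennard_stone", "split_spectra"]


@dataclass(frozen=True)
class PartitionResult:
    """Sample-level train/test assignment with the Kennard-Stone pick order."""

    train_sample_ids: tuple
    test_sample_ids: tuple
    selection_order: tuple

    def __post_init__(self) -> None:
        if set(self.train_sample_ids) & set(self.test_sample_ids):
            raise ParameterError("train and test sets overlap")
        if tuple(sorted(map(str, self.selection_order[: len(self.train_sample_ids)]))) != tuple(
            sorted(map(str, self.train_sample_ids))
        ):
            raise ParameterError("selection_order must begin with the train ids")


def kennard_stone(features: np.ndarray, n_select: int,
                  standardize: bool = False) -> list[int]:
    """Select ``n_select`` row indices by the Kennard-Stone max-min criterion.

    Ties are broken by the smallest row index, so the output is fully
    deterministic.  With ``standardize=True`` columns are z-scored first
    (population sd), which puts mixed-unit reference features on one scale.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if n_select < 2:
        raise ParameterError("n_select must be at least 2")
    if n_select > n:
        raise ParameterError("n_select exceeds number of samples")
    if not np.all(np.isfinite(x)):
        raise ParameterError("features contain missing or non-finite values")
    if standardize:
        sd = x.std(axis=0)
        if np.any(sd == 0):
            raise DegenerateInputError("constant feature column under standardize")
        x = (x - x.mean(axis=0)) / sd

    dist = cdist(x, x)
    # Seed: the pair at maximal distance, smaller index first.
    i, j = np.unravel_index(np.argmax(dist), dist.shape)
    selected = [min(i, j), max(i, j)]
    min_dist = np.minimum(dist[selected[0]], dist[selected[1]])
    min_dist[selected] = -np.inf
    while len(selected) < n_select:
        nxt = int(np.argmax(min_dist))  # argmax returns the first (smallest) index on ties
        selected.append(nxt)
        min_dist = np.minimum(min_dist, dist[nxt])
        min_dist[nxt] = -np.inf
    return selected


def split_spectra(spectra: SpectraSet, refs: pd.DataFrame | None, n_train: int,
                  feature_space: str = "reference", n_test: int | None = None,
                  standardize: bool | None = None) -> PartitionResult:
    """Partition samples into calibration/prediction sets by Kennard-Stone.

    Parameters
    ----------
    spectra
        Spectra set; replicates are averaged per sample when
        ``feature_space="spectra"``.
    refs
        Reference table with a ``sample_id`` column and numeric feature
        columns (required for ``feature_space="reference"``).  Non-numeric
        columns are ignored.
    n_train
        Number of samples in the calibration set.
    feature_space
        ``"reference"`` runs Kennard-Stone on the physicochemical attributes;
        ``"spectra"`` on replicate-averaged spectra.
    n_test
        If given and smaller than the remainder, Kennard-Stone selection is
        continued past ``n_train`` and only the next ``n_test`` picks form
        the prediction set (the rest are withheld entirely).  Default: all
        remaining samples are the prediction set.
    standardize
        Z-score features before the Euclidean distance.  Default: ``True``
        for reference features (mixed units), ``False`` for spectra.
    """
    sample_ids = pd.unique(spectra.sample_id)
    n_samples = len(sample_ids)
    if n_train >= n_samples:
        raise ParameterError("n_train must be smaller than the number of samples")

    if feature_space == "reference":
        if refs is None:
            raise ParameterError("reference table required for feature_space='reference'")
        if "sample_id" not in refs.columns:
            raise ParameterError("reference table lacks a sample_id column")
        table = refs.set_index("sample_id")
        missing = [s for s in sample_ids if s not in table.index]
        if missing:
            raise ParameterError(f"reference table missing samples: {missing[:5]}")
        feats = table.loc[list(sample_ids)].select_dtypes(include=[np.number]).to_numpy(float)
        if standardize is None:
            standardize = True
    elif feature_space == "spectra":
        ids, feats = spectra.sample_mean_matrix()
        sample_ids = ids
        if standardize is None:
            standardize = False
    else:
        raise ParameterError(f"unknown feature_space {feature_space!r}")

    if n_test is None:
        n_test = n_samples - n_train
    if n_test < 1 or n_train + n_test > n_samples:
        raise ParameterError("invalid n_test")

    if n_train + n_test == n_samples:
        order = kennard_stone(feats, n_train, standardize=standardize)
        train_ids = [sample_ids[k] for k in order]
        test_ids = [s for s in sample_ids if s not in set(train_ids)]
        selection = train_ids
    else:
        # withhold the tail: continue the max-min ranking to pick the test set too
        order = kennard_stone(feats, n_train + n_test, standardize=standardize)
        train_ids = [sample_ids[k] for k in order[:n_train]]
        test_ids = [sample_ids[k] for k in order[n_train:]]
        selection = train_ids
    return PartitionResult(
        train_sample_ids=tuple(train_ids),
        test_sample_ids=tuple(test_ids),
        selection_order=tuple(selection),
    )
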