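"""Weighted total expression of a gene set per tissue, and its correlation
with a reference set (typically the ribosomal protein genes).

Each gene's expression is first normalized to its own mean across all
samples in the matrix (so every gene averages to 1 and contributes on equal
footing regardless of absolute abundance); the *weighted total* of a set in
a sample is the sum of these normalized values over the set's members, and
the per-tissue value is the mean of the per-sample totals over that tissue's
samples.  Pearson correlation between two sets' per-tissue vectors measures
whether the sets scale together across tissues.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["WeightedWarning", "weighted_total", "correlate_with_reference"]


class WeightedWarning(UserWarning):
    """Warning about genes excluded from a weighted total."""


def weighted_total(
    matrix: pd.DataFrame,
    members: Sequence[str],
    annotation: pd.Series,
    set_name: str = "",
    statistic: str = "mean",
) -> pd.Series:
    """Per-tissue mean of the per-sample sum of mean-normalized abundances.

    Gene means are computed over all samples of the matrix (not per tissue).
    Members absent from the matrix or with zero mean are excluded with a
    warning; if no member has a nonzero mean this is an error.  Only samples
    present in both the matrix and the annotation enter the per-tissue
    aggregation (``statistic`` is ``"mean"``, the default, or ``"median"``).
    """
    if statistic not in ("mean", "median"):
        raise ValueError(f"statistic must be 'mean' or 'median', got {statistic!r}")
    present = [m for m in members if m in matrix.index]
    absent = [m for m in members if m not in matrix.index]
    if absent:
        warnings.warn(
            f"set {set_name or '<unnamed>'!r}: member(s) absent from matrix: {absent}",
            WeightedWarning,
            stacklevel=2,
        )
    sub = matrix.loc[present].astype(float)
    means = sub.mean(axis=1)
    zero = list(means.index[means == 0])
    if zero:
        warnings.warn(
            f"set {set_name or '<unnamed>'!r}: gene(s) with zero mean excluded: {zero}",
            WeightedWarning,
            stacklevel=2,
        )
        sub = sub.drop(index=zero)
        means = means.drop(index=zero)
    if sub.empty:
        raise ValueError(
            f"set {set_name or '<unnamed>'!r}: no member with nonzero mean expression"
        )
    per_sample = sub.div(means, axis=0).sum(axis=0)
    shared = [s for s in per_sample.index if s in annotation.index]
    if not shared:
        raise ValueError("no matrix sample is annotated with a tissue label")
    labels = annotation.loc[shared]
    grouped = per_sample.loc[shared].groupby(labels)
    out = grouped.mean() if statistic == "mean" else grouped.median()
    out.name = set_name or None
    out.index.name = "tissue"
    return out


def correlate_with_reference(
    a: pd.Series, b: pd.Series
) -> tuple[float, int, list[str]]:
    """Pearson r between two per-tissue weighted-total vectors.

    Computed over the tissues shared by both vectors; returns
    ``(r, n_tissues, tissues)``.  Requires at least 3 shared tissues and
    nonzero variance on both sides.
    """
    shared = sorted(set(a.index) & set(b.index))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared tissues, have {len(shared)}")
    x = a.loc[shared].to_numpy(dtype=float)
    y = b.loc[shared].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a weighted-total vector; r undefined")
    r = float(stats.pearsonr(x, y).statistic)
    return r, len(shared), shared
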