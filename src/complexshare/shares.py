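"""Within-group relative abundance (share) computation.

The core statistic: for a defined group of genes (a complex or functional
set), each member's *share* in a sample is its abundance divided by the
summed abundance of all matched members in that sample.  Shares are computed
on the raw linear scale (TPM or intensity), never log-transformed — a
fraction of a total is only meaningful on the linear scale.

Before shares are formed, samples in which the group as a whole is barely
expressed are dropped: a sample is excluded when its group total is strictly
less than half the mean group total across all samples.  The threshold is
computed once, in a single pass (the filter is therefore idempotent on its
own output when the mean is not recomputed).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SharesWarning",
    "group_totals",
    "filter_low_total_samples",
    "compute_shares",
    "share_to_alt_denominator",
    "tissue_summary",
]

COLSUM_TOL = 1e-9


class SharesWarning(UserWarning):
    """Warning about samples or tissues dropped during share computation."""


def group_totals(
    matrix: pd.DataFrame, members: Sequence[str], group: str = ""
) -> pd.Series:
    """Per-sample total abundance over the group's matched member genes.

    Members absent from the matrix contribute zero (they are expected to have
    been reported by :func:`~complexshare.catalog.resolve_symbols` already).

    Raises
    ------
    ValueError
        If no member is present in the matrix at all.
    """
    matched = [m for m in members if m in matrix.index]
    if not matched:
        raise ValueError(f"group {group or '<unnamed>'!r}: no member gene found in matrix")
    totals = matrix.loc[matched].sum(axis=0)
    totals.name = group or None
    return totals


def filter_low_total_samples(totals: pd.Series) -> list[str]:
    """Samples whose group total is at least half the mean group total.

    The exclusion is strict: a sample exactly at ``0.5 * mean`` is retained.
    The mean is taken over *all* samples, once.

    Raises
    ------
    ValueError
        If the mean total is zero (the group is expressed in no sample) or
        the input is empty.
    """
    if len(totals) == 0:
        raise ValueError("no samples to filter")
    mean = float(totals.mean())
    if mean == 0.0:
        raise ValueError("group total is zero in every sample; nothing to retain")
    threshold = 0.5 * mean
    return list(totals.index[totals.to_numpy(dtype=float) >= threshold])


def compute_shares(
    matrix: pd.DataFrame,
    members: Sequence[str],
    retained: Sequence[str],
    group: str = "",
) -> pd.DataFrame:
    """Share matrix: member abundance / group total, per retained sample.

    Columns (samples) sum to 1 within ``COLSUM_TOL``.  Missing members get no
    share row.  Every retained sample must have a positive group total (the
    contract established by :func:`filter_low_total_samples`).
    """
    matched = [m for m in members if m in matrix.index]
    if not matched:
        raise ValueError(f"group {group or '<unnamed>'!r}: no member gene found in matrix")
    sub = matrix.loc[matched, list(retained)].astype(float)
    totals = sub.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(
            f"retained sample(s) with non-positive group total: {bad} "
            "(filter contract violated)"
        )
    shares = sub.div(totals, axis=1)
    shares.attrs["group"] = group
    shares.attrs["normalized"] = True
    return shares


def share_to_alt_denominator(
    matrix: pd.DataFrame,
    numerator_members: Sequence[str],
    denominator_members: Sequence[str],
    retained: Sequence[str],
    group: str = "",
) -> pd.DataFrame:
    """Shares against an alternative denominator gene set.

    Supports normalizing e.g. elongation-factor abundance to the ribosomal
    protein total instead of the group's own total.  Columns need not sum to
    1 (the numerator need not be a subset of the denominator); the result is
    flagged ``normalized=False`` in ``attrs``.
    """
    num = [m for m in numerator_members if m in matrix.index]
    if not num:
        raise ValueError("no numerator gene found in matrix")
    den_totals = group_totals(matrix, denominator_members, group=group or "denominator")
    den = den_totals.loc[list(retained)]
    if (den <= 0).any():
        bad = list(den.index[den <= 0])
        raise ValueError(f"retained sample(s) with non-positive denominator total: {bad}")
    shares = matrix.loc[num, list(retained)].astype(float).div(den, axis=1)
    shares.attrs["group"] = group
    shares.attrs["normalized"] = False
    return shares


def tissue_summary(
    shares: pd.DataFrame,
    annotation: pd.Series,
    statistic: str = "median",
) -> pd.DataFrame:
    """Per-(gene, tissue) central tendency of shares over retained samples.

    ``statistic`` is ``"median"`` (default, robust to outlier samples) or
    ``"mean"``.  Tissues present in the annotation but with no retained
    sample are omitted with a warning.  Every retained sample must be
    annotated.

    Returns a tidy frame with columns ``gene``, ``tissue``, ``summary``,
    ``n_samples``.
    """
    if statistic not in ("median", "mean"):
        raise ValueError(f"statistic must be 'median' or 'mean', got {statistic!r}")
    samples = list(shares.columns)
    missing = [s for s in samples if s not in annotation.index]
    if missing:
        raise ValueError(f"retained sample(s) without tissue annotation: {missing}")
    labels = annotation.loc[samples]
    empty = sorted(set(annotation.unique()) - set(labels.unique()))
    if empty:
        warnings.warn(
            f"tissue(s) with zero retained samples omitted: {empty}",
            SharesWarning,
            stacklevel=2,
        )
    rows = []
    for tissue, cols in labels.groupby(labels).groups.items():
        block = shares[list(cols)]
        summary = block.median(axis=1) if statistic == "median" else block.mean(axis=1)
        for gene, value in summary.items():
            rows.append((gene, tissue, float(value), len(cols)))
    out = pd.DataFrame(rows, columns=["gene", "tissue", "summary", "n_samples"])
    return out.sort_values(["gene", "tissue"], kind="stable").reset_index(drop=True)
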