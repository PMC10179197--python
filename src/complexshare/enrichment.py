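"""Sample-set enrichment over tissue groups (GSEA-style running sum).

The set-enrichment statistic of the GSEA family, repurposed with the roles
swapped: the *ranked list* is the list of samples ordered by a gene's
within-group share (descending), and the *sets* are tissue groups of
samples.  Walking down the ranking, a hit (a sample belonging to the tissue)
increments a running sum by its weighted statistic magnitude
``|share|^p / sum_hits |share|^p`` and a miss decrements it by
``1 / (N - n_set)``; the enrichment score (ES) is the running-sum value of
maximal absolute deviation from zero, signed.  The walk always returns to
exactly zero at the end.

Significance comes from a permutation null: random same-size sample subsets
with the ranked statistic held fixed — the analogue of gene-set permutation
in standard gene-set enrichment implementations, which likewise share
permutations across same-size sets.  When the subset space is small enough
(``C(N, n_set) <= n_permutations``) the null is enumerated exhaustively.
The normalized enrichment score (NES) divides ES by the mean magnitude of
same-sign null scores, and the permutation p-value uses the +1-corrected
estimator, so ``p = 0`` is impossible.  p-values are then
Benjamini-Hochberg-adjusted across the tissue labels tested for the same
gene (the family is the number of sample groups).
"""

from __future__ import annotations

import itertools
import math
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentWarning",
    "PermutationConfig",
    "RankedSamples",
    "rank_samples",
    "enrichment_score",
    "running_sum",
    "exhaustive_null",
    "permutation_null",
    "nes_and_pvalue",
    "fdr_over_tissues",
    "run_enrichment",
]


#: tolerance for resolving an exact tie between the positive and negative
#: running-sum extrema (the positive one wins); absorbs summation rounding
ES_TIE_TOL = 1e-12


class EnrichmentWarning(UserWarning):
    """Warning about skipped tissues or degenerate enrichment inputs."""


@dataclass(frozen=True)
class PermutationConfig:
    """Permutation-test configuration.

    Parameters
    ----------
    n_permutations:
        Null size (default 10,000); at least 100 for p-value reporting.
    seed:
        Root seed; expanded into independent substreams per
        (gene, set size), so results are invariant to iteration order.
    weight_exponent:
        Exponent ``p`` on the statistic magnitude in hit increments.
        1 (default) weights hits by their share; 0 gives the classic
        unweighted Kolmogorov-Smirnov statistic.
    min_set_size:
        Tissues with fewer retained samples are skipped.
    fdr_threshold:
        q-value cutoff for the significance flag (default 0.01).
    exhaustive:
        ``"auto"`` (enumerate all subsets when ``C(N, k) <= n_permutations``),
        ``True`` (force enumeration) or ``False`` (always sample).
    """

    n_permutations: int = 10_000
    seed: int = 0
    weight_exponent: float = 1.0
    min_set_size: int = 3
    fdr_threshold: float = 0.01
    exhaustive: bool | str = "auto"

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100 for p-value reporting")
        if self.weight_exponent < 0:
            raise ValueError("weight_exponent must be non-negative")
        if self.min_set_size < 1:
            raise ValueError("min_set_size must be >= 1")
        if self.exhaustive not in (True, False, "auto"):
            raise ValueError("exhaustive must be True, False or 'auto'")


@dataclass(frozen=True)
class RankedSamples:
    """Samples sorted descending by statistic, ties broken by ascending id."""

    samples: tuple[str, ...]
    statistics: np.ndarray  # float, descending

    def __post_init__(self) -> None:
        if not np.isfinite(self.statistics).all():
            raise ValueError("ranked statistics must be finite")
        if len(self.samples) != len(self.statistics):
            raise ValueError("samples and statistics length mismatch")

    def __len__(self) -> int:
        return len(self.samples)


def rank_samples(shares: pd.DataFrame, gene: str) -> RankedSamples:
    """Rank samples by a gene's share, descending; deterministic tie order.

    Ties are broken by ascending sample identifier so the ranking is stable
    across runs and platforms.
    """
    if gene not in shares.index:
        raise KeyError(f"gene {gene!r} not present in share matrix")
    values = shares.loc[gene].to_numpy(dtype=float)
    ids = np.asarray(shares.columns, dtype=object)
    # lexsort: last key is primary; ascending id within equal statistics
    order = np.lexsort((ids, -values))
    return RankedSamples(samples=tuple(ids[order]), statistics=values[order])


def _hit_weights(statistics: np.ndarray, weight_exponent: float) -> np.ndarray:
    if weight_exponent == 0:
        return np.ones_like(statistics)
    return np.abs(statistics) ** weight_exponent


def _es_from_sorted_positions(
    pos: np.ndarray, weights: np.ndarray, n: int
) -> np.ndarray:
    """ES for a batch of subsets given row-wise *sorted* hit positions.

    ``pos`` is (B, k) int, each row sorted ascending; ``weights`` is the
    per-position hit weight vector of length ``n``.  The running-sum extrema
    can only occur immediately after a hit (local maximum candidates) or
    immediately before a hit (local minimum candidates), which reduces the
    walk to ``k`` evaluation points per subset.
    """
    b, k = pos.shape
    miss_dec = 1.0 / (n - k)
    w = weights[pos]  # (B, k)
    wsum = w.sum(axis=1, keepdims=True)
    degenerate = wsum[:, 0] == 0
    if degenerate.any():
        # all-zero statistics in the hit set: fall back to equal hit weights
        w[degenerate] = 1.0
        wsum[degenerate] = float(k)
    cum = np.cumsum(w, axis=1) / wsum
    j = np.arange(k)
    misses_before = pos - j  # misses encountered before the j-th hit
    after = cum - misses_before * miss_dec  # value just after each hit
    before = after - w / wsum  # value just before each hit
    hi = after.max(axis=1)
    lo = np.minimum(before.min(axis=1), 0.0)
    # ES_TIE_TOL absorbs rounding at exact |max| == |min| ties (tie -> positive)
    es = np.where(hi >= -lo - ES_TIE_TOL, hi, lo)
    return np.clip(es, -1.0, 1.0)


def running_sum(
    ranked: RankedSamples, member_set: set[str] | frozenset[str], weight_exponent: float = 1.0
) -> np.ndarray:
    """Full running-sum profile of the weighted KS walk (length N).

    Entry ``i`` is the walk value after processing rank position ``i``.
    """
    n = len(ranked)
    hits = np.array([s in member_set for s in ranked.samples], dtype=bool)
    k = int(hits.sum())
    _check_set(ranked, member_set, k, n)
    w = _hit_weights(ranked.statistics, weight_exponent)
    hit_w = np.where(hits, w, 0.0)
    wsum = hit_w.sum()
    if wsum == 0:
        hit_w = hits.astype(float)
        wsum = float(k)
    steps = hit_w / wsum - (~hits) / (n - k)
    return np.cumsum(steps)


def _check_set(ranked: RankedSamples, member_set, k: int, n: int) -> None:
    if k == 0:
        raise ValueError("member set is empty (or disjoint from the ranking)")
    if k >= n:
        raise ValueError("member set spans all ranked samples")
    unknown = set(member_set) - set(ranked.samples)
    if unknown:
        raise ValueError(f"set member(s) not in ranking: {sorted(unknown)}")


def enrichment_score(
    ranked: RankedSamples,
    member_set: set[str] | frozenset[str],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Enrichment score and running-sum profile for one sample set.

    ES is the running-sum value of maximal absolute deviation from zero,
    signed; when the positive and negative extrema tie in magnitude the
    positive one is taken.  ES is always in [-1, 1] and the walk ends at 0.
    """
    profile = running_sum(ranked, member_set, weight_exponent)
    hi = float(profile.max())
    lo = min(float(profile.min()), 0.0)
    es = hi if hi >= -lo - ES_TIE_TOL else lo
    return float(np.clip(es, -1.0, 1.0)), profile


def exhaustive_null(
    ranked: RankedSamples, set_size: int, weight_exponent: float = 1.0
) -> np.ndarray:
    """ES of every ``C(N, set_size)`` sample subset (enumeration order)."""
    n = len(ranked)
    if not 0 < set_size < n:
        raise ValueError(f"set_size must be in (0, {n}), got {set_size}")
    pos = np.array(list(itertools.combinations(range(n), set_size)), dtype=np.intp)
    w = _hit_weights(ranked.statistics, weight_exponent)
    return _es_from_sorted_positions(pos, w, n)


def permutation_null(
    ranked: RankedSamples,
    set_size: int,
    config: PermutationConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Null ES distribution for random same-size sample subsets.

    Each permutation draws a uniformly random subset of ``set_size`` samples
    (without replacement within a draw) from the ranked list and records its
    ES; the ranked statistic is held fixed.  Exhaustive enumeration replaces
    sampling when ``C(N, set_size) <= n_permutations`` (config ``"auto"``)
    or when forced.  Reproducible given the config seed.
    """
    n = len(ranked)
    if not 0 < set_size < n:
        raise ValueError(f"set_size must be in (0, {n}), got {set_size}")
    use_exhaustive = config.exhaustive is True or (
        config.exhaustive == "auto"
        and math.comb(n, set_size) <= config.n_permutations
    )
    if use_exhaustive:
        return exhaustive_null(ranked, set_size, config.weight_exponent)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    b = config.n_permutations
    w = _hit_weights(ranked.statistics, config.weight_exponent)
    keys = rng.random((b, n))
    pos = np.argpartition(keys, set_size, axis=1)[:, :set_size]
    pos.sort(axis=1)
    return _es_from_sorted_positions(pos.astype(np.intp), w, n)


def nes_and_pvalue(es: float, null_scores: np.ndarray) -> tuple[float, float]:
    """Normalize ES and estimate its permutation p-value.

    NES divides ES by the mean |null ES| over null values with the same sign
    as ES; the p-value is ``(1 + #{same-sign null with |null| >= |es|}) /
    (1 + #same-sign null)``.  ``es = 0`` maps to ``(0, 1)``.  If no null
    value shares the sign of ES, NES is NaN (flagged undefined) and the
    p-value is ``1 / (1 + len(null))``.
    """
    null_scores = np.asarray(null_scores, dtype=float)
    if null_scores.size == 0:
        raise ValueError("null score vector is empty")
    if es == 0.0:
        return 0.0, 1.0
    same = null_scores[np.sign(null_scores) == np.sign(es)]
    if same.size == 0:
        return float("nan"), 1.0 / (1.0 + null_scores.size)
    # ES_TIE_TOL: a null score equal to |es| up to rounding counts as extreme
    pvalue = (1.0 + int((np.abs(same) >= abs(es) - ES_TIE_TOL).sum())) / (1.0 + same.size)
    nes = es / float(np.abs(same).mean())
    return nes, pvalue


def fdr_over_tissues(pvalues: pd.Series) -> pd.Series:
    """Benjamini-Hochberg adjustment across one gene's tissue labels.

    The family is the set of tissue groups tested for that gene.  q-values
    are monotone and never smaller than their p-values.
    """
    if len(pvalues) == 0:
        return pvalues.copy()
    q = multipletests(pvalues.to_numpy(dtype=float), method="fdr_bh")[1]
    return pd.Series(q, index=pvalues.index, name="qvalue")


def _substream(seed: int, gene: str, set_size: int) -> np.random.Generator:
    """Independent, iteration-order-invariant RNG keyed by (gene, set size)."""
    key = zlib.crc32(gene.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed, key, set_size]))


def run_enrichment(
    shares: pd.DataFrame,
    annotation: pd.Series,
    config: PermutationConfig | None = None,
    group: str = "",
    global_fdr: bool = False,
) -> pd.DataFrame:
    """Enrichment of every member gene x tissue group, with NES, p and q.

    For each gene the samples are ranked by share and every tissue label
    with at least ``min_set_size`` retained samples (and fewer than all of
    them) is tested.  The permutation null is computed once per
    (gene ranking, set size) and shared across same-size tissue sets; its
    RNG substream is keyed by (seed, gene, set size) so results do not
    depend on iteration order.  q-values are BH-adjusted within each gene's
    tissue family (``global_fdr=True`` additionally adjusts across all
    genes x tissues instead).

    Returns a frame with columns ``group, gene, tissue, set_size, es, nes,
    pvalue, qvalue, significant``.
    """
    config = config or PermutationConfig()
    samples = list(shares.columns)
    missing = [s for s in samples if s not in annotation.index]
    if missing:
        raise ValueError(f"retained sample(s) without tissue annotation: {missing}")
    labels = annotation.loc[samples]
    n = len(samples)
    tissue_sets: dict[str, frozenset[str]] = {}
    for tissue in sorted(labels.unique()):
        members = frozenset(labels.index[labels == tissue])
        if len(members) < config.min_set_size:
            warnings.warn(
                f"tissue {tissue!r} has {len(members)} retained sample(s) "
                f"(< min_set_size={config.min_set_size}); skipped",
                EnrichmentWarning,
                stacklevel=2,
            )
            continue
        if len(members) >= n:
            warnings.warn(
                f"tissue {tissue!r} spans all retained samples; skipped",
                EnrichmentWarning,
                stacklevel=2,
            )
            continue
        tissue_sets[tissue] = members
    rows: list[dict] = []
    for gene in shares.index:
        ranked = rank_samples(shares, gene)
        nulls: dict[int, np.ndarray] = {}
        for tissue, members in tissue_sets.items():
            k = len(members)
            if k not in nulls:
                nulls[k] = permutation_null(
                    ranked, k, config, rng=_substream(config.seed, str(gene), k)
                )
            es, _ = enrichment_score(ranked, members, config.weight_exponent)
            nes, pvalue = nes_and_pvalue(es, nulls[k])
            rows.append(
                {
                    "group": group,
                    "gene": gene,
                    "tissue": tissue,
                    "set_size": k,
                    "es": es,
                    "nes": nes,
                    "pvalue": pvalue,
                }
            )
    records = pd.DataFrame(
        rows, columns=["group", "gene", "tissue", "set_size", "es", "nes", "pvalue"]
    )
    if records.empty:
        records["qvalue"] = pd.Series(dtype=float)
        records["significant"] = pd.Series(dtype=bool)
        return records
    if global_fdr:
        records["qvalue"] = fdr_over_tissues(records["pvalue"]).to_numpy()
    else:
        records["qvalue"] = (
            records.groupby("gene", sort=False)["pvalue"]
            .transform(lambda p: fdr_over_tissues(p).to_numpy())
        )
    records["significant"] = records["qvalue"] < config.fdr_threshold
    return records
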