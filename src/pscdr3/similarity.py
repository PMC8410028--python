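"""Minimum Hamming / Levenshtein distance profiles of CDR3 sets.

Antigen-selected repertoires are more self-similar than bystander pools:
each sequence tends to sit close (few substitutions or indels) to another
member of the set.  For every sequence we record the minimum distance to
any *other* sequence in the set.  Hamming distances are defined only
between equal-length sequences; a sequence with no equal-length partner
has an undefined Hamming minimum and is excluded from the histogram
denominator.  The observed profile is compared against the median profile
of equal-sized random resamplings from a background pool (activated or
resting) with a two-sided Fisher exact test on counts at or below a
distance cutoff.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np
from scipy.stats import fisher_exact

__all__ = [
    "DistanceProfile",
    "MedianProfile",
    "DistanceEnrichmentResult",
    "DEFAULT_CUTOFFS",
    "min_distance_profile",
    "resampled_profile_baseline",
    "compare_distance_enrichment",
]

#: Distance bins treated as "highly similar" in the enrichment comparison.
DEFAULT_CUTOFFS = {"hamming": 2, "levenshtein": 1}


@dataclass
class DistanceProfile:
    """Per-sequence minimum distances and the derived histogram.

    ``minima`` is aligned with ``sequences``; NaN marks an undefined
    minimum (Hamming with no equal-length partner).
    """

    metric: str
    sequences: list[str]
    minima: np.ndarray

    @property
    def n_defined(self) -> int:
        return int(np.sum(~np.isnan(self.minima)))

    def counts(self) -> dict[int, int]:
        defined = self.minima[~np.isnan(self.minima)].astype(int)
        return dict(sorted(Counter(defined.tolist()).items()))

    @property
    def percentages(self) -> dict[int, float]:
        n = self.n_defined
        return {d: 100.0 * c / n for d, c in self.counts().items()}

    def count_at_or_below(self, cutoff: int) -> int:
        return sum(c for d, c in self.counts().items() if d <= cutoff)


@dataclass
class MedianProfile:
    """Median-of-resamples distance profile (the resampled baseline)."""

    metric: str
    percentages: dict[int, float]
    n: int  # defined-minimum denominator of each resample (median)
    n_resamples: int

    def counts(self) -> dict[int, int]:
        return {d: int(round(pct * self.n / 100.0)) for d, pct in self.percentages.items()}

    def count_at_or_below(self, cutoff: int) -> int:
        return sum(c for d, c in self.counts().items() if d <= cutoff)


@dataclass(frozen=True)
class DistanceEnrichmentResult:
    odds_ratio: float
    p_value: float
    table: np.ndarray
    cutoff: int


def _hamming_minima(seqs: Sequence[str]) -> np.ndarray:
    minima = np.full(len(seqs), np.nan)
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    for indices in by_len.values():
        if len(indices) < 2:
            continue
        arr = np.frombuffer(
            "".join(seqs[i] for i in indices).encode("ascii"), dtype=np.uint8
        ).reshape(len(indices), -1)
        # all-pairs Hamming within the length group
        dist = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
        np.fill_diagonal(dist, dist.max() + 1)
        group_min = dist.min(axis=1)
        for pos, i in enumerate(indices):
            minima[i] = group_min[pos]
    return minima


def _levenshtein_minima(seqs: Sequence[str]) -> np.ndarray:
    n = len(seqs)
    minima = np.full(n, np.inf)
    counts = Counter(seqs)
    lengths = np.array([len(s) for s in seqs])
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    length_values = sorted(by_len)
    for i, s in enumerate(seqs):
        if counts[s] > 1:
            minima[i] = 0
            continue
        best = np.inf
        # visit length buckets in order of |length difference|, which lower-
        # bounds the edit distance, so we can stop early
        for lv in sorted(length_values, key=lambda lv: abs(lv - lengths[i])):
            gap = abs(lv - lengths[i])
            if gap >= best:
                break
            for j in by_len[lv]:
                if j == i:
                    continue
                k = int(best) - 1 if np.isfinite(best) else -1
                res = edlib.align(s, seqs[j], mode="NW", task="distance", k=k)
                d = res["editDistance"]
                if d != -1 and d < best:
                    best = d
                    if best == gap:  # cannot improve within this bucket
                        break
            if best == 0:
                break
        minima[i] = best
    return minima


def min_distance_profile(sequences: Sequence[str], metric: str) -> DistanceProfile:
    """Minimum distance of each sequence to any other sequence in the set.

    ``sequences`` may contain cross-individual duplicates; a duplicated
    sequence has minimum distance 0 under either metric.
    """
    if metric not in ("hamming", "levenshtein"):
        raise ValueError("metric must be 'hamming' or 'levenshtein'")
    seqs = list(sequences)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    if metric == "hamming":
        minima = _hamming_minima(seqs)
    else:
        minima = _levenshtein_minima(seqs)
    return DistanceProfile(metric=metric, sequences=seqs, minima=minima)


def resampled_profile_baseline(
    pool_by_individual: Mapping[str, Sequence[str]],
    strata_sizes: Mapping[str, int],
    *,
    metric: str,
    n_resamples: int = 100,
    seed: int,
    stratified: bool = True,
) -> MedianProfile:
    """Median distance profile of random resamplings from a background pool.

    Each resample draws, without replacement, ``strata_sizes[ind]`` unique
    sequences from each individual's pool (or the same total from the
    pooled sequences when ``stratified=False``) and profiles the pooled
    draw.  The median percentage at each distance across resamples is
    returned.
    """
    rng = np.random.default_rng(seed)
    for ind, size in strata_sizes.items():
        if stratified and size > len(pool_by_individual[ind]):
            raise ValueError(f"stratum {ind!r} larger than its pool")
    total = sum(strata_sizes.values())
    pooled = [s for seqs in pool_by_individual.values() for s in seqs]
    if not stratified and total > len(pooled):
        raise ValueError("requested sample larger than pooled sequences")

    per_resample: list[dict[int, float]] = []
    denominators = []
    for _ in range(n_resamples):
        if stratified:
            draw: list[str] = []
            for ind in sorted(strata_sizes):
                pool = list(pool_by_individual[ind])
                idx = rng.choice(len(pool), size=strata_sizes[ind], replace=False)
                draw.extend(pool[k] for k in idx)
        else:
            idx = rng.choice(len(pooled), size=total, replace=False)
            draw = [pooled[k] for k in idx]
        prof = min_distance_profile(draw, metric)
        per_resample.append(prof.percentages)
        denominators.append(prof.n_defined)

    distances = sorted({d for pcts in per_resample for d in pcts})
    med = {
        d: float(np.median([pcts.get(d, 0.0) for pcts in per_resample]))
        for d in distances
    }
    return MedianProfile(
        metric=metric,
        percentages=med,
        n=int(np.median(denominators)),
        n_resamples=n_resamples,
    )


def compare_distance_enrichment(
    observed: DistanceProfile,
    baseline: MedianProfile | DistanceProfile,
    cutoff: int | None = None,
) -> DistanceEnrichmentResult:
    """Two-sided Fisher exact test: observed vs baseline counts at or below
    the distance cutoff (defaults: Hamming 2, Levenshtein 1)."""
    if observed.metric != baseline.metric:
        raise ValueError("profiles use different metrics")
    if cutoff is None:
        cutoff = DEFAULT_CUTOFFS[observed.metric]
    obs_n = observed.n_defined
    base_n = baseline.n if isinstance(baseline, MedianProfile) else baseline.n_defined
    obs_le = observed.count_at_or_below(cutoff)
    base_le = baseline.count_at_or_below(cutoff)
    table = np.array([[obs_le, obs_n - obs_le], [base_le, base_n - base_le]])
    odds, p = fisher_exact(table, alternative="two-sided")
    return DistanceEnrichmentResult(
        odds_ratio=float(odds), p_value=float(p), table=table, cutoff=cutoff
    )
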