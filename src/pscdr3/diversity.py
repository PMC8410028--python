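"""Hill diversity profiles of clonotype abundance distributions.

The Hill number of order q for proportional abundances P_i (optionally
pooled over samples j with weights W_j) is

    D(q) = ( sum_j W_j sum_i P_i|j ^ q ) ^ (1 / (1 - q))

with the q -> 1 limit  exp( - sum_j W_j sum_i P_i|j ln P_i|j ).  q tunes
the weight of abundant clones: q = 0 is species richness, q = 1 the
exponential of Shannon entropy, q = 2 the inverse Simpson index.  Curves
over q in [0, 4] are estimated by uniform resampling (multinomial
bootstrap at a fixed read depth) so that sets sequenced at different
depths are comparable; pairs of curves are compared with the empirical
cumulative distribution function of the paired bootstrap delta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

__all__ = [
    "DiversityCurve",
    "hill_diversity",
    "default_q_grid",
    "diversity_curve",
    "compare_diversity",
    "diversity_fold_change",
    "cohort_fold_change_test",
]


def default_q_grid(q_max: float = 4.0, step: float = 0.05) -> np.ndarray:
    n = int(round(q_max / step))
    return np.round(np.linspace(0.0, q_max, n + 1), 10)


def _hill_single(p: np.ndarray, q: float) -> float:
    p = p[p > 0]
    if q == 1.0:
        return float(np.exp(-np.sum(p * np.log(p))))
    if q == 0.0:
        return float(p.size)
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def hill_diversity(profile, q: float, weights=None) -> float:
    """Hill number of order ``q``.

    ``profile`` is a 1-D array of proportional abundances summing to 1,
    or, with ``weights`` given, a sequence of such arrays pooled with
    sample weights W_j summing to 1.
    """
    if q < 0:
        raise ValueError("q must be non-negative")
    if weights is None:
        p = np.asarray(profile, dtype=float)
        if p.ndim != 1:
            raise ValueError("profile must be 1-D (or pass weights for pooled samples)")
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("abundances must sum to 1")
        return _hill_single(p, q)
    w = np.asarray(weights, dtype=float)
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("sample weights must sum to 1")
    inner = 0.0
    for wj, pj in zip(w, profile, strict=True):
        pj = np.asarray(pj, dtype=float)
        pj = pj[pj > 0]
        if q == 1.0:
            inner += wj * np.sum(pj * np.log(pj))
        else:
            inner += wj * np.sum(pj**q)
    if q == 1.0:
        return float(np.exp(-inner))
    return float(inner ** (1.0 / (1.0 - q)))


@dataclass
class DiversityCurve:
    """Bootstrap Hill-diversity curve over a grid of orders q."""

    q_grid: np.ndarray
    values: np.ndarray  # mean across bootstrap resamples
    lower: np.ndarray  # 2.5th percentile
    upper: np.ndarray  # 97.5th percentile
    boot: np.ndarray  # n_boot x len(q_grid)
    resample_size: int
    n_boot: int
    seed: int


def diversity_curve(
    counts,
    *,
    q_grid: np.ndarray | None = None,
    resample_size: int,
    n_boot: int = 200,
    seed: int,
) -> DiversityCurve:
    """Hill-diversity curve from clone read counts via uniform resampling.

    Each bootstrap replicate draws ``resample_size`` reads with
    replacement from the count distribution and evaluates the Hill number
    on the resampled proportions at every q.  The point estimate is the
    mean across replicates, the band the 2.5/97.5 percentiles.
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    if resample_size <= 0:
        raise ValueError("resample_size must be positive")
    if counts.sum() < resample_size:
        raise ValueError("resample_size exceeds total reads")
    if q_grid is None:
        q_grid = default_q_grid()
    q_grid = np.asarray(q_grid, dtype=float)
    rng = np.random.default_rng(seed)
    probs = counts / counts.sum()
    draws = rng.multinomial(resample_size, probs, size=n_boot).astype(float)
    props = draws / resample_size

    boot = np.empty((n_boot, q_grid.size))
    nonzero = props > 0
    logp = np.where(nonzero, np.log(np.where(nonzero, props, 1.0)), 0.0)
    for k, q in enumerate(q_grid):
        if q == 0.0:
            boot[:, k] = nonzero.sum(axis=1)
        elif q == 1.0:
            boot[:, k] = np.exp(-np.sum(props * logp, axis=1))
        else:
            boot[:, k] = np.sum(
                np.where(nonzero, props**q, 0.0), axis=1
            ) ** (1.0 / (1.0 - q))
    return DiversityCurve(
        q_grid=q_grid,
        values=boot.mean(axis=0),
        lower=np.percentile(boot, 2.5, axis=0),
        upper=np.percentile(boot, 97.5, axis=0),
        boot=boot,
        resample_size=resample_size,
        n_boot=n_boot,
        seed=seed,
    )


def _check_compatible(a: DiversityCurve, b: DiversityCurve) -> None:
    if not np.array_equal(a.q_grid, b.q_grid):
        raise ValueError("curves use different q grids")


def compare_diversity(curve_a: DiversityCurve, curve_b: DiversityCurve) -> pd.DataFrame:
    """Per-q two-sided p values from the bootstrap-delta ECDF.

    delta = paired difference of bootstrap replicates; the two-sided p is
    2 * min(P(delta <= 0), P(delta >= 0)), floored at 1/n_boot and capped
    at 1.
    """
    _check_compatible(curve_a, curve_b)
    if (curve_a.n_boot != curve_b.n_boot
            or curve_a.resample_size != curve_b.resample_size):
        raise ValueError("curves must share n_boot and resample_size")
    delta = curve_a.boot - curve_b.boot
    p_lo = np.mean(delta <= 0, axis=0)
    p_hi = np.mean(delta >= 0, axis=0)
    p = 2.0 * np.minimum(p_lo, p_hi)
    p = np.clip(p, 1.0 / curve_a.n_boot, 1.0)
    return pd.DataFrame(
        {"q": curve_a.q_grid, "delta": delta.mean(axis=0), "p_value": p}
    )


def diversity_fold_change(
    curve_num: DiversityCurve, curve_den: DiversityCurve
) -> pd.DataFrame:
    """Elementwise ratio of the point estimates of two curves (Hill >= 1,
    so the denominator is never zero)."""
    _check_compatible(curve_num, curve_den)
    return pd.DataFrame(
        {"q": curve_num.q_grid, "fold_change": curve_num.values / curve_den.values}
    )


def cohort_fold_change_test(ratios_a: pd.DataFrame, ratios_b: pd.DataFrame):
    """Wilcoxon matched-pairs signed-rank test on two per-individual
    fold-change distributions (rows: individuals, columns: q values or a
    single summary column).  Returns (statistic, p_value)."""
    a = np.asarray(ratios_a, dtype=float).ravel()
    b = np.asarray(ratios_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired distributions must have matching shape")
    stat, p = wilcoxon(a, b)
    return float(stat), float(p)
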