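"""Selection of putatively antigen-specific CDR3s (ps-CDR3s).

A clonotype observed in the activated (CD154+) compartment may be there
because it is antigen specific, or because an abundant bystander clone was
carried along.  The selection procedure tests, for every unique CDR3
observed in an individual's activated sample, whether its read proportion
in the activated compartment exceeds what the pooled activated+resting
memory repertoire would predict, using a G test of independence on the
2x2 table (this clone vs all other reads) x (activated vs resting):

    G = 2 * sum_i O_i * ln(O_i / E_i)

with expected counts ``E_i`` from the table marginals, zero cells
contributing 0 and the p value taken from the upper tail of the
chi-square distribution with one degree of freedom (no continuity or
Williams correction).  Benjamini-Hochberg FDR adjustment is applied over
the individual's tested universe, and two further filters remove
sequences with an activated read count of 1 and sequences whose activated
proportion does not exceed their resting proportion.  Sequences passing
all three criteria are the individual's ps-CDR3s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .io import Repertoire

__all__ = [
    "NotTestableError",
    "GTestResult",
    "SelectionConfig",
    "g_test",
    "bh_adjust",
    "select_ps_cdr3",
    "extract_nt_detail",
    "IndividualSelection",
]


class NotTestableError(ValueError):
    """The clone lies outside the tested universe (no activated reads)."""


@dataclass(frozen=True)
class GTestResult:
    """G statistic and chi-square(1) p value for one 2x2 clone table."""

    g_stat: float
    p_value: float
    observed: np.ndarray  # 2x2: rows clone/other, cols activated/resting
    expected: np.ndarray


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds of the ps-CDR3 selection procedure.

    alpha      FDR cutoff on the BH-adjusted q values (default 0.05)
    min_count  minimum activated read count (default 2: singletons removed)
    level      aggregation level of the tested universe, "aa" or "nt"
    """

    alpha: float = 0.05
    min_count: int = 2
    level: str = "aa"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.level not in ("aa", "nt"):
            raise ValueError("level must be 'aa' or 'nt'")


def _g_stat_vec(
    a: np.ndarray, a_total: int, r: np.ndarray, r_total: int
) -> np.ndarray:
    """Vectorized G statistic for 2x2 tables [[a, r], [A-a, R-r]]."""
    a = np.asarray(a, dtype=float)
    r = np.asarray(r, dtype=float)
    n = float(a_total + r_total)
    clone_tot = a + r
    other_tot = n - clone_tot
    # Expected counts from marginals.
    e_a = clone_tot * a_total / n
    e_r = clone_tot * r_total / n
    e_oa = other_tot * a_total / n
    e_or = other_tot * r_total / n
    g = 2.0 * (
        xlogy(a, a / np.where(e_a > 0, e_a, 1.0))
        + xlogy(r, r / np.where(e_r > 0, e_r, 1.0))
        + xlogy(a_total - a, (a_total - a) / np.where(e_oa > 0, e_oa, 1.0))
        + xlogy(r_total - r, (r_total - r) / np.where(e_or > 0, e_or, 1.0))
    )
    # Tiny negative values arise from rounding when proportions are equal.
    return np.maximum(g, 0.0)


def g_test(
    activated_count: int,
    activated_total: int,
    resting_count: int,
    resting_total: int,
) -> GTestResult:
    """G test of independence for a single clone's 2x2 read table.

    Raises :class:`NotTestableError` when the clone has no activated
    reads, and ``ValueError`` on negative or inconsistent inputs.
    """
    vals = (activated_count, activated_total, resting_count, resting_total)
    if any(v < 0 for v in vals):
        raise ValueError("counts and totals must be non-negative")
    if activated_count > activated_total or resting_count > resting_total:
        raise ValueError("compartment total smaller than clone count")
    if activated_total < 1 or resting_total < 1:
        raise ValueError("compartment totals must be >= 1")
    if activated_count == 0:
        raise NotTestableError("clone has no activated reads; outside the tested universe")

    g = float(_g_stat_vec(np.array([activated_count]), activated_total,
                          np.array([resting_count]), resting_total)[0])
    p = float(chi2.sf(g, df=1)) if g > 0 else 1.0
    observed = np.array(
        [
            [activated_count, resting_count],
            [activated_total - activated_count, resting_total - resting_count],
        ],
        dtype=float,
    )
    n = observed.sum()
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / n
    return GTestResult(g_stat=g, p_value=p, observed=observed, expected=expected)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q values (order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_ps_cdr3(
    activated: Repertoire,
    resting: Repertoire,
    config: SelectionConfig | None = None,
) -> pd.DataFrame:
    """Run the full selection procedure for one individual.

    The tested universe is every unique sequence (amino acid by default)
    in the activated compartment; resting-only clones are never tested.
    Returns one row per tested sequence with the G statistic, p and
    BH-adjusted q value, the three filter flags and their conjunction
    ``is_ps``, sorted by (q, -G, sequence) for deterministic output.
    """
    config = config or SelectionConfig()
    if activated.clonotypes.empty:
        raise ValueError("activated repertoire is empty")
    key = "aa_seq" if config.level == "aa" else "nt_seq"

    act = activated.clonotypes.groupby(key, sort=True)["count"].sum()
    res = resting.clonotypes.groupby(key, sort=True)["count"].sum()
    a_total = int(act.sum())
    r_total = int(res.sum())
    if a_total < 1 or r_total < 1:
        raise ValueError("both compartments must have nonzero totals")

    a = act.to_numpy(dtype=float)
    r = res.reindex(act.index, fill_value=0).to_numpy(dtype=float)
    g = _g_stat_vec(a, a_total, r, r_total)
    p = np.where(g > 0, chi2.sf(g, df=1), 1.0)
    q = bh_adjust(p)

    out = pd.DataFrame(
        {
            "aa_seq" if key == "aa_seq" else "nt_seq": act.index,
            "activated_count": a.astype(int),
            "resting_count": r.astype(int),
            "activated_total": a_total,
            "resting_total": r_total,
            "activated_prop": a / a_total,
            "resting_prop": r / r_total,
            "g_stat": g,
            "p_value": p,
            "q_value": q,
        }
    )
    out["passes_q"] = out["q_value"] < config.alpha
    out["passes_count"] = out["activated_count"] >= config.min_count
    out["passes_prop"] = out["activated_prop"] > out["resting_prop"]
    out["is_ps"] = out["passes_q"] & out["passes_count"] & out["passes_prop"]
    out = out.sort_values(
        ["q_value", "g_stat", key], ascending=[True, False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out


def extract_nt_detail(activated: Repertoire, enrichment: pd.DataFrame) -> pd.DataFrame:
    """Nucleotide-level detail of the selected (is_ps) amino-acid sequences.

    One row per contributing nucleotide rearrangement, carrying gene calls
    and insertion counts; feeds the publicity/convergence library.
    """
    selected = set(enrichment.loc[enrichment["is_ps"], "aa_seq"])
    detail = activated.clonotypes[activated.clonotypes["aa_seq"].isin(selected)].copy()
    return detail.sort_values(["aa_seq", "nt_seq"], kind="mergesort").reset_index(drop=True)


@dataclass
class IndividualSelection:
    """Selection output for one individual: the enrichment table plus the
    nucleotide-level detail of the selected sequences."""

    individual_id: str
    enrichment: pd.DataFrame
    nt_detail: pd.DataFrame

    @classmethod
    def from_repertoires(
        cls,
        activated: Repertoire,
        resting: Repertoire,
        config: SelectionConfig | None = None,
    ) -> "IndividualSelection":
        enr = select_ps_cdr3(activated, resting, config)
        return cls(
            individual_id=activated.individual_id,
            enrichment=enr,
            nt_detail=extract_nt_detail(activated, enr),
        )
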