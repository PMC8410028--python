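"""Probing T-helper-subset repertoires for ps-CDR3s.

Bulk Th1/Th2/Th17/Tfh repertoires of an individual are probed for that
same individual's ps-CDR3 amino-acid sequences (autologous, exact string
match).  Reported per subset: the read-weighted fraction of subset reads
matching a ps-CDR3, a logistic regression of ps membership on per-
sequence read counts (clonal expansion), and pairwise Jaccard overlap of
the matched ps sets between subsets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import Repertoire, aggregate_by_aa

logger = logging.getLogger(__name__)

__all__ = [
    "SubsetProbeResult",
    "ExpansionResult",
    "probe_subsets",
    "expansion_regression",
    "subset_jaccard",
]


@dataclass
class SubsetProbeResult:
    """Per (individual, subset) ps read fractions and matched ps sets."""

    fractions: pd.DataFrame  # individual_id, subset, ps_read_fraction, totals
    matched: dict[tuple[str, str], frozenset[str]]  # (individual, subset) -> aa set
    per_sequence: pd.DataFrame  # individual, subset, aa_seq, count, is_ps

    def matched_by_subset(self, subset: str) -> frozenset[str]:
        out: set[str] = set()
        for (ind, sub), seqs in self.matched.items():
            if sub == subset:
                out |= seqs
        return frozenset(out)


def probe_subsets(
    subset_reps: Iterable[Repertoire],
    libraries: Mapping[str, Iterable[str]],
) -> SubsetProbeResult:
    """Probe subset repertoires for autologous ps-CDR3s.

    ``libraries`` maps individual id to that individual's ps-CDR3 amino-
    acid sequences.  Subset repertoires of individuals without a library
    are skipped with a warning.
    """
    frac_rows = []
    seq_rows = []
    matched: dict[tuple[str, str], frozenset[str]] = {}
    for rep in subset_reps:
        if rep.individual_id not in libraries:
            logger.warning("no ps library for individual %s; skipped", rep.individual_id)
            continue
        subset = rep.compartment.removeprefix("subset:")
        ps_set = set(libraries[rep.individual_id])
        agg = aggregate_by_aa(rep)
        agg["is_ps"] = agg["aa_seq"].isin(ps_set)
        total = int(agg["count"].sum())
        ps_reads = int(agg.loc[agg["is_ps"], "count"].sum())
        frac_rows.append(
            {
                "individual_id": rep.individual_id,
                "subset": subset,
                "ps_read_fraction": ps_reads / total if total else 0.0,
                "ps_reads": ps_reads,
                "total_reads": total,
            }
        )
        matched[(rep.individual_id, subset)] = frozenset(
            agg.loc[agg["is_ps"], "aa_seq"]
        )
        for rec in agg.itertuples(index=False):
            seq_rows.append(
                {
                    "individual_id": rep.individual_id,
                    "subset": subset,
                    "aa_seq": rec.aa_seq,
                    "count": rec.count,
                    "is_ps": rec.is_ps,
                }
            )
    return SubsetProbeResult(
        fractions=pd.DataFrame(frac_rows),
        matched=matched,
        per_sequence=pd.DataFrame(seq_rows),
    )


@dataclass(frozen=True)
class ExpansionResult:
    slope: float
    odds_ratio: float  # per unit read count
    p_value: float
    n: int
    separation_flag: bool


def expansion_regression(
    per_sequence: pd.DataFrame, *, log_counts: bool = False
) -> ExpansionResult:
    """Logistic regression of ps membership on per-sequence read counts.

    ``per_sequence`` needs ``count`` and ``is_ps`` columns (one row per
    unique sequence in the subset, possibly pooled over individuals).
    Complete or quasi-complete separation is flagged, not silently
    accepted.
    """
    y = per_sequence["is_ps"].astype(int).to_numpy()
    if y.min() == y.max():
        raise ValueError("need both ps and non-ps sequences for the regression")
    x = per_sequence["count"].to_numpy(dtype=float)
    if log_counts:
        x = np.log1p(x)
    X = sm.add_constant(x)
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(y, X).fit(disp=0)
        except Exception:  # PerfectSeparationError or singular matrix
            separation = True
            fit = sm.Logit(y, X).fit_regularized(alpha=1e-6, disp=0)
        for w in caught:
            if "separation" in str(w.message).lower() or "convergence" in str(
                w.message
            ).lower():
                separation = True
    slope = float(fit.params[1])
    try:
        p = float(fit.pvalues[1])
    except Exception:
        p = float("nan")
    return ExpansionResult(
        slope=slope,
        odds_ratio=float(np.exp(slope)),
        p_value=p,
        n=len(y),
        separation_flag=separation,
    )


def subset_jaccard(
    matched_sets: Mapping[str, Iterable[str]],
    publicity_labels: Mapping[str, bool] | None = None,
) -> dict[str, pd.DataFrame]:
    """Pairwise Jaccard matrices between subsets' matched ps sets.

    Returns matrices "overall" and, when ``publicity_labels`` (aa -> is
    public) is given, "public" and "private".  Cells where both sets are
    empty are NaN (undefined); the diagonal is 1 for non-empty sets.
    """
    subsets = sorted(matched_sets)
    if len(subsets) < 2:
        raise ValueError("need at least 2 subsets")
    sets = {s: set(matched_sets[s]) for s in subsets}

    def matrix(filter_fn) -> pd.DataFrame:
        filt = {s: {aa for aa in sets[s] if filter_fn(aa)} for s in subsets}
        mat = pd.DataFrame(index=subsets, columns=subsets, dtype=float)
        for a in subsets:
            for b in subsets:
                union = filt[a] | filt[b]
                if not union:
                    mat.loc[a, b] = np.nan
                else:
                    mat.loc[a, b] = len(filt[a] & filt[b]) / len(union)
        return mat

    out = {"overall": matrix(lambda aa: True)}
    if publicity_labels is not None:
        out["public"] = matrix(lambda aa: publicity_labels.get(aa, False))
        out["private"] = matrix(lambda aa: not publicity_labels.get(aa, False))
    return out
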