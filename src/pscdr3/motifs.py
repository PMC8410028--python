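"""Continuous and discontinuous k-mer motif mining in trimmed CDR3s.

The CDR3 stem residues (the conserved C104/position-105 pair at the start
and F118 at the end) are unlikely to contact peptide, so sequences are
trimmed to the central antigen-contact region before motif enumeration:
all continuous 3/4/5-mers plus gapped 4-mers (one internal wildcard) and
gapped 5-mers (one or two internal wildcards), so every pattern keeps at
least three conserved residues and never starts or ends with a gap.

Motif enrichment is read-weighted: the proportion of ps-CDR3 reads whose
trimmed sequence contains the pattern, divided by the same proportion in
the pooled resting reads.  A pattern is a *dominant motif* when it is at
least 10-fold enriched, occurs in at least 3 unique ps-CDR3s, and those
ps-CDR3s come from at least 3 individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "MotifConfig",
    "MotifResult",
    "trim_cdr3",
    "enumerate_nmers",
    "motif_enrichment",
]


@dataclass(frozen=True)
class MotifConfig:
    fold_threshold: float = 10.0
    min_cdr3s: int = 3
    min_individuals: int = 3
    trim_head: int = 2  # conserved C104 + position 105
    trim_tail: int = 1  # conserved F118
    include_single_gap_5mers: bool = True


def trim_cdr3(aa_seq: str, *, head: int = 2, tail: int = 1) -> str | None:
    """Trim a CDR3 to its central antigen-contact region.

    Removes the first ``head`` and last ``tail`` residues; returns None
    (sequence skipped) when the input is too short to leave anything.
    """
    if len(aa_seq) < head + tail + 1:
        return None
    return aa_seq[head : len(aa_seq) - tail]


def enumerate_nmers(trimmed: str, *, include_single_gap_5mers: bool = True) -> set[str]:
    """All motif patterns of a trimmed sequence.

    Continuous windows of size 3, 4 and 5; size-4 windows with one
    internal wildcard; size-5 windows with one (optional) or two internal
    wildcards.  Wildcards are written ``.`` and never occupy the first or
    last pattern position.  Duplicates within the sequence collapse.
    """
    if len(trimmed) < 3:
        raise ValueError("trimmed sequence shorter than 3 residues")
    patterns: set[str] = set()
    for n in (3, 4, 5):
        for start in range(len(trimmed) - n + 1):
            window = trimmed[start : start + n]
            patterns.add(window)
            internal = range(1, n - 1)
            if n == 4:
                gap_choices = [(i,) for i in internal]
            elif n == 5:
                gap_choices = list(combinations(internal, 2))
                if include_single_gap_5mers:
                    gap_choices += [(i,) for i in internal]
            else:
                gap_choices = []
            for gaps in gap_choices:
                chars = list(window)
                for g in gaps:
                    chars[g] = "."
                patterns.add("".join(chars))
    return patterns


@dataclass
class MotifResult:
    """Motif-enrichment table plus pattern membership maps."""

    table: pd.DataFrame
    ps_members: dict[str, frozenset[str]]  # pattern -> ps aa sequences containing it
    config: MotifConfig

    def dominant_map(self) -> dict[str, frozenset[str]]:
        dominant = set(self.table.loc[self.table["dominant"], "pattern"])
        return {p: self.ps_members[p] for p in dominant}


def _pattern_index(
    aa_counts: Mapping[str, float],
    config: MotifConfig,
    restrict_to: set[str] | None = None,
):
    """Map pattern -> (read count, set of aa sequences), counting each
    read once however many offsets match."""
    reads: dict[str, float] = {}
    members: dict[str, set[str]] = {}
    for aa, count in aa_counts.items():
        trimmed = trim_cdr3(aa, head=config.trim_head, tail=config.trim_tail)
        if trimmed is None or len(trimmed) < 3:
            continue
        pats = enumerate_nmers(
            trimmed, include_single_gap_5mers=config.include_single_gap_5mers
        )
        if restrict_to is not None:
            pats &= restrict_to
        for p in pats:
            reads[p] = reads.get(p, 0.0) + count
            members.setdefault(p, set()).add(aa)
    return reads, members


def motif_enrichment(
    ps_records: pd.DataFrame,
    resting_counts: pd.DataFrame,
    config: MotifConfig | None = None,
) -> MotifResult:
    """Read-weighted motif fold enrichment of ps-CDR3s over resting reads.

    ``ps_records`` has one row per (individual, ps amino-acid sequence)
    with columns ``aa_seq``, ``count`` (activated reads) and
    ``individual_id``; ``resting_counts`` has pooled resting ``aa_seq``
    and ``count``.  Patterns absent from resting get fold = +inf.
    """
    config = config or MotifConfig()
    if ps_records.empty or resting_counts.empty:
        raise ValueError("ps_records and resting_counts must be non-empty")

    ps_total = float(ps_records["count"].sum())
    rest_total = float(resting_counts["count"].sum())

    ps_aa_counts = ps_records.groupby("aa_seq")["count"].sum().to_dict()
    ps_reads, ps_members = _pattern_index(ps_aa_counts, config)

    # individuals contributing each pattern
    ind_by_aa = ps_records.groupby("aa_seq")["individual_id"].agg(set).to_dict()
    pattern_inds = {
        p: set().union(*(ind_by_aa[aa] for aa in aas)) for p, aas in ps_members.items()
    }

    rest_aa_counts = resting_counts.groupby("aa_seq")["count"].sum().to_dict()
    ps_patterns = set(ps_reads)
    rest_reads, _ = _pattern_index(rest_aa_counts, config, restrict_to=ps_patterns)

    rows = []
    for p in sorted(ps_patterns):
        psc = ps_reads[p]
        rc = rest_reads.get(p, 0.0)
        ps_prop = psc / ps_total
        rest_prop = rc / rest_total
        fold = float("inf") if rc == 0 else ps_prop / rest_prop
        n_cdr3 = len(ps_members[p])
        n_ind = len(pattern_inds[p])
        rows.append(
            {
                "pattern": p,
                "size": len(p),
                "n_wildcards": p.count("."),
                "ps_read_count": psc,
                "ps_read_proportion": ps_prop,
                "resting_read_count": rc,
                "resting_read_proportion": rest_prop,
                "fold_enrichment": fold,
                "n_unique_ps_cdr3s": n_cdr3,
                "n_individuals": n_ind,
                "dominant": (
                    fold >= config.fold_threshold
                    and n_cdr3 >= config.min_cdr3s
                    and n_ind >= config.min_individuals
                ),
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["dominant", "fold_enrichment", "pattern"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return MotifResult(
        table=table,
        ps_members={p: frozenset(s) for p, s in ps_members.items()},
        config=config,
    )
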