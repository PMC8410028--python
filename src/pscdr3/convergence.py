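"""Publicity, convergent recombination and encoding-probability matrices.

Pooling each individual's selected ps-CDR3s yields a cohort library keyed
by amino-acid sequence.  A sequence selected in two or more individuals
is *public*; one encoded by two or more distinct nucleotide
rearrangements is *convergent*.  Public clonotypes tend to lie closer to
germline (fewer non-templated N insertions at the V-D and D-J junctions)
and to show more convergence than private ones; both contrasts are tested
with two-sided Mann-Whitney U tests.  For a convergent sequence the
per-position encoding probability matrix tabulates, read across its
nucleotide variants, how often each codon (and each V gene) encodes each
amino-acid position — the numeric content of a sequence logo.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .enrichment import IndividualSelection

__all__ = [
    "PsCdr3Library",
    "build_library",
    "insertion_comparison",
    "convergence_comparison",
    "encoding_probability_matrix",
]


@dataclass
class PsCdr3Library:
    """Pooled ps-CDR3 library across individuals.

    aa_table   one row per unique amino-acid sequence: contributing
               individuals, publicity (their number), is_public,
               convergence (number of distinct nucleotide variants) and
               is_convergent, plus total pooled activated reads.
    variants   one row per unique nucleotide variant with gene calls,
               insertion counts and the individuals carrying it.
    """

    aa_table: pd.DataFrame
    variants: pd.DataFrame

    @property
    def n_sequences(self) -> int:
        return len(self.aa_table)

    @property
    def n_public(self) -> int:
        return int(self.aa_table["is_public"].sum())

    def publicity_of(self, aa_seq: str) -> int:
        row = self.aa_table.loc[self.aa_table["aa_seq"] == aa_seq]
        if row.empty:
            raise KeyError(aa_seq)
        return int(row["publicity"].iloc[0])


def build_library(
    selections: Iterable[IndividualSelection],
    *,
    variant_key_includes_v: bool = False,
) -> PsCdr3Library:
    """Pool per-individual selections into a cohort library.

    Nucleotide variants are keyed by nucleotide sequence alone by default;
    set ``variant_key_includes_v`` to also distinguish V gene calls (which
    matters when vendors trim rearrangements differently).
    """
    selections = list(selections)
    ids = [s.individual_id for s in selections]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate individual ids in selections")
    if not selections:
        raise ValueError("need at least one individual selection")

    rows = []
    for sel in selections:
        det = sel.nt_detail
        for rec in det.itertuples(index=False):
            rows.append(
                {
                    "aa_seq": rec.aa_seq,
                    "nt_seq": rec.nt_seq,
                    "v_call": rec.v_call,
                    "j_call": rec.j_call,
                    "count": rec.count,
                    "vd_insertions": rec.vd_insertions,
                    "dj_insertions": rec.dj_insertions,
                    "individual_id": sel.individual_id,
                }
            )
    pooled = pd.DataFrame(rows)
    if pooled.empty:
        raise ValueError("no selected sequences in any individual")

    key_cols = ["aa_seq", "nt_seq"] + (["v_call"] if variant_key_includes_v else [])
    variants = (
        pooled.groupby(key_cols, dropna=False, sort=True)
        .agg(
            v_call=("v_call", "first"),
            j_call=("j_call", "first"),
            count=("count", "sum"),
            vd_insertions=("vd_insertions", "first"),
            dj_insertions=("dj_insertions", "first"),
            individuals=("individual_id", lambda s: tuple(sorted(set(s)))),
        )
        .reset_index()
    )
    variants = variants.loc[:, ~variants.columns.duplicated()]
    ins_cols = ["vd_insertions", "dj_insertions"]
    variants["total_insertions"] = variants[ins_cols].sum(axis=1, min_count=2)

    aa_table = (
        pooled.groupby("aa_seq", sort=True)
        .agg(
            individuals=("individual_id", lambda s: tuple(sorted(set(s)))),
            count=("count", "sum"),
        )
        .reset_index()
    )
    conv = variants.groupby("aa_seq", sort=True)["nt_seq"].nunique()
    aa_table["publicity"] = aa_table["individuals"].map(len)
    aa_table["is_public"] = aa_table["publicity"] >= 2
    aa_table["convergence"] = aa_table["aa_seq"].map(conv).astype(int)
    aa_table["is_convergent"] = aa_table["convergence"] >= 2
    return PsCdr3Library(aa_table=aa_table, variants=variants)


def _mwu(public_vals: np.ndarray, private_vals: np.ndarray):
    if len(public_vals) == 0 or len(private_vals) == 0:
        return None
    stat, p = mannwhitneyu(public_vals, private_vals, alternative="two-sided")
    return {
        "u_stat": float(stat),
        "p_value": float(p),
        "median_public": float(np.median(public_vals)),
        "median_private": float(np.median(private_vals)),
        "n_public": int(len(public_vals)),
        "n_private": int(len(private_vals)),
    }


def insertion_comparison(library: PsCdr3Library) -> dict:
    """Public-vs-private contrasts of total, V-D and D-J insertion counts.

    One record per unique nucleotide variant (insertions are properties
    of rearrangements, not amino-acid sequences).  Returns a dict with
    per-contrast Mann-Whitney results, or ``{"available": False}`` when
    no variant carries insertion data.
    """
    public_aa = set(library.aa_table.loc[library.aa_table["is_public"], "aa_seq"])
    var = library.variants.copy()
    var["is_public"] = var["aa_seq"].isin(public_aa)
    out: dict = {"available": False}
    for name in ("total_insertions", "vd_insertions", "dj_insertions"):
        vals = var[[name, "is_public"]].dropna(subset=[name])
        res = _mwu(
            vals.loc[vals["is_public"], name].to_numpy(dtype=float),
            vals.loc[~vals["is_public"], name].to_numpy(dtype=float),
        )
        out[name] = res
        if res is not None:
            out["available"] = True
    return out


def convergence_comparison(library: PsCdr3Library) -> dict:
    """Public-vs-private contrast of convergence counts and the fraction
    of convergent sequences in each class."""
    tab = library.aa_table
    pub = tab.loc[tab["is_public"]]
    priv = tab.loc[~tab["is_public"]]
    result = {
        "fraction_convergent_public": (
            float(pub["is_convergent"].mean()) if len(pub) else float("nan")
        ),
        "fraction_convergent_private": (
            float(priv["is_convergent"].mean()) if len(priv) else float("nan")
        ),
        "n_convergent": int(tab["is_convergent"].sum()),
        "test": _mwu(
            pub["convergence"].to_numpy(dtype=float),
            priv["convergence"].to_numpy(dtype=float),
        ),
    }
    return result


def encoding_probability_matrix(
    aa_seq: str, variants: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-position codon probabilities (and V-gene probabilities) across
    the nucleotide variants of one amino-acid sequence.

    ``variants`` needs ``nt_seq`` and ``v_call`` columns.  Variants whose
    nucleotide length is not 3x the amino-acid length are skipped.  Rows
    of the codon matrix sum to 1 over the codons observed at each
    position.
    """
    usable = []
    for rec in variants.itertuples(index=False):
        if len(rec.nt_seq) == 3 * len(aa_seq):
            usable.append(rec)
    if not usable:
        raise ValueError(f"no length-consistent nucleotide variants for {aa_seq!r}")

    n_var = len(usable)
    counts: list[dict[str, int]] = [dict() for _ in aa_seq]
    for rec in usable:
        for pos in range(len(aa_seq)):
            codon = rec.nt_seq[3 * pos : 3 * pos + 3]
            counts[pos][codon] = counts[pos].get(codon, 0) + 1
    all_codons = sorted({c for d in counts for c in d})
    mat = pd.DataFrame(0.0, index=range(len(aa_seq)), columns=all_codons)
    for pos, d in enumerate(counts):
        for codon, c in d.items():
            mat.loc[pos, codon] = c / n_var
    mat.insert(0, "aa", list(aa_seq))

    v_counts = pd.Series([rec.v_call for rec in usable]).value_counts(dropna=False)
    v_probs = (v_counts / n_var).sort_index()
    return mat, v_probs
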