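"""CDR3 trimming, n-mer enumeration and read-weighted motif enrichment."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pscdr3 import enumerate_nmers, motif_enrichment, trim_cdr3
from pscdr3.motifs import MotifConfig


class TestTrimCdr3:
    def test_example(self):
        assert trim_cdr3("CASSLGETQYF") == "SSLGETQY"

    def test_degenerate_skipped(self):
        assert trim_cdr3("CAF") is None

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=4, max_size=25))
    @settings(max_examples=50, deadline=None)
    def test_length_arithmetic(self, seq):
        assert len(trim_cdr3(seq)) == len(seq) - 3


def brute_force_patterns(trimmed: str) -> set[str]:
    """Independent enumeration: every continuous window of size 3-5 plus
    every wildcard assignment over internal positions keeping >=3
    conserved residues."""
    out = set()
    for n in (3, 4, 5):
        for i in range(len(trimmed) - n + 1):
            w = trimmed[i : i + n]
            for k in range(0, n - 3 + 1):
                for gaps in combinations(range(1, n - 1), k):
                    chars = list(w)
                    for g in gaps:
                        chars[g] = "."
                    out.add("".join(chars))
    return out


class TestEnumerateNmers:
    def test_sslg_exact(self):
        assert enumerate_nmers("SSLG") == {"SSL", "SLG", "SSLG", "S.LG", "SS.G"}

    def test_aaa_collapses(self):
        assert enumerate_nmers("AAA") == {"AAA"}

    def test_counts_match_combinatorial_formula(self):
        # all-distinct letters so nothing collapses
        for L in range(5, 13):
            trimmed = "ADEFGHIKLMNP"[:L]
            pats = enumerate_nmers(trimmed)
            continuous = (L - 2) + (L - 3) + (L - 4)
            disc4 = 2 * (L - 3)
            disc5 = 6 * (L - 4)  # one or two internal wildcards
            assert len(pats) == continuous + disc4 + disc5
            assert pats == brute_force_patterns(trimmed)

    def test_no_edge_wildcards(self):
        for p in enumerate_nmers("ADEFGHIK"):
            assert p[0] != "." and p[-1] != "."
            assert len(p) - p.count(".") >= 3

    def test_excluding_single_gap_5mers(self):
        pats = enumerate_nmers("ADEFG", include_single_gap_5mers=False)
        five = {p for p in pats if len(p) == 5 and "." in p}
        assert all(p.count(".") == 2 for p in five)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            enumerate_nmers("AD")


def _ps_records(rows):
    return pd.DataFrame(rows, columns=["individual_id", "aa_seq", "count"])


class TestMotifEnrichment:
    def test_fold_arithmetic(self):
        # one ps sequence holding all 300 ps reads shares motif reads 30/300
        ps = _ps_records([("P1", "CASGRALYF", 30), ("P1", "CAWWWWWWF", 270)])
        rest = pd.DataFrame(
            {"aa_seq": ["CASGRALYF", "CAYYYYYYF"], "count": [10, 9990]}
        )
        res = motif_enrichment(ps, rest)
        row = res.table[res.table["pattern"] == "SGRAL"].iloc[0]
        assert row["fold_enrichment"] == pytest.approx((30 / 300) / (10 / 10000))

    def test_absent_from_resting_is_infinite(self):
        ps = _ps_records([("P1", "CASGRALYF", 10), ("P2", "CTSGRALWF", 10),
                          ("P3", "CNSGRALHF", 10)])
        rest = pd.DataFrame({"aa_seq": ["CAYYYYYYF"], "count": [1000]})
        res = motif_enrichment(ps, rest)
        row = res.table[res.table["pattern"] == "SGRAL"].iloc[0]
        assert np.isinf(row["fold_enrichment"])
        assert row["dominant"]  # 3 CDR3s, 3 individuals, fold >= 10

    def test_dominance_requires_three_individuals(self):
        ps = _ps_records([("P1", "CASGRALYF", 10), ("P1", "CTSGRALWF", 10),
                          ("P1", "CNSGRALHF", 10)])
        rest = pd.DataFrame({"aa_seq": ["CAYYYYYYF"], "count": [1000]})
        res = motif_enrichment(ps, rest)
        row = res.table[res.table["pattern"] == "SGRAL"].iloc[0]
        assert row["n_unique_ps_cdr3s"] == 3 and row["n_individuals"] == 1
        assert not row["dominant"]

    def test_scale_invariance(self):
        ps = _ps_records([("P1", "CASGRALYF", 3), ("P2", "CTSGRALWF", 7)])
        rest = pd.DataFrame({"aa_seq": ["CASGRALYF", "CAYYYYYYF"],
                             "count": [5, 995]})
        f1 = motif_enrichment(ps, rest).table.set_index("pattern")["fold_enrichment"]
        ps10 = ps.assign(count=ps["count"] * 10)
        rest10 = rest.assign(count=rest["count"] * 10)
        f2 = motif_enrichment(ps10, rest10).table.set_index("pattern")["fold_enrichment"]
        pd.testing.assert_series_equal(f1, f2)

    def test_dominant_members_satisfy_rules(self, small_cohort, small_selections):
        from pscdr3 import aggregate_by_aa

        ps = pd.concat(
            [
                sel.enrichment[sel.enrichment["is_ps"]]
                .rename(columns={"activated_count": "count"})[["aa_seq", "count"]]
                .assign(individual_id=ind)
                for ind, sel in small_selections.items()
            ],
            ignore_index=True,
        )
        rest = pd.concat(
            [
                aggregate_by_aa(c["resting"])
                for c in small_cohort.repertoires.values()
            ]
        ).groupby("aa_seq", as_index=False)["count"].sum()
        res = motif_enrichment(ps, rest)
        cfg = res.config
        ind_of = ps.groupby("aa_seq")["individual_id"].agg(set)
        for rec in res.table[res.table["dominant"]].itertuples(index=False):
            members = res.ps_members[rec.pattern]
            assert len(members) >= cfg.min_cdr3s
            inds = set().union(*(ind_of[aa] for aa in members))
            assert len(inds) >= cfg.min_individuals
            assert rec.fold_enrichment >= cfg.fold_threshold

    def test_planted_motif_recovered(self, small_cohort, small_selections):
        """The simulator's planted public motif comes out dominant."""
        from pscdr3 import aggregate_by_aa

        ps = pd.concat(
            [
                sel.enrichment[sel.enrichment["is_ps"]]
                .rename(columns={"activated_count": "count"})[["aa_seq", "count"]]
                .assign(individual_id=ind)
                for ind, sel in small_selections.items()
            ],
            ignore_index=True,
        )
        rest = pd.concat(
            [aggregate_by_aa(c["resting"]) for c in small_cohort.repertoires.values()]
        ).groupby("aa_seq", as_index=False)["count"].sum()
        res = motif_enrichment(ps, rest)
        planted = small_cohort.config.planted_motifs[0]
        dominant = set(res.table.loc[res.table["dominant"], "pattern"])
        assert planted in dominant
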