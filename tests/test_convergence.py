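"""Publicity, convergent recombination and encoding-probability matrices."""

import numpy as np
import pandas as pd
import pytest

from pscdr3 import (
    IndividualSelection,
    build_library,
    convergence_comparison,
    encoding_probability_matrix,
    insertion_comparison,
)


def make_selection(individual_id, variants):
    """variants: list of (aa, nt, vd_ins, dj_ins)."""
    nt_detail = pd.DataFrame(
        [
            {
                "nt_seq": nt,
                "aa_seq": aa,
                "v_call": "TRBV5",
                "d_call": "TRBD1",
                "j_call": "TRBJ2-1",
                "count": 5,
                "vd_insertions": vd,
                "dj_insertions": dj,
            }
            for aa, nt, vd, dj in variants
        ]
    )
    enrichment = pd.DataFrame(
        {"aa_seq": sorted({v[0] for v in variants}), "is_ps": True}
    )
    return IndividualSelection(
        individual_id=individual_id, enrichment=enrichment, nt_detail=nt_detail
    )


class TestBuildLibrary:
    def test_private_clone(self):
        lib = build_library([make_selection("P1", [("KFG", "AAATTTGGG", 1, 1)])])
        row = lib.aa_table.iloc[0]
        assert row["publicity"] == 1 and not row["is_public"]

    def test_publicity_counts_distinct_individuals(self):
        sels = [
            make_selection(f"P{i}", [("KFG", "AAATTTGGG", 1, 1)]) for i in range(8)
        ] + [make_selection("P8", [("GFK", "GGGTTTAAA", 2, 2)])]
        lib = build_library(sels)
        assert lib.publicity_of("KFG") == 8
        assert lib.publicity_of("GFK") == 1

    def test_convergence_two_nt_variants(self):
        lib = build_library(
            [
                make_selection(
                    "P1",
                    [("KFG", "AAATTTGGG", 1, 1), ("KFG", "AAGTTTGGG", 2, 0)],
                )
            ]
        )
        row = lib.aa_table.iloc[0]
        assert row["convergence"] == 2 and row["is_convergent"]

    def test_duplicate_individual_ids_rejected(self):
        sel = make_selection("P1", [("KFG", "AAATTTGGG", 1, 1)])
        with pytest.raises(ValueError):
            build_library([sel, sel])

    def test_merge_order_invariance(self):
        sels = [
            make_selection("P1", [("KFG", "AAATTTGGG", 1, 1)]),
            make_selection("P2", [("KFG", "AAGTTTGGG", 0, 2), ("GFK", "GGGTTTAAA", 3, 3)]),
            make_selection("P3", [("KFG", "AAATTTGGG", 1, 1)]),
        ]
        a = build_library(sels).aa_table
        b = build_library(reversed(sels)).aa_table
        pd.testing.assert_frame_equal(a, b)

    def test_cohort_library_truth(self, small_cohort, small_library):
        """Publicity of recovered public clones never exceeds the number of
        individuals the simulator spiked them into."""
        spiked_in = {}
        for t in small_cohort.truth.values():
            pub = t.table[t.table["is_public"]]
            for aa in pub["aa_seq"]:
                spiked_in[aa] = spiked_in.get(aa, 0) + 1
        for rec in small_library.aa_table.itertuples(index=False):
            if rec.aa_seq in spiked_in:
                assert rec.publicity <= spiked_in[rec.aa_seq]


class TestInsertionComparison:
    def _library_with_insertion_gap(self, rng, n=40):
        sels = []
        # public clones in 2 individuals with low insertions
        pub = [(f"K{i:02d}FG", f"AA{i:02d}", int(a), int(b))
               for i, (a, b) in enumerate(rng.poisson(1.5, (n, 2)))]
        priv1 = [(f"M{i:02d}FG", f"CC{i:02d}", int(a), int(b))
                 for i, (a, b) in enumerate(rng.poisson(3.5, (n, 2)))]
        sels.append(make_selection("P1", pub + priv1))
        sels.append(make_selection("P2", pub))
        return build_library(sels)

    def test_public_fewer_insertions(self):
        rng = np.random.default_rng(12)
        res = insertion_comparison(self._library_with_insertion_gap(rng))
        assert res["available"]
        t = res["total_insertions"]
        assert t["median_public"] < t["median_private"]
        assert t["p_value"] < 0.01

    def test_total_is_sum(self, small_library):
        var = small_library.variants.dropna(
            subset=["vd_insertions", "dj_insertions"]
        )
        assert (
            var["total_insertions"] == var["vd_insertions"] + var["dj_insertions"]
        ).all()

    def test_all_missing_reported_unavailable(self):
        sel = make_selection("P1", [("KFG", "AAATTTGGG", None, None),
                                    ("GFK", "GGGTTTAAA", None, None)])
        sel.nt_detail["vd_insertions"] = pd.array([None, None], dtype="Int64")
        sel.nt_detail["dj_insertions"] = pd.array([None, None], dtype="Int64")
        res = insertion_comparison(build_library([sel]))
        assert not res["available"]


class TestConvergenceComparison:
    def test_no_convergence(self):
        lib = build_library([make_selection("P1", [("KFG", "AAATTTGGG", 1, 1),
                                                   ("GFK", "GGGTTTAAA", 1, 1)])])
        res = convergence_comparison(lib)
        assert res["n_convergent"] == 0
        assert res["fraction_convergent_private"] == 0.0

    def test_hand_built_medians(self):
        sels = [
            make_selection(
                "P1",
                [("KFG", "AAATTTGGA", 1, 1), ("KFG", "AAGTTTGGA", 1, 1),
                 ("KFG", "AAATTCGGA", 1, 1), ("GFK", "GGGTTTAAA", 1, 1)],
            ),
            make_selection("P2", [("KFG", "AAATTTGGA", 1, 1)]),
        ]
        res = convergence_comparison(build_library(sels))
        assert res["test"]["median_public"] == 3
        assert res["test"]["median_private"] == 1


class TestEncodingProbabilityMatrix:
    def test_single_variant_all_ones(self):
        variants = pd.DataFrame({"nt_seq": ["AAATTTGGA"], "v_call": ["TRBV5"]})
        mat, vprobs = encoding_probability_matrix("KFG", variants)
        assert (mat.drop(columns="aa").max(axis=1) == 1.0).all()
        assert vprobs.iloc[0] == 1.0

    def test_two_variants_split_one_codon(self):
        variants = pd.DataFrame(
            {"nt_seq": ["AAATTTGGA", "AAGTTTGGA"], "v_call": ["TRBV5", "TRBV6"]}
        )
        mat, vprobs = encoding_probability_matrix("KFG", variants)
        num = mat.drop(columns="aa")
        assert sorted(num.loc[0][num.loc[0] > 0]) == [0.5, 0.5]
        assert num.loc[1].max() == 1.0
        assert vprobs.tolist() == [0.5, 0.5]

    def test_rows_sum_to_one_and_matches_tabulation(self):
        rng = np.random.default_rng(3)
        from pscdr3.simulate import _CODONS

        aa = "KFGW"
        variants = []
        for _ in range(5):
            variants.append("".join(
                _CODONS[c][rng.integers(0, len(_CODONS[c]))] for c in aa
            ))
        df = pd.DataFrame({"nt_seq": variants, "v_call": ["TRBV5"] * 5})
        mat, _ = encoding_probability_matrix(aa, df)
        num = mat.drop(columns="aa")
        np.testing.assert_allclose(num.sum(axis=1), 1.0)
        # brute-force frequency tabulation at position 0
        from collections import Counter

        c = Counter(v[0:3] for v in variants)
        for codon, n in c.items():
            assert num.loc[0, codon] == pytest.approx(n / 5)

    def test_length_mismatch_skipped(self):
        variants = pd.DataFrame(
            {"nt_seq": ["AAATTTGGA", "AAATTT"], "v_call": ["TRBV5", "TRBV6"]}
        )
        mat, _ = encoding_probability_matrix("KFG", variants)
        assert mat.drop(columns="aa").loc[0].max() == 1.0  # only 1 usable variant

    def test_no_usable_variant_raises(self):
        variants = pd.DataFrame({"nt_seq": ["AAATTT"], "v_call": ["TRBV5"]})
        with pytest.raises(ValueError):
            encoding_probability_matrix("KFG", variants)
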