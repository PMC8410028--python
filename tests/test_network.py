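"""Homology network construction, statistics, baselines and GML export."""

import numpy as np
import pandas as pd
import pytest

from pscdr3 import build_network, degree_statistics, export_gml, import_gml
from pscdr3.network import levenshtein1_pairs, resampled_edge_baseline
from tests.conftest import levenshtein_dp, make_repertoire
from tests.test_convergence import make_selection
from pscdr3 import build_library


def _library(variant_specs):
    """variant_specs: {aa: (n_variants, individual_ids)}"""
    sels = {}
    for aa, (n_var, inds) in variant_specs.items():
        for k, ind in enumerate(inds):
            base = f"{aa}_nt"
            sels.setdefault(ind, []).append(
                (aa, f"{base}{0}", 1, 1)
            )
        # extra nt variants on the first individual
        for v in range(1, n_var):
            sels[inds[0]].append((aa, f"{base}{v}", 1, 1))
    return build_library(
        [make_selection(ind, variants) for ind, variants in sels.items()]
    )


class TestBuildNetwork:
    def test_hand_example(self):
        lib = _library(
            {
                "CASSLGETQYF": (2, ["P1"]),
                "CASSLGETQFF": (1, ["P1"]),
                "CASSPWDTHKL": (1, ["P1"]),
            }
        )
        net = build_network(lib)
        assert net.graph.has_edge("CASSLGETQYF", "CASSLGETQFF")
        assert net.graph.edges["CASSLGETQYF", "CASSLGETQFF"]["etype"] == "levenshtein"
        assert net.self_edges["CASSLGETQYF"] == 1
        assert net.total_edges == 2
        assert not net.in_graph("CASSPWDTHKL")

    def test_both_edge_deduplicated(self):
        lib = _library({"CASGRALYF": (1, ["P1"]), "CASGRALWF": (1, ["P1"])})
        motifs = {"SGRAL": frozenset({"CASGRALYF", "CASGRALWF"})}
        net = build_network(lib, motifs)
        assert net.n_pair_edges == 1
        assert net.graph.edges["CASGRALYF", "CASGRALWF"]["etype"] == "both"

    def test_motif_only_edge(self):
        lib = _library({"CASGRALYFAA": (1, ["P1"]), "CTSGRALWW": (1, ["P1"])})
        motifs = {"SGRAL": frozenset({"CASGRALYFAA", "CTSGRALWW"})}
        net = build_network(lib, motifs)
        assert net.graph.edges["CASGRALYFAA", "CTSGRALWW"]["etype"] == "motif"

    def test_edge_set_matches_brute_force(self):
        rng = np.random.default_rng(13)
        alphabet = np.array(list("ADEFG"))  # small alphabet forces neighbors
        seqs = list({
            "".join(rng.choice(alphabet, rng.integers(6, 10))) for _ in range(300)
        })
        pairs = levenshtein1_pairs(seqs)
        brute = {
            tuple(sorted((a, b)))
            for i, a in enumerate(seqs)
            for b in seqs[i + 1 :]
            if levenshtein_dp(a, b) == 1
        }
        assert pairs == brute

    def test_insertion_order_invariance(self):
        specs = {
            "CASSLGETQYF": (2, ["P1", "P2"]),
            "CASSLGETQFF": (1, ["P2"]),
            "CASSLGETQWF": (3, ["P1"]),
        }
        n1 = build_network(_library(specs)).total_edges
        n2 = build_network(_library(dict(reversed(list(specs.items()))))).total_edges
        assert n1 == n2


class TestDegreeStatistics:
    def test_all_isolated(self):
        lib = _library({"CAAAAAAAF": (1, ["P1"]), "CWWWWWWWWWF": (1, ["P1"])})
        net = build_network(lib)
        stats = degree_statistics(net)
        assert stats.membership_fraction_private == 0.0
        assert stats.degree_p is None

    def test_hand_medians(self):
        # star of public hubs vs private leaves
        lib = _library(
            {
                "CAAAAAF": (3, ["P1", "P2"]),   # public, 2 self-edges
                "CAAAAWF": (3, ["P1", "P2"]),   # public, lev-1 to the hub
                "CAAAATF": (1, ["P1"]),
                "CAAAASF": (1, ["P1"]),
            }
        )
        net = build_network(lib)
        stats = degree_statistics(net)
        assert stats.degree_median_public > stats.degree_median_private


class TestResampledEdgeBaseline:
    def _pool(self, rng, n=120):
        alphabet = np.array(list("ADEFGHIK"))
        rows = []
        for i in range(n):
            rows.append(
                {
                    "individual_id": f"P{i % 4}",
                    "aa_seq": "".join(rng.choice(alphabet, rng.integers(8, 12))),
                    "count": int(rng.integers(1, 50)),
                    "n_nt_variants": 1,
                }
            )
        return pd.DataFrame(rows)

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        pool = self._pool(rng)
        kw = dict(n_resamples=10, seed=5, motif_mode="none")
        b1 = resampled_edge_baseline(pool, 40, 10, **kw)
        b2 = resampled_edge_baseline(pool, 40, 10, **kw)
        np.testing.assert_array_equal(b1.counts, b2.counts)

    def test_observed_at_mean_gives_zero_z(self):
        rng = np.random.default_rng(2)
        pool = self._pool(rng)
        b = resampled_edge_baseline(pool, 40, 10, n_resamples=20, seed=5,
                                    motif_mode="none")
        if b.sd > 0:
            b2 = resampled_edge_baseline(pool, 40, int(round(b.mean)),
                                         n_resamples=20, seed=5, motif_mode="none")
            assert abs(b2.z) == pytest.approx(
                abs(int(round(b.mean)) - b.mean) / b.sd, abs=1e-12
            )

    def test_zero_sd_reported_undefined(self):
        pool = pd.DataFrame(
            {
                "individual_id": ["P1"] * 3,
                "aa_seq": ["CAAAAAAAF", "CWWWWWWWF", "CYYYYYYYF"],
                "count": [1, 1, 1],
                "n_nt_variants": [1, 1, 1],
            }
        )
        b = resampled_edge_baseline(pool, 3, 5, n_resamples=10, seed=1,
                                    motif_mode="none")
        assert b.sd == 0 and b.z is None and b.p_value is None

    def test_oversized_sample_rejected(self):
        pool = self._pool(np.random.default_rng(0), n=10)
        with pytest.raises(ValueError):
            resampled_edge_baseline(pool, 11, 0, n_resamples=2, seed=0,
                                    motif_mode="none")


class TestGmlRoundTrip:
    def test_round_trip_preserves_edges(self, tmp_path):
        lib = _library(
            {
                "CASSLGETQYF": (3, ["P1", "P2"]),
                "CASSLGETQFF": (1, ["P1"]),
                "CASSPWDTHKL": (1, ["P1"]),
            }
        )
        net = build_network(lib)
        path = export_gml(net, tmp_path / "net.gml")
        back = import_gml(path)
        assert set(back.graph.edges) == set(net.graph.edges)
        assert back.self_edges == {k: v for k, v in net.self_edges.items()}
        assert back.total_edges == net.total_edges

    def test_edgeless_network_valid(self, tmp_path):
        lib = _library({"CAAAAAAAF": (1, ["P1"]), "CWWWWWWWWWF": (1, ["P1"])})
        net = build_network(lib)
        back = import_gml(export_gml(net, tmp_path / "net.gml"))
        assert back.graph.number_of_nodes() == 2
        assert back.total_edges == 0

    def test_counts_preserved_large(self, tmp_path, small_library):
        net = build_network(small_library)
        back = import_gml(export_gml(net, tmp_path / "net.gml"))
        assert back.graph.number_of_nodes() == net.graph.number_of_nodes()
        assert back.n_pair_edges == net.n_pair_edges
        assert back.n_self_edges == net.n_self_edges
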