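"""Homology network of ps-CDR3 amino-acid sequences.

Each unique ps-CDR3 is a node.  A pair edge connects two nodes when their
Levenshtein distance is 1 or when they share a dominant motif (a pair
connected by both rules carries type "both" and counts once).  Every
additional nucleotide variant of a sequence adds one self-edge, so a node
with convergence c carries c - 1 self-edges.  The degree of a node counts
its pair edges plus its self-edges (one each); a node is "in the graph"
when its degree is at least 1.  Observed edge totals are compared to the
edge counts of equal-sized random resamplings from a background pool via
a Z test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu, norm

from .convergence import PsCdr3Library
from .motifs import MotifConfig, motif_enrichment

__all__ = [
    "Cdr3Network",
    "build_network",
    "levenshtein1_pairs",
    "degree_statistics",
    "resampled_edge_baseline",
    "EdgeBaseline",
    "export_gml",
    "import_gml",
]


@dataclass
class Cdr3Network:
    """Pair-edge graph plus per-node self-edge counts."""

    graph: nx.Graph  # nodes: aa sequences; pair edges with attr "etype"
    self_edges: dict[str, int]

    @property
    def n_pair_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_self_edges(self) -> int:
        return sum(self.self_edges.values())

    @property
    def total_edges(self) -> int:
        return self.n_pair_edges + self.n_self_edges

    def degree(self, node: str) -> int:
        return self.graph.degree(node) + self.self_edges.get(node, 0)

    def degrees(self) -> pd.Series:
        return pd.Series({n: self.degree(n) for n in self.graph.nodes}, dtype=int)

    def in_graph(self, node: str) -> bool:
        return self.degree(node) >= 1


def levenshtein1_pairs(seqs: Sequence[str]) -> set[tuple[str, str]]:
    """All unordered pairs of distinct sequences at Levenshtein distance 1.

    Equal length -> Hamming distance 1; length difference 1 -> the
    shorter equals the longer with one character deleted.  Larger length
    gaps cannot give distance 1.
    """
    pairs: set[tuple[str, str]] = set()
    by_len: dict[int, list[str]] = {}
    for s in set(seqs):
        by_len.setdefault(len(s), []).append(s)
    for length, group in by_len.items():
        group = sorted(group)
        if len(group) >= 2:
            arr = np.frombuffer(
                "".join(group).encode("ascii"), dtype=np.uint8
            ).reshape(len(group), length)
            dist = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
            ii, jj = np.nonzero(np.triu(dist == 1, k=1))
            for i, j in zip(ii.tolist(), jj.tolist()):
                pairs.add(tuple(sorted((group[i], group[j]))))
        shorter = set(by_len.get(length - 1, []))
        if shorter:
            for s in group:
                seen = set()
                for k in range(length):
                    d = s[:k] + s[k + 1 :]
                    if d in shorter and d not in seen:
                        seen.add(d)
                        pairs.add(tuple(sorted((s, d))))
    return pairs


def build_network(
    library: PsCdr3Library,
    dominant_motifs: Mapping[str, frozenset[str]] | None = None,
) -> Cdr3Network:
    """Build the homology graph from a library and its dominant motifs.

    ``dominant_motifs`` maps each dominant pattern to the set of ps-CDR3
    amino-acid sequences containing it (``MotifResult.dominant_map()``);
    pass None to build a Levenshtein + convergence graph only.
    """
    if library.aa_table.empty:
        raise ValueError("library is empty")
    nodes = library.aa_table["aa_seq"].tolist()
    g = nx.Graph()
    for rec in library.aa_table.itertuples(index=False):
        g.add_node(
            rec.aa_seq,
            publicity=int(rec.publicity),
            public=bool(rec.is_public),
            convergence=int(rec.convergence),
            individuals=";".join(rec.individuals),
        )
    lev = levenshtein1_pairs(nodes)
    for u, v in lev:
        g.add_edge(u, v, etype="levenshtein")
    if dominant_motifs:
        node_set = set(nodes)
        for members in dominant_motifs.values():
            mem = sorted(members & node_set)
            for i in range(len(mem)):
                for j in range(i + 1, len(mem)):
                    u, v = mem[i], mem[j]
                    if g.has_edge(u, v):
                        if g.edges[u, v]["etype"] == "levenshtein":
                            g.edges[u, v]["etype"] = "both"
                    else:
                        g.add_edge(u, v, etype="motif")
    self_edges = {
        rec.aa_seq: int(rec.convergence) - 1
        for rec in library.aa_table.itertuples(index=False)
    }
    return Cdr3Network(graph=g, self_edges=self_edges)


@dataclass
class DegreeStatistics:
    membership_table: np.ndarray  # rows public/private, cols in/out of graph
    membership_fraction_public: float
    membership_fraction_private: float
    membership_p: float | None
    degree_median_public: float | None
    degree_median_private: float | None
    degree_p: float | None


def degree_statistics(net: Cdr3Network) -> DegreeStatistics:
    """Public-vs-private graph membership (Fisher exact) and node degree
    (Mann-Whitney U, over in-graph nodes) contrasts."""
    rows = []
    for n, data in net.graph.nodes(data=True):
        rows.append((n, data["public"], net.degree(n)))
    df = pd.DataFrame(rows, columns=["aa_seq", "public", "degree"])
    df["in_graph"] = df["degree"] >= 1

    pub = df[df["public"]]
    priv = df[~df["public"]]
    table = np.array(
        [
            [int(pub["in_graph"].sum()), int((~pub["in_graph"]).sum())],
            [int(priv["in_graph"].sum()), int((~priv["in_graph"]).sum())],
        ]
    )
    frac_pub = float(pub["in_graph"].mean()) if len(pub) else 0.0
    frac_priv = float(priv["in_graph"].mean()) if len(priv) else 0.0
    membership_p = None
    if len(pub) and len(priv):
        membership_p = float(fisher_exact(table, alternative="two-sided")[1])

    pub_deg = pub.loc[pub["in_graph"], "degree"].to_numpy(dtype=float)
    priv_deg = priv.loc[priv["in_graph"], "degree"].to_numpy(dtype=float)
    degree_p = med_pub = med_priv = None
    if len(pub_deg):
        med_pub = float(np.median(pub_deg))
    if len(priv_deg):
        med_priv = float(np.median(priv_deg))
    if len(pub_deg) and len(priv_deg):
        degree_p = float(mannwhitneyu(pub_deg, priv_deg, alternative="two-sided")[1])
    return DegreeStatistics(
        membership_table=table,
        membership_fraction_public=frac_pub,
        membership_fraction_private=frac_priv,
        membership_p=membership_p,
        degree_median_public=med_pub,
        degree_median_private=med_priv,
        degree_p=degree_p,
    )


@dataclass
class EdgeBaseline:
    counts: np.ndarray
    mean: float
    sd: float
    observed: int
    z: float | None
    p_value: float | None


def _edges_of_sample(
    sample: pd.DataFrame,
    motif_mode: str,
    motifs: Mapping[str, frozenset[str]] | None,
    resting_ref: pd.DataFrame | None,
    motif_config: MotifConfig,
) -> int:
    per_aa = sample.groupby("aa_seq").agg(
        n_nt_variants=("n_nt_variants", "sum")
    )
    seqs = per_aa.index.tolist()
    pair_edges = set(levenshtein1_pairs(seqs))
    if motif_mode == "recompute":
        if resting_ref is None:
            raise ValueError("motif_mode='recompute' needs a resting reference")
        result = motif_enrichment(sample, resting_ref, motif_config)
        motif_map = result.dominant_map()
    elif motif_mode == "fixed":
        motif_map = {}
        if motifs:
            from .motifs import enumerate_nmers, trim_cdr3

            pattern_set = set(motifs)
            for aa in seqs:
                trimmed = trim_cdr3(
                    aa, head=motif_config.trim_head, tail=motif_config.trim_tail
                )
                if trimmed is None or len(trimmed) < 3:
                    continue
                for p in enumerate_nmers(trimmed) & pattern_set:
                    motif_map.setdefault(p, set()).add(aa)
    elif motif_mode == "none":
        motif_map = {}
    else:
        raise ValueError("motif_mode must be 'recompute', 'fixed' or 'none'")
    for members in motif_map.values():
        mem = sorted(members)
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                pair_edges.add((mem[i], mem[j]))
    self_edges = int((per_aa["n_nt_variants"] - 1).clip(lower=0).sum())
    return len(pair_edges) + self_edges


def resampled_edge_baseline(
    pool: pd.DataFrame,
    size: int,
    observed_edges: int,
    *,
    n_resamples: int = 100,
    seed: int,
    motif_mode: str = "recompute",
    motifs: Mapping[str, frozenset[str]] | None = None,
    resting_ref: pd.DataFrame | None = None,
    motif_config: MotifConfig | None = None,
) -> EdgeBaseline:
    """Edge counts of equal-sized random resamplings from a background pool.

    ``pool`` has one row per (individual, amino-acid sequence) with
    columns ``individual_id``, ``aa_seq``, ``count`` and
    ``n_nt_variants``.  Each resample draws ``size`` rows without
    replacement and counts pair edges (Levenshtein-1 plus motif edges per
    ``motif_mode``) and self-edges (one per extra nucleotide variant).
    Returns the baseline distribution and a two-sided Z test of the
    observed total against it (z undefined when the baseline sd is 0).
    """
    motif_config = motif_config or MotifConfig()
    if size > len(pool):
        raise ValueError("resample size exceeds pool")
    rng = np.random.default_rng(seed)
    counts = np.empty(n_resamples, dtype=int)
    for b in range(n_resamples):
        idx = rng.choice(len(pool), size=size, replace=False)
        sample = pool.iloc[idx]
        counts[b] = _edges_of_sample(
            sample, motif_mode, motifs, resting_ref, motif_config
        )
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if n_resamples > 1 else 0.0
    if sd > 0:
        z = (observed_edges - mean) / sd
        p = float(2 * norm.sf(abs(z)))
    else:
        z = p = None
    return EdgeBaseline(
        counts=counts, mean=mean, sd=sd, observed=observed_edges, z=z, p_value=p
    )


def export_gml(net: Cdr3Network, path: str | Path) -> Path:
    """Write the network as GML (self-edges materialized as loop edges)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    g = nx.MultiGraph()
    for n, data in net.graph.nodes(data=True):
        g.add_node(n, **{k: int(v) if isinstance(v, bool) else v for k, v in data.items()})
    for u, v, data in net.graph.edges(data=True):
        g.add_edge(u, v, etype=data["etype"])
    for n, k in net.self_edges.items():
        for _ in range(k):
            g.add_edge(n, n, etype="convergence")
    nx.write_gml(g, path)
    return path


def import_gml(path: str | Path) -> Cdr3Network:
    """Read back a network written by :func:`export_gml`."""
    g = nx.read_gml(str(path))
    pair = nx.Graph()
    self_edges: dict[str, int] = {}
    for n, data in g.nodes(data=True):
        pair.add_node(n, **data)
        self_edges[n] = 0
    for u, v, data in g.edges(data=True):
        if u == v:
            self_edges[u] += 1
        else:
            pair.add_edge(u, v, etype=data.get("etype", "levenshtein"))
    return Cdr3Network(graph=pair, self_edges=self_edges)
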