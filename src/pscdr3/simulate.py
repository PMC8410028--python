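"""Synthetic paired activated/resting repertoires with known ground truth.

The generator emulates the statistical structure the selection procedure
assumes: a heavy-tailed (Zipf-like) background of bystander clones whose
proportions are shared between the activated and resting compartments,
plus a spiked subset of clones whose activated-compartment proportions
are multiplied by an enrichment factor and renormalized.  A shared pool
of *public* spiked clones recurs across individuals; public clones carry
fewer non-templated insertions, several codon-degenerate nucleotide
variants (convergent recombination) and an optional planted amino-acid
motif, mirroring the hallmarks of antigen selection that the downstream
characterization modules are built to detect.

All randomness flows from a single seed through spawned generator
streams: the public pool uses one stream and each individual another, so
``simulate_individual(config, i)`` is reproducible on its own and
consistent with ``simulate_cohort``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .io import IMMUNOSEQ_COLUMNS, Repertoire

__all__ = [
    "SimConfig",
    "Truth",
    "CohortSim",
    "simulate_individual",
    "simulate_cohort",
    "write_cohort",
    "simulate_subset",
]

# 18-letter alphabet for the random stem: no C (avoids spurious trim
# anchors inside the stem) and no X/stop by construction.
_STEM_ALPHABET = np.frombuffer(b"ADEFGHIKLMNPQRSTVWY", dtype="S1")
_STEM_ALPHABET = _STEM_ALPHABET[_STEM_ALPHABET != b"C"]

_table = CodonTable.unambiguous_dna_by_id[1]
_CODONS: dict[str, list[str]] = {}
for codon, aa in _table.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()


@dataclass(frozen=True)
class SimConfig:
    """Cohort simulation parameters (defaults are the study conditions).

    27 individuals with 2000 clones each under a Zipf(1.5) abundance law,
    100 spiked clones per individual at 10-fold activated enrichment and
    1e5 reads per compartment.  Public spiked clones come from a shared
    pool of 10, each included per individual with probability 0.3, carry
    3 nucleotide variants and Poisson insertions with mean 1.5 per
    junction (private: 3.5), and share a planted motif.
    """

    n_individuals: int = 27
    n_background_clones: int = 2000
    zipf_exponent: float = 1.5
    n_spiked_clones: int = 100
    enrichment_factor: float = 10.0
    depth_activated: int = 100_000
    depth_resting: int = 100_000
    public_pool_size: int = 10
    public_inclusion_prob: float = 0.3
    n_variants_public: int = 3
    insertion_mean_public: float = 1.5  # per junction (V-D and D-J)
    insertion_mean_private: float = 3.5
    planted_motifs: tuple[str, ...] = ("SGRAL",)
    min_len: int = 10  # full CDR3 length incl. conserved C...F
    max_len: int = 18
    seed: int = 0

    def __post_init__(self) -> None:
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if not 0 <= self.public_inclusion_prob <= 1:
            raise ValueError("public_inclusion_prob must be in [0, 1]")
        if self.n_spiked_clones > self.n_background_clones:
            raise ValueError("more spiked clones than clones")
        if min(self.n_individuals, self.n_background_clones,
               self.depth_activated, self.depth_resting) < 1:
            raise ValueError("counts must be positive")


@dataclass
class Truth:
    """Ground truth for one simulated individual."""

    individual_id: str
    table: pd.DataFrame  # one row per spiked clone

    @property
    def enriched_aa(self) -> frozenset[str]:
        """Truly enriched aa sequences that were actually emitted in the
        activated compartment (truth is a subset of observed sequences)."""
        t = self.table
        return frozenset(t.loc[t["activated_emitted"], "aa_seq"])


def _random_stems(rng: np.random.Generator, n: int, min_len: int, max_len: int) -> list[str]:
    lengths = rng.integers(min_len - 2, max_len - 1, size=n)  # stem excl. C and F
    letters = rng.choice(_STEM_ALPHABET, size=int(lengths.sum()))
    stems = []
    pos = 0
    for L in lengths:
        stems.append(letters[pos : pos + L].tobytes().decode("ascii"))
        pos += L
    return stems


def _unique_aa(rng: np.random.Generator, n: int, cfg: SimConfig,
               taken: set[str] | None = None) -> list[str]:
    taken = set(taken or ())
    out: list[str] = []
    while len(out) < n:
        for stem in _random_stems(rng, n - len(out), cfg.min_len, cfg.max_len):
            aa = "C" + stem + "F"
            if aa not in taken:
                taken.add(aa)
                out.append(aa)
    return out


def _reverse_translate(rng: np.random.Generator, aa_seqs: Sequence[str]) -> list[str]:
    """One random codon-degenerate nucleotide sequence per amino-acid seq."""
    out = []
    for aa in aa_seqs:
        out.append(
            "".join(
                _CODONS[ch][rng.integers(0, len(_CODONS[ch]))] for ch in aa
            )
        )
    return out


def _plant_motif(rng: np.random.Generator, stem: str, motif: str) -> str:
    if len(stem) <= len(motif):
        return motif
    pos = rng.integers(0, len(stem) - len(motif) + 1)
    return stem[:pos] + motif + stem[pos + len(motif) :]


@dataclass
class _PublicClone:
    aa_seq: str
    nt_variants: list[str]
    v_calls: list[str]
    j_call: str
    vd_insertions: list[int]
    dj_insertions: list[int]
    motif: str | None


def _public_pool(config: SimConfig) -> list[_PublicClone]:
    """The cohort-shared pool of public spiked clones (own seed stream)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    pool: list[_PublicClone] = []
    taken: set[str] = set()
    motifs = config.planted_motifs or ()
    for k in range(config.public_pool_size):
        motif = motifs[k % len(motifs)] if motifs else None
        while True:
            stem = _random_stems(rng, 1, config.min_len, config.max_len)[0]
            if motif is not None:
                stem = _plant_motif(rng, stem, motif)
            aa = "C" + stem + "F"
            if aa not in taken:
                taken.add(aa)
                break
        n_var = config.n_variants_public
        variants: list[str] = []
        while len(variants) < n_var:
            nt = _reverse_translate(rng, [aa])[0]
            if nt not in variants:
                variants.append(nt)
        pool.append(
            _PublicClone(
                aa_seq=aa,
                nt_variants=variants,
                v_calls=[f"TRBV{rng.integers(2, 31)}" for _ in range(n_var)],
                j_call=f"TRBJ{rng.integers(1, 3)}-{rng.integers(1, 7)}",
                vd_insertions=rng.poisson(config.insertion_mean_public, n_var).tolist(),
                dj_insertions=rng.poisson(config.insertion_mean_public, n_var).tolist(),
                motif=motif,
            )
        )
    return pool


def simulate_individual(
    config: SimConfig, individual_index: int
) -> tuple[Repertoire, Repertoire, Truth]:
    """Simulate one individual's paired activated/resting repertoires.

    Resting reads are multinomial over the Zipf background; activated
    reads over the same background with the spiked clones' proportions
    multiplied by the enrichment factor and renormalized.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1 + individual_index]))
    individual_id = f"P{individual_index + 1:03d}"
    pool = _public_pool(cfg)

    include = rng.random(len(pool)) < cfg.public_inclusion_prob
    public = [c for c, inc in zip(pool, include) if inc]
    n_private_spiked = max(cfg.n_spiked_clones - len(public), 0)
    n_private_bg = cfg.n_background_clones - len(public) - n_private_spiked

    taken = {c.aa_seq for c in pool}
    private_aa = _unique_aa(rng, n_private_spiked + n_private_bg, cfg, taken)
    private_nt = _reverse_translate(rng, private_aa)
    private_vd = rng.poisson(cfg.insertion_mean_private, len(private_aa))
    private_dj = rng.poisson(cfg.insertion_mean_private, len(private_aa))
    private_v = rng.integers(2, 31, len(private_aa))
    private_j1 = rng.integers(1, 3, len(private_aa))
    private_j2 = rng.integers(1, 7, len(private_aa))

    # clone table: public spiked first, then private spiked, then background
    clones: list[dict] = []
    for c in public:
        clones.append({"aa": c.aa_seq, "spiked": True, "public": True, "clone": c})
    for i in range(n_private_spiked):
        clones.append({"aa": private_aa[i], "spiked": True, "public": False, "idx": i})
    for i in range(n_private_spiked, len(private_aa)):
        clones.append({"aa": private_aa[i], "spiked": False, "public": False, "idx": i})

    n_clones = len(clones)
    ranks = rng.permutation(n_clones) + 1
    base = ranks.astype(float) ** (-cfg.zipf_exponent)
    base /= base.sum()
    spiked_mask = np.array([c["spiked"] for c in clones])
    act = base * np.where(spiked_mask, cfg.enrichment_factor, 1.0)
    act /= act.sum()

    # expand clone-level proportions to nucleotide-variant level
    var_rows: list[dict] = []
    var_p_rest: list[float] = []
    var_p_act: list[float] = []
    for ci, c in enumerate(clones):
        if c["public"]:
            pc: _PublicClone = c["clone"]
            w = rng.dirichlet(np.ones(len(pc.nt_variants)))
            for vi, nt in enumerate(pc.nt_variants):
                var_rows.append(
                    {
                        "nt_seq": nt,
                        "aa_seq": pc.aa_seq,
                        "v_call": pc.v_calls[vi],
                        "d_call": "TRBD1",
                        "j_call": pc.j_call,
                        "vd_insertions": pc.vd_insertions[vi],
                        "dj_insertions": pc.dj_insertions[vi],
                    }
                )
                var_p_rest.append(base[ci] * w[vi])
                var_p_act.append(act[ci] * w[vi])
        else:
            i = c["idx"]
            var_rows.append(
                {
                    "nt_seq": private_nt[i],
                    "aa_seq": c["aa"],
                    "v_call": f"TRBV{private_v[i]}",
                    "d_call": "TRBD1",
                    "j_call": f"TRBJ{private_j1[i]}-{private_j2[i]}",
                    "vd_insertions": int(private_vd[i]),
                    "dj_insertions": int(private_dj[i]),
                }
            )
            var_p_rest.append(base[ci])
            var_p_act.append(act[ci])

    p_rest = np.array(var_p_rest)
    p_act = np.array(var_p_act)
    rest_counts = rng.multinomial(cfg.depth_resting, p_rest / p_rest.sum())
    act_counts = rng.multinomial(cfg.depth_activated, p_act / p_act.sum())

    def _to_rep(counts: np.ndarray, compartment: str) -> Repertoire:
        df = pd.DataFrame(var_rows)
        df["count"] = counts
        df = df[df["count"] > 0].reset_index(drop=True)
        df["vd_insertions"] = df["vd_insertions"].astype("Int64")
        df["dj_insertions"] = df["dj_insertions"].astype("Int64")
        df = df[
            ["nt_seq", "aa_seq", "v_call", "d_call", "j_call", "count",
             "vd_insertions", "dj_insertions"]
        ]
        return Repertoire(
            individual_id=individual_id, compartment=compartment, clonotypes=df
        )

    activated = _to_rep(act_counts, "activated")
    resting = _to_rep(rest_counts, "resting")

    # ground truth per spiked clone, with analytic expected activated counts
    act_by_aa: dict[str, int] = {}
    for row, c in zip(var_rows, act_counts):
        act_by_aa[row["aa_seq"]] = act_by_aa.get(row["aa_seq"], 0) + int(c)
    truth_rows = []
    for ci, c in enumerate(clones):
        if not c["spiked"]:
            continue
        truth_rows.append(
            {
                "individual_id": individual_id,
                "aa_seq": c["aa"],
                "is_public": c["public"],
                "planted_motif": c["clone"].motif if c["public"] else None,
                "base_proportion": base[ci],
                "expected_activated_count": cfg.depth_activated * act[ci],
                "expected_resting_count": cfg.depth_resting * base[ci],
                "activated_emitted": act_by_aa.get(c["aa"], 0) > 0,
            }
        )
    truth = Truth(individual_id=individual_id, table=pd.DataFrame(truth_rows))
    return activated, resting, truth


@dataclass
class CohortSim:
    config: SimConfig
    repertoires: dict[str, dict[str, Repertoire]]  # id -> {activated, resting}
    truth: dict[str, Truth]

    @property
    def individual_ids(self) -> list[str]:
        return sorted(self.repertoires)


def simulate_cohort(config: SimConfig) -> CohortSim:
    """Simulate the full cohort in memory."""
    reps: dict[str, dict[str, Repertoire]] = {}
    truth: dict[str, Truth] = {}
    for i in range(config.n_individuals):
        act, rest, t = simulate_individual(config, i)
        reps[act.individual_id] = {"activated": act, "resting": rest}
        truth[act.individual_id] = t
    return CohortSim(config=config, repertoires=reps, truth=truth)


def write_cohort(cohort: CohortSim, out_dir: str | Path) -> Path:
    """Write a cohort as immunoSEQ-dialect TSVs plus manifest and truth
    tables; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cmap = IMMUNOSEQ_COLUMNS
    manifest_rows = []
    for ind in cohort.individual_ids:
        for compartment, rep in cohort.repertoires[ind].items():
            df = rep.clonotypes.rename(
                columns={
                    "nt_seq": cmap.nt_seq,
                    "aa_seq": cmap.aa_seq,
                    "count": cmap.count,
                    "v_call": cmap.v_call,
                    "d_call": cmap.d_call,
                    "j_call": cmap.j_call,
                    "vd_insertions": cmap.vd_insertions,
                    "dj_insertions": cmap.dj_insertions,
                }
            ).copy()
            df[cmap.frame_status] = "In"
            fname = f"{ind}_{compartment}.tsv"
            df.to_csv(out_dir / fname, sep="\t", index=False)
            manifest_rows.append(
                {
                    "individual_id": ind,
                    "compartment": compartment,
                    "path": fname,
                    "dialect": "immunoseq",
                }
            )
    manifest = pd.DataFrame(manifest_rows)
    manifest_path = out_dir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    truth_all = pd.concat([t.table for t in cohort.truth.values()], ignore_index=True)
    truth_all.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return manifest_path


def simulate_subset(
    individual_id: str,
    subset: str,
    ps_sequences: Sequence[str],
    *,
    ps_read_fraction: float,
    n_background: int = 500,
    depth: int = 10_000,
    seed: int,
    config: SimConfig | None = None,
) -> Repertoire:
    """A bulk T-helper-subset repertoire with a planted ps read fraction.

    Background clones follow the Zipf law of ``config``; the requested
    fraction of the subset's reads is carried by the given autologous
    ps-CDR3 sequences (uniformly split among those sampled in).
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    ps_sequences = list(ps_sequences)
    bg_aa = _unique_aa(rng, n_background, cfg, set(ps_sequences))
    bg_p = (np.arange(1, n_background + 1) ** -cfg.zipf_exponent)
    bg_p = (1.0 - ps_read_fraction) * bg_p / bg_p.sum()
    ps_p = (
        np.full(len(ps_sequences), ps_read_fraction / len(ps_sequences))
        if ps_sequences
        else np.array([])
    )
    aa = ps_sequences + bg_aa
    p = np.concatenate([ps_p, bg_p])
    counts = rng.multinomial(depth, p / p.sum())
    nt = _reverse_translate(rng, aa)
    df = pd.DataFrame(
        {
            "nt_seq": nt,
            "aa_seq": aa,
            "v_call": [f"TRBV{v}" for v in rng.integers(2, 31, len(aa))],
            "d_call": "TRBD1",
            "j_call": "TRBJ2-1",
            "count": counts,
            "vd_insertions": pd.array(
                rng.poisson(cfg.insertion_mean_private, len(aa)), dtype="Int64"
            ),
            "dj_insertions": pd.array(
                rng.poisson(cfg.insertion_mean_private, len(aa)), dtype="Int64"
            ),
        }
    )
    df = df[df["count"] > 0].reset_index(drop=True)
    return Repertoire(
        individual_id=individual_id, compartment=f"subset:{subset}", clonotypes=df
    )
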