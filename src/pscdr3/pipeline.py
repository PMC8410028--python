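"""End-to-end orchestration: select ps-CDR3s, then characterize them.

``run_all`` executes the full workflow on a cohort manifest — selection,
distance profiles, diversity curves, publicity/convergence, motif mining,
network analysis and (when subset tables are present) T-helper-subset
probing — writing TSV result tables, a GML network, a machine-readable
``summary.json`` and an effective-parameter log sufficient to reproduce
the run.  Every stage failure aborts with the stage name; outputs of
completed stages are retained.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import convergence as conv
from . import diversity as dv
from . import motifs as mt
from . import network as nw
from . import similarity as sim
from . import subsets as sb
from .enrichment import IndividualSelection, SelectionConfig
from .io import Repertoire, aggregate_by_aa, load_cohort, read_manifest, write_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Effective parameters of a full pipeline run (defaults as published:
    alpha 0.05, activated count >= 2, 10-fold/>=3/>=3 motif rules,
    diversity orders 0-4, 100 resamples)."""

    manifest: str
    out_dir: str
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    seed: int = 7
    n_resamples: int = 100
    n_boot: int = 200
    q_max: float = 4.0
    q_step: float = 0.05
    hamming_cutoff: int = 2
    levenshtein_cutoff: int = 1
    motif: mt.MotifConfig = field(default_factory=mt.MotifConfig)
    motif_mode: str = "recompute"  # edge-baseline motif handling
    min_ps_for_diversity: int = 30
    run_similarity: bool = True
    run_diversity: bool = True
    run_convergence: bool = True
    run_motifs: bool = True
    run_network: bool = True
    run_subsets: bool = True

    def to_dict(self) -> dict:
        # out_dir is implicit in where the parameter log lives; leaving it
        # out keeps reruns into different directories byte-comparable
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        return d


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def _split_cohort(cohort):
    paired, subset_reps = {}, []
    for ind, comps in cohort.items():
        if any(c.startswith("subset:") for c in comps):
            subset_reps.extend(r for c, r in comps.items() if c.startswith("subset:"))
        core = {c: r for c, r in comps.items() if c in ("activated", "resting")}
        if core:
            missing = {"activated", "resting"} - set(core)
            if missing:
                raise StageError(
                    f"stage 'load' failed: individual {ind!r} missing "
                    f"{sorted(missing)} compartment"
                )
            paired[ind] = core
    return paired, subset_reps


def run_all(config: RunConfig) -> dict:
    """Run the full workflow; returns the summary dict (also written to
    ``summary.json`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"parameters": config.to_dict()}

    manifest = read_manifest(config.manifest)
    base_dir = Path(config.manifest).parent
    cohort = load_cohort(manifest, base_dir=base_dir)
    paired, subset_reps = _split_cohort(cohort)
    if not paired:
        raise StageError("stage 'load' failed: no activated/resting pairs in manifest")

    # --- selection -------------------------------------------------------
    @_stage("select")
    def _select():
        selections = {}
        for ind in sorted(paired):
            sel = IndividualSelection.from_repertoires(
                paired[ind]["activated"], paired[ind]["resting"], config.selection
            )
            selections[ind] = sel
            write_table(
                sel.enrichment, out / "select" / f"{ind}_enrichment.tsv",
                kind="enrichment", allow_empty=True,
            )
        return selections

    selections = _select()
    library = conv.build_library(selections.values())
    lib_out = library.aa_table.copy()
    lib_out["individuals"] = lib_out["individuals"].map(";".join)
    write_table(lib_out, out / "library.tsv", kind="summary", allow_empty=True)
    var_out = library.variants.copy()
    var_out["individuals"] = var_out["individuals"].map(";".join)
    write_table(var_out, out / "library_variants.tsv", kind="summary", allow_empty=True)

    ps_by_ind = {
        ind: sorted(sel.enrichment.loc[sel.enrichment["is_ps"], "aa_seq"])
        for ind, sel in selections.items()
    }
    summary["selection"] = {
        "n_ps_total": int(sum(len(v) for v in ps_by_ind.values())),
        "n_unique_ps_aa": library.n_sequences,
        "n_public": library.n_public,
        "per_individual": {ind: len(v) for ind, v in sorted(ps_by_ind.items())},
    }

    # --- similarity ------------------------------------------------------
    if config.run_similarity:
        @_stage("similarity")
        def _similarity():
            pooled_ps = [aa for ind in sorted(ps_by_ind) for aa in ps_by_ind[ind]]
            res = {}
            if len(pooled_ps) >= 2:
                pools = {
                    comp: {
                        ind: sorted(paired[ind][comp].clonotypes["aa_seq"].unique())
                        for ind in sorted(paired)
                    }
                    for comp in ("activated", "resting")
                }
                strata = {ind: len(ps_by_ind[ind]) for ind in sorted(ps_by_ind)}
                for metric, cutoff in (
                    ("hamming", config.hamming_cutoff),
                    ("levenshtein", config.levenshtein_cutoff),
                ):
                    observed = sim.min_distance_profile(pooled_ps, metric)
                    write_table(
                        pd.DataFrame(
                            {"distance": list(observed.percentages),
                             "percentage": list(observed.percentages.values())}
                        ),
                        out / "distances" / f"ps_{metric}_profile.tsv",
                        kind="summary", allow_empty=True,
                    )
                    res[metric] = {}
                    for comp in ("activated", "resting"):
                        baseline = sim.resampled_profile_baseline(
                            pools[comp], strata, metric=metric,
                            n_resamples=config.n_resamples, seed=config.seed,
                        )
                        test = sim.compare_distance_enrichment(observed, baseline, cutoff)
                        res[metric][comp] = {
                            "odds_ratio": test.odds_ratio,
                            "p_value": test.p_value,
                            "cutoff": cutoff,
                        }
            return res

        summary["similarity"] = _similarity()

    # --- diversity -------------------------------------------------------
    if config.run_diversity:
        @_stage("diversity")
        def _diversity():
            q_grid = dv.default_q_grid(config.q_max, config.q_step)
            rows = []
            eligible = []
            for ind in sorted(paired):
                ps = set(ps_by_ind[ind])
                if len(ps) <= config.min_ps_for_diversity:
                    continue
                eligible.append(ind)
                act_agg = aggregate_by_aa(paired[ind]["activated"])
                rest_agg = aggregate_by_aa(paired[ind]["resting"])
                ps_counts = act_agg.loc[act_agg["aa_seq"].isin(ps), "count"]
                size = int(min(ps_counts.sum(), act_agg["count"].sum(),
                               rest_agg["count"].sum()))
                curves = {}
                for name, counts in (
                    ("ps", ps_counts), ("activated", act_agg["count"]),
                    ("resting", rest_agg["count"]),
                ):
                    curves[name] = dv.diversity_curve(
                        counts.to_numpy(), q_grid=q_grid, resample_size=size,
                        n_boot=config.n_boot, seed=config.seed,
                    )
                for num, den in (("resting", "ps"), ("activated", "ps"),
                                 ("resting", "activated")):
                    fc = dv.diversity_fold_change(curves[num], curves[den])
                    for q, v in zip(fc["q"], fc["fold_change"]):
                        rows.append({"individual_id": ind, "contrast": f"{num}/{den}",
                                     "q": q, "fold_change": v})
            fc_table = pd.DataFrame(rows)
            if not fc_table.empty:
                write_table(fc_table, out / "diversity" / "fold_changes.tsv",
                            kind="summary", allow_empty=True)
            return {"eligible_individuals": eligible}

        summary["diversity"] = _diversity()

    # --- convergence -----------------------------------------------------
    if config.run_convergence:
        @_stage("convergence")
        def _convergence():
            ins = conv.insertion_comparison(library)
            cg = conv.convergence_comparison(library)
            mats_dir = out / "convergence" / "logo_matrices"
            pub_conv = library.aa_table[
                library.aa_table["is_public"] & library.aa_table["is_convergent"]
            ]["aa_seq"]
            for aa in pub_conv:
                variants = library.variants[library.variants["aa_seq"] == aa]
                try:
                    mat, vprobs = conv.encoding_probability_matrix(aa, variants)
                except ValueError:
                    continue
                write_table(mat, mats_dir / f"{aa}_codons.tsv", kind="summary",
                            allow_empty=True)
            return {"insertions": ins, "convergence": cg}

        summary["convergence"] = _convergence()

    # --- motifs ----------------------------------------------------------
    motif_result = None
    if config.run_motifs:
        @_stage("motifs")
        def _motifs():
            ps_records = pd.DataFrame(
                [
                    {"individual_id": ind, "aa_seq": rec.aa_seq,
                     "count": rec.activated_count}
                    for ind, sel in sorted(selections.items())
                    for rec in sel.enrichment[sel.enrichment["is_ps"]].itertuples(
                        index=False)
                ]
            )
            rest_frames = [
                aggregate_by_aa(paired[ind]["resting"]) for ind in sorted(paired)
            ]
            resting_pool = (
                pd.concat(rest_frames).groupby("aa_seq", as_index=False)["count"].sum()
            )
            if ps_records.empty:
                return None, {"n_patterns": 0, "n_dominant": 0}
            result = mt.motif_enrichment(ps_records, resting_pool, config.motif)
            write_table(result.table, out / "motifs" / "motifs.tsv", kind="motifs",
                        allow_empty=True)
            return result, {
                "n_patterns": int(len(result.table)),
                "n_dominant": int(result.table["dominant"].sum()),
            }

        motif_result, motif_summary = _motifs()
        summary["motifs"] = motif_summary

    # --- network ---------------------------------------------------------
    if config.run_network:
        @_stage("network")
        def _network():
            dom = motif_result.dominant_map() if motif_result is not None else None
            net = nw.build_network(library, dom)
            nw.export_gml(net, out / "network" / "network.gml")
            stats = nw.degree_statistics(net)
            rest_frames = []
            for ind in sorted(paired):
                agg = aggregate_by_aa(paired[ind]["resting"])
                agg["individual_id"] = ind
                rest_frames.append(agg)
            resting_pool = pd.concat(rest_frames, ignore_index=True)
            resting_ref = resting_pool.groupby("aa_seq", as_index=False)["count"].sum()
            baselines = {}
            for comp in ("activated", "resting"):
                frames = []
                for ind in sorted(paired):
                    agg = aggregate_by_aa(paired[ind][comp])
                    agg["individual_id"] = ind
                    frames.append(agg)
                pool = pd.concat(frames, ignore_index=True)
                size = min(len(library.aa_table), len(pool))
                bl = nw.resampled_edge_baseline(
                    pool, size, net.total_edges,
                    n_resamples=config.n_resamples, seed=config.seed,
                    motif_mode=config.motif_mode,
                    motifs=dom, resting_ref=resting_ref, motif_config=config.motif,
                )
                baselines[comp] = {"mean": bl.mean, "sd": bl.sd, "z": bl.z,
                                   "p_value": bl.p_value}
            return {
                "n_nodes": net.graph.number_of_nodes(),
                "n_pair_edges": net.n_pair_edges,
                "n_self_edges": net.n_self_edges,
                "n_total_edges": net.total_edges,
                "membership_fraction_public": stats.membership_fraction_public,
                "membership_fraction_private": stats.membership_fraction_private,
                "membership_p": stats.membership_p,
                "degree_median_public": stats.degree_median_public,
                "degree_median_private": stats.degree_median_private,
                "degree_p": stats.degree_p,
                "edge_baselines": baselines,
            }

        summary["network"] = _network()

    # --- subsets ---------------------------------------------------------
    if config.run_subsets and subset_reps:
        @_stage("subsets")
        def _subsets():
            libraries = {ind: ps for ind, ps in ps_by_ind.items() if ps}
            probe = sb.probe_subsets(subset_reps, libraries)
            write_table(probe.fractions, out / "subsets" / "fractions.tsv",
                        kind="summary", allow_empty=True)
            reg = {}
            for subset in sorted({s for _, s in probe.matched}):
                per_seq = probe.per_sequence[probe.per_sequence["subset"] == subset]
                if per_seq["is_ps"].nunique() == 2:
                    r = sb.expansion_regression(per_seq)
                    reg[subset] = {"slope": r.slope, "odds_ratio": r.odds_ratio,
                                   "p_value": r.p_value,
                                   "separation": r.separation_flag}
            matched = {s: probe.matched_by_subset(s)
                       for s in sorted({x for _, x in probe.matched})}
            jac = {}
            if len(matched) >= 2:
                publicity = dict(zip(library.aa_table["aa_seq"],
                                     library.aa_table["is_public"]))
                mats = sb.subset_jaccard(matched, publicity)
                for name, mat in mats.items():
                    write_table(mat.reset_index(names="subset"),
                                out / "subsets" / f"jaccard_{name}.tsv",
                                kind="summary", allow_empty=True)
                jac["matrices"] = sorted(mats)
            return {"regression": reg, **jac}

        summary["subsets"] = _subsets()

    with open(out / "params.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")
    return summary


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
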