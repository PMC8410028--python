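"""Shared fixtures: a small simulated cohort and per-individual selections."""

from __future__ import annotations

import pandas as pd
import pytest

from pscdr3 import (
    IndividualSelection,
    SimConfig,
    build_library,
    simulate_cohort,
)


def make_repertoire(records, individual_id="P1", compartment="activated"):
    """Build a Repertoire from (nt, aa, count) or full-dict records."""
    from pscdr3.io import CLONOTYPE_COLUMNS, Repertoire

    rows = []
    for rec in records:
        if isinstance(rec, dict):
            row = dict(rec)
        else:
            nt, aa, count = rec
            row = {"nt_seq": nt, "aa_seq": aa, "count": count}
        row.setdefault("v_call", "TRBV5")
        row.setdefault("d_call", "TRBD1")
        row.setdefault("j_call", "TRBJ2-1")
        row.setdefault("vd_insertions", pd.NA)
        row.setdefault("dj_insertions", pd.NA)
        rows.append(row)
    df = pd.DataFrame(rows)[CLONOTYPE_COLUMNS]
    df["vd_insertions"] = df["vd_insertions"].astype("Int64")
    df["dj_insertions"] = df["dj_insertions"].astype("Int64")
    return Repertoire(individual_id=individual_id, compartment=compartment, clonotypes=df)


SMALL_CONFIG = SimConfig(
    n_individuals=6,
    n_background_clones=300,
    n_spiked_clones=20,
    depth_activated=20_000,
    depth_resting=20_000,
    public_pool_size=6,
    public_inclusion_prob=0.5,
    seed=11,
)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_selections(small_cohort):
    return {
        ind: IndividualSelection.from_repertoires(
            comps["activated"], comps["resting"]
        )
        for ind, comps in small_cohort.repertoires.items()
    }


@pytest.fixture(scope="session")
def small_library(small_selections):
    return build_library(small_selections.values())


def levenshtein_dp(a: str, b: str) -> int:
    """Independent O(len(a)*len(b)) edit-distance oracle for tests."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]
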