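"""Reading, validating and writing TCR rearrangement tables.

Rearrangement tables are tab-separated files with one row per unique
nucleotide rearrangement, carrying the CDR3beta nucleotide and amino-acid
sequence, V/D/J gene calls, a read (template) count and the number of
non-templated N insertions at the V-D and D-J junctions.  Two dialects are
supported out of the box: the immunoSEQ export format (Adaptive
Biotechnologies column names) and the AIRR Rearrangement standard.  Both
are plain TSV; the :class:`ColumnMap` maps logical field names onto the
vendor headers and can be overridden record-by-record because column names
drift across export versions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: Canonical column order of the in-memory clonotype table.
CLONOTYPE_COLUMNS = [
    "nt_seq",
    "aa_seq",
    "v_call",
    "d_call",
    "j_call",
    "count",
    "vd_insertions",
    "dj_insertions",
]

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


class FormatError(ValueError):
    """A mandatory column could not be resolved in the input table."""


class EmptyRepertoireError(ValueError):
    """No productive, in-frame records survived quality filtering."""


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from logical field names to source column headers.

    ``nt_seq``, ``aa_seq`` and ``count`` are mandatory; the gene calls,
    insertion counts and the productivity flag are optional and left
    missing when the source table does not carry them.
    """

    nt_seq: str
    aa_seq: str
    count: str
    v_call: str | None = None
    d_call: str | None = None
    j_call: str | None = None
    vd_insertions: str | None = None
    dj_insertions: str | None = None
    frame_status: str | None = None

    def as_dict(self) -> dict[str, str]:
        return {
            logical: source
            for logical, source in self.__dict__.items()
            if source is not None
        }


#: Default immunoSEQ export headers.  n1Insertion is taken as the V-D
#: junction and n2Insertion as the D-J junction; Adaptive's documentation
#: does not name them explicitly, so the mapping is overridable.
IMMUNOSEQ_COLUMNS = ColumnMap(
    nt_seq="nucleotide",
    aa_seq="aminoAcid",
    count="count (templates/reads)",
    v_call="vGeneName",
    d_call="dGeneName",
    j_call="jGeneName",
    vd_insertions="n1Insertion",
    dj_insertions="n2Insertion",
    frame_status="sequenceStatus",
)

#: Default AIRR Rearrangement headers (np1/np2 region lengths stand in for
#: the V-D / D-J insertion counts).
AIRR_COLUMNS = ColumnMap(
    nt_seq="junction",
    aa_seq="junction_aa",
    count="duplicate_count",
    v_call="v_call",
    d_call="d_call",
    j_call="j_call",
    vd_insertions="np1_length",
    dj_insertions="np2_length",
    frame_status="productive",
)

DIALECTS: Mapping[str, ColumnMap] = {
    "immunoseq": IMMUNOSEQ_COLUMNS,
    "airr": AIRR_COLUMNS,
}


@dataclass
class Repertoire:
    """One compartment of one individual: a table of clonotypes.

    ``clonotypes`` holds one row per unique nucleotide rearrangement with
    the canonical columns of :data:`CLONOTYPE_COLUMNS`.  ``compartment``
    is ``"activated"``, ``"resting"`` or ``"subset:<name>"``.
    """

    individual_id: str
    compartment: str
    clonotypes: pd.DataFrame
    n_dropped: int = 0

    @property
    def total_reads(self) -> int:
        return int(self.clonotypes["count"].sum())

    @property
    def unique_nt(self) -> int:
        return int(self.clonotypes["nt_seq"].nunique())

    @property
    def unique_aa(self) -> int:
        return int(self.clonotypes["aa_seq"].nunique())

    def __len__(self) -> int:
        return len(self.clonotypes)


def _is_productive_flag(value: object) -> bool:
    """Interpret a productivity/frame column value (vendor conventions vary)."""
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    return text in {"in", "in-frame", "inframe", "true", "t", "productive", "1", "1.0"}


def _aa_is_clean(aa: str) -> bool:
    return len(aa) > 0 and set(aa) <= _AA_ALPHABET


def read_rearrangements(
    path: str | Path,
    *,
    dialect: str = "immunoseq",
    column_map: ColumnMap | None = None,
    individual_id: str,
    compartment: str,
) -> Repertoire:
    """Read a rearrangement TSV and return a quality-filtered :class:`Repertoire`.

    Records are dropped (and counted in ``Repertoire.n_dropped``) when
    they are flagged unproductive/out-of-frame, when the amino-acid CDR3
    contains a stop (``*``), an ambiguous residue (``X``) or any
    character outside the 20-letter alphabet, when the count is below 1,
    or when a full-length junction nucleotide sequence translates to a
    different amino-acid sequence.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}")
    cmap = column_map or DIALECTS[dialect]

    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)

    for logical in ("nt_seq", "aa_seq", "count"):
        source = getattr(cmap, logical)
        if source not in raw.columns:
            raise FormatError(
                f"mandatory column {source!r} (field {logical!r}) not found in {path.name}"
            )

    df = pd.DataFrame(index=raw.index)
    for logical, source in cmap.as_dict().items():
        if source in raw.columns:
            df[logical] = raw[source]
    for col in CLONOTYPE_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA

    n_in = len(df)
    df["count"] = pd.to_numeric(df["count"], errors="coerce")
    for col in ("vd_insertions", "dj_insertions"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")

    keep = df["aa_seq"].notna() & df["count"].notna() & (df["count"] >= 1)
    keep &= df["aa_seq"].fillna("").map(_aa_is_clean)
    if "frame_status" in df.columns and df["frame_status"].notna().any():
        keep &= df["frame_status"].map(_is_productive_flag)

    # Translation consistency is only checkable when the nucleotide column
    # holds exactly the junction (immunoSEQ exports a fixed 87-bp window).
    def _translation_ok(row) -> bool:
        nt, aa = row["nt_seq"], row["aa_seq"]
        if pd.isna(nt) or len(str(nt)) != 3 * len(str(aa)):
            return True
        try:
            return str(Seq(str(nt)).translate()) == str(aa)
        except Exception:
            return True

    keep &= df.apply(_translation_ok, axis=1)

    df = df.loc[keep, CLONOTYPE_COLUMNS].reset_index(drop=True)
    df["count"] = df["count"].astype(int)
    n_dropped = n_in - len(df)
    if n_dropped:
        logger.info("%s: dropped %d/%d records in QC", path.name, n_dropped, n_in)
    if df.empty:
        raise EmptyRepertoireError(f"no productive records left in {path} after filtering")
    return Repertoire(
        individual_id=individual_id,
        compartment=compartment,
        clonotypes=df,
        n_dropped=n_dropped,
    )


def aggregate_by_aa(rep: Repertoire) -> pd.DataFrame:
    """Collapse a repertoire to one row per unique amino-acid CDR3.

    Returns a table with ``aa_seq``, the summed read ``count`` over all
    nucleotide variants, and ``n_nt_variants`` (the number of distinct
    nucleotide rearrangements encoding the amino-acid sequence).
    """
    out = (
        rep.clonotypes.groupby("aa_seq", sort=True)
        .agg(count=("count", "sum"), n_nt_variants=("nt_seq", "nunique"))
        .reset_index()
    )
    return out


def write_table(
    records: pd.DataFrame,
    path: str | Path,
    *,
    kind: str = "summary",
    allow_empty: bool = False,
) -> Path:
    """Write a result table as TSV with a header row.

    ``kind`` is recorded only for error messages; all result tables share
    the same lossless TSV round-trip format.
    """
    if records.empty and not allow_empty:
        raise ValueError(f"refusing to write empty {kind} table (pass allow_empty=True)")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest (individual_id, compartment, path, dialect)."""
    manifest = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual_id", "compartment", "path"}
    missing = required - set(manifest.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    if "dialect" not in manifest.columns:
        manifest["dialect"] = "immunoseq"
    return manifest


def load_cohort(
    manifest: pd.DataFrame, *, base_dir: str | Path | None = None
) -> dict[str, dict[str, Repertoire]]:
    """Load every repertoire referenced by a manifest.

    Returns ``{individual_id: {compartment: Repertoire}}``.  Relative
    paths are resolved against ``base_dir`` when given.
    """
    cohort: dict[str, dict[str, Repertoire]] = {}
    for row in manifest.itertuples(index=False):
        p = Path(row.path)
        if base_dir is not None and not p.is_absolute():
            p = Path(base_dir) / p
        rep = read_rearrangements(
            p,
            dialect=row.dialect,
            individual_id=row.individual_id,
            compartment=row.compartment,
        )
        cohort.setdefault(row.individual_id, {})[row.compartment] = rep
    return cohort


__all__ = [
    "CLONOTYPE_COLUMNS",
    "ColumnMap",
    "IMMUNOSEQ_COLUMNS",
    "AIRR_COLUMNS",
    "DIALECTS",
    "Repertoire",
    "FormatError",
    "EmptyRepertoireError",
    "read_rearrangements",
    "aggregate_by_aa",
    "write_table",
    "read_table",
    "read_manifest",
    "load_cohort",
]
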