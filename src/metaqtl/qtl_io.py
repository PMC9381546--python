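"""Readers and writers for the pipeline's tabular formats.

Canonical dialect is TSV with a header row.  ``read_qtl_table`` accepts a
column-name mapping so compilations with alternate headers (or CSV) can be
ingested without editing the file.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO

from .errors import DomainError, FormatError
from .types import GeneRecord, GeneticMap, MarkerPhysicalTable, QtlRecord

log = logging.getLogger(__name__)

#: canonical column names of a QTL table
QTL_COLUMNS = [
    "study_id",
    "qtl_id",
    "chromosome",
    "position",
    "lod",
    "r2",
    "pop_size",
    "ci_start",
    "ci_end",
    "flank_left",
    "flank_right",
]

_REQUIRED = ("study_id", "chromosome", "position")


def normalize_r2(value: float) -> float:
    """Coerce a PVE value to a proportion in (0, 1].

    Source studies mix conventions: values above 1 are taken as percentages
    and divided by 100; values at or below 1 pass through unchanged.
    """
    if value <= 0 or value > 100:
        raise DomainError(f"R² must be in (0, 100], got {value}")
    return value / 100 if value > 1 else value


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return float(value)


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return str(value)


def read_qtl_table(
    path: str | Path,
    dialect: dict[str, str] | None = None,
    sep: str = "\t",
) -> list[QtlRecord]:
    """Parse a QTL compilation into validated, sorted records.

    Parameters
    ----------
    path:
        TSV (or, with ``sep=','``, CSV) file with a header row.
    dialect:
        Optional mapping from canonical column names to the file's header
        names, e.g. ``{"r2": "PVE"}``.
    sep:
        Field separator.

    Rows violating the record invariants (chromosome outside 1–12, R² outside
    (0, 100], CI not bracketing the position, ...) are dropped with a logged
    reason.  Returned records are sorted by (chromosome, position).
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise FormatError(f"{path}: QTL table contains no rows")
    rename = {v: k for k, v in (dialect or {}).items()}
    df = df.rename(columns=rename)
    for col in _REQUIRED:
        if col not in df.columns:
            raise FormatError(f"{path}: required column {col!r} is missing")

    records: list[QtlRecord] = []
    for idx, row in df.iterrows():
        try:
            records.append(_row_to_record(row, idx))
        except (DomainError, ValueError) as exc:
            log.warning("dropping QTL row %s: %s", idx, exc)
    if not records:
        raise FormatError(f"{path}: no valid QTL rows after filtering")
    records.sort(key=lambda q: (q.chromosome, q.position, q.qtl_id))
    return records


def _row_to_record(row: pd.Series, idx) -> QtlRecord:
    chrom = int(float(row["chromosome"]))
    if not 1 <= chrom <= 12:
        raise DomainError(f"chromosome {chrom} outside 1..12")
    position = float(row["position"])
    r2 = _opt_float(row.get("r2"))
    if r2 is not None:
        r2 = normalize_r2(r2)
    pop_size = _opt_float(row.get("pop_size"))
    if pop_size is not None:
        pop_size = int(pop_size)
        if pop_size < 2:
            raise DomainError(f"pop_size {pop_size} < 2")
    lod = _opt_float(row.get("lod"))
    if lod is not None and lod < 0:
        raise DomainError(f"LOD {lod} < 0")
    ci_start = _opt_float(row.get("ci_start"))
    ci_end = _opt_float(row.get("ci_end"))
    if ci_start is not None and ci_end is not None:
        if not ci_start <= position <= ci_end:
            raise DomainError(
                f"CI [{ci_start}, {ci_end}] does not bracket position {position}"
            )
    qtl_id = _opt_str(row.get("qtl_id")) or f"qtl_{idx}"
    return QtlRecord(
        study_id=str(row["study_id"]),
        qtl_id=qtl_id,
        chromosome=chrom,
        position=position,
        lod=lod,
        r2=r2,
        pop_size=pop_size,
        ci_start=ci_start,
        ci_end=ci_end,
        flank_left=_opt_str(row.get("flank_left")),
        flank_right=_opt_str(row.get("flank_right")),
    )


def qtl_records_to_frame(records: list[QtlRecord]) -> pd.DataFrame:
    rows = [
        {
            "study_id": q.study_id,
            "qtl_id": q.qtl_id,
            "chromosome": q.chromosome,
            "position": q.position,
            "lod": q.lod,
            "r2": q.r2,
            "pop_size": q.pop_size,
            "ci_start": q.ci_start,
            "ci_end": q.ci_end,
            "flank_left": q.flank_left,
            "flank_right": q.flank_right,
        }
        for q in records
    ]
    return pd.DataFrame(rows, columns=QTL_COLUMNS)


def write_qtl_table(records: list[QtlRecord], path: str | Path) -> None:
    qtl_records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_genetic_maps(path: str | Path) -> dict[str, GeneticMap]:
    """Read a long-format map TSV (map_id, marker, chromosome, position_cM)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("map_id", "marker", "chromosome", "position_cM"):
        if col not in df.columns:
            raise FormatError(f"{path}: required column {col!r} is missing")
    maps: dict[str, GeneticMap] = {}
    for map_id, group in df.groupby("map_id", sort=True):
        entries = [
            (str(r.marker), int(r.chromosome), float(r.position_cM))
            for r in group.itertuples()
        ]
        maps[str(map_id)] = GeneticMap(str(map_id), entries)
    return maps


def read_reference_map(path: str | Path) -> GeneticMap:
    """Read a single-map TSV; a constant map_id column is optional."""
    maps = read_genetic_maps(path)
    if len(maps) != 1:
        raise FormatError(f"{path}: expected exactly one map_id, found {len(maps)}")
    return next(iter(maps.values()))


def write_genetic_maps(maps: list[GeneticMap], path: str | Path) -> None:
    rows = [
        {"map_id": m.map_id, "marker": marker, "chromosome": chrom, "position_cM": pos}
        for m in maps
        for marker, chrom, pos in m.entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_marker_physical_table(path: str | Path) -> MarkerPhysicalTable:
    df = pd.read_csv(path, sep="\t")
    for col in ("marker", "chromosome", "bp"):
        if col not in df.columns:
            raise FormatError(f"{path}: required column {col!r} is missing")
    table = MarkerPhysicalTable()
    for r in df.itertuples():
        table.add(str(r.marker), int(r.chromosome), int(r.bp))
    return table


def read_gff3_genes(path: str | Path, feature_type: str = "gene") -> list[GeneRecord]:
    """Extract gene-level records from a GFF3 annotation.

    Only rows of ``feature_type`` are kept; reversed coordinates are
    normalized so start <= end.  An annotation without genes yields an empty
    list, not an error.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneRecord] = []
    for feat in db.features_of_type(feature_type):
        try:
            chrom = int(str(feat.seqid).lstrip("Chrchr"))
        except ValueError:
            log.warning("skipping gene on non-numeric seqid %r", feat.seqid)
            continue
        locus = feat.attributes.get("ID", [feat.id])[0]
        desc = feat.attributes.get("description", [""])[0]
        genes.append(
            GeneRecord(
                locus_id=locus,
                chromosome=chrom,
                start_bp=int(feat.start),
                end_bp=int(feat.end),
                strand=feat.strand or ".",
                description=desc,
            )
        )
    genes.sort(key=lambda g: (g.chromosome, g.start_bp))
    return genes


def read_panel(path: str | Path) -> pd.DataFrame:
    """Read a validation panel TSV (genotype_id, tgw_g, allele)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("genotype_id", "tgw_g", "allele"):
        if col not in df.columns:
            raise FormatError(f"{path}: required column {col!r} is missing")
    if (df["tgw_g"] <= 0).any():
        raise FormatError(f"{path}: tgw_g must be positive")
    return df


def read_alignment(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA into an id -> sequence dict (order preserved)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_class_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sequence_id, class in {low, high})."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sequence_id", "class"):
        if col not in df.columns:
            raise FormatError(f"{path}: required column {col!r} is missing")
    return dict(zip(df["sequence_id"].astype(str), df["class"].astype(str)))
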