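"""Physical anchoring of meta-QTL, gene extraction, and alignment variants."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import AlignmentError, ConsistencyError, DomainError, LookupFailure
from .types import GeneRecord, MarkerPhysicalTable, MetaQtl, PhysicalInterval


@dataclass
class ClassVariant:
    """A run of alignment columns that perfectly separates two classes."""

    column: int  # 0-based start column
    kind: str  # "substitution" | "indel"
    low_allele: str
    high_allele: str
    span: int = 1


def physical_interval(
    flank_left: str, flank_right: str, table: MarkerPhysicalTable
) -> PhysicalInterval:
    """Closed bp interval spanned by two flanking markers (order-insensitive)."""
    for marker in (flank_left, flank_right):
        if marker not in table:
            raise LookupFailure(f"marker {marker!r} absent from physical table")
    chrom_l, bp_l = table[flank_left]
    chrom_r, bp_r = table[flank_right]
    if chrom_l != chrom_r:
        raise ConsistencyError(
            f"flanking markers {flank_left!r} (chr{chrom_l}) and "
            f"{flank_right!r} (chr{chrom_r}) lie on different chromosomes"
        )
    return PhysicalInterval(chrom_l, min(bp_l, bp_r), max(bp_l, bp_r))


def genes_in_interval(
    genes: list[GeneRecord], interval: PhysicalInterval
) -> list[GeneRecord]:
    """Genes overlapping the closed interval (any overlap counts), by start."""
    hits = [
        g
        for g in genes
        if g.chromosome == interval.chromosome
        and g.start_bp <= interval.end_bp
        and g.end_bp >= interval.start_bp
    ]
    hits.sort(key=lambda g: g.start_bp)
    return hits


def anchor_mqtl(
    mqtl: MetaQtl, table: MarkerPhysicalTable, genes: list[GeneRecord] | None = None
) -> tuple[PhysicalInterval, list[GeneRecord]]:
    """Fill an MQTL's physical interval from its flanking markers and list
    the genes it contains."""
    if mqtl.flank_left is None or mqtl.flank_right is None:
        raise DomainError(f"{mqtl.mqtl_id}: flanking markers are not set")
    interval = physical_interval(mqtl.flank_left, mqtl.flank_right, table)
    mqtl.physical_start = interval.start_bp
    mqtl.physical_end = interval.end_bp
    return interval, genes_in_interval(genes or [], interval)


def class_distinguishing_variants(
    alignment: dict[str, str], classes: dict[str, str]
) -> list[ClassVariant]:
    """Scan an alignment for columns that perfectly separate two classes.

    A column qualifies when all low-class residues agree, all high-class
    residues agree, and the two consensuses differ.  Adjacent qualifying
    columns of the same kind are merged into one variant; a run touching a
    gap in either consensus is reported as an indel with its column span.
    """
    low_ids = [i for i, c in classes.items() if c == "low"]
    high_ids = [i for i, c in classes.items() if c == "high"]
    if not low_ids or not high_ids:
        raise DomainError("each class needs at least one sequence")
    for sid in low_ids + high_ids:
        if sid not in alignment:
            raise DomainError(f"sequence {sid!r} missing from alignment")
    lengths = {len(alignment[sid]) for sid in low_ids + high_ids}
    if len(lengths) != 1:
        raise AlignmentError(f"aligned sequences have unequal lengths: {sorted(lengths)}")
    (length,) = lengths

    cols: list[tuple[int, str, str]] = []
    for j in range(length):
        low = {alignment[sid][j] for sid in low_ids}
        high = {alignment[sid][j] for sid in high_ids}
        if len(low) == 1 and len(high) == 1 and low != high:
            cols.append((j, low.pop(), high.pop()))

    variants: list[ClassVariant] = []
    run: list[tuple[int, str, str]] = []

    def flush() -> None:
        if not run:
            return
        start = run[0][0]
        low_allele = "".join(c[1] for c in run)
        high_allele = "".join(c[2] for c in run)
        kind = "indel" if "-" in low_allele + high_allele else "substitution"
        variants.append(
            ClassVariant(
                column=start,
                kind=kind,
                low_allele=low_allele,
                high_allele=high_allele,
                span=len(run),
            )
        )
        run.clear()

    for col in cols:
        if run and col[0] != run[-1][0] + 1:
            flush()
        if run:
            prev_gap = "-" in (run[-1][1], run[-1][2])
            cur_gap = "-" in (col[1], col[2])
            if prev_gap != cur_gap:
                flush()
        run.append(col)
    flush()
    return variants
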