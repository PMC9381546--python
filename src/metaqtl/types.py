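"""Core domain types shared across the pipeline.

Conventions: genetic positions are centimorgans (cM) as floats; physical
positions are 1-based inclusive base pairs (GFF3 convention); intervals are
closed on both ends.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

N_CHROMOSOMES = 12

#: 95% CI width of a Gaussian in units of its standard deviation (2 x 1.96).
CI95_FACTOR = 3.92


@dataclass
class QtlRecord:
    """One QTL as reported by a source study, on that study's own map."""

    study_id: str
    qtl_id: str
    chromosome: int
    position: float
    lod: float | None = None
    r2: float | None = None
    pop_size: int | None = None
    ci_start: float | None = None
    ci_end: float | None = None
    flank_left: str | None = None
    flank_right: str | None = None

    def reported_ci(self) -> float | None:
        """Width of the study-reported confidence interval, if usable."""
        if self.ci_start is None or self.ci_end is None:
            return None
        width = self.ci_end - self.ci_start
        return width if width > 0 else None


@dataclass
class GeneticMap:
    """Ordered marker -> cM assignments for one map."""

    map_id: str
    entries: list[tuple[str, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_chrom: dict[int, list[tuple[str, float]]] = {}
        seen: set[str] = set()
        for marker, chrom, pos in self.entries:
            if marker in seen:
                raise ValueError(f"duplicate marker {marker!r} in map {self.map_id!r}")
            seen.add(marker)
            self._by_chrom.setdefault(int(chrom), []).append((marker, float(pos)))
        for chrom, markers in self._by_chrom.items():
            markers.sort(key=lambda mp: mp[1])

    @property
    def chromosomes(self) -> list[int]:
        return sorted(self._by_chrom)

    def markers_on(self, chromosome: int) -> list[tuple[str, float]]:
        """(marker, cM) pairs on a chromosome, sorted by position."""
        return list(self._by_chrom.get(int(chromosome), []))

    def position_of(self, marker: str) -> tuple[int, float] | None:
        for chrom, markers in self._by_chrom.items():
            for name, pos in markers:
                if name == marker:
                    return chrom, pos
        return None

    def nearest_marker(self, chromosome: int, position: float) -> str | None:
        markers = self._by_chrom.get(int(chromosome))
        if not markers:
            return None
        return min(markers, key=lambda mp: (abs(mp[1] - position), mp[0]))[0]

    def flanking_markers(
        self, chromosome: int, start: float, end: float
    ) -> tuple[str | None, str | None]:
        """Nearest markers strictly outside the closed interval [start, end]."""
        markers = self._by_chrom.get(int(chromosome), [])
        positions = [pos for _, pos in markers]
        left = bisect.bisect_left(positions, start) - 1
        right = bisect.bisect_right(positions, end)
        left_marker = markers[left][0] if left >= 0 else None
        right_marker = markers[right][0] if right < len(markers) else None
        return left_marker, right_marker


@dataclass
class MarkerPhysicalTable:
    """marker -> (chromosome, bp) lookup, bp 1-based."""

    rows: dict[str, tuple[int, int]] = field(default_factory=dict)

    def add(self, marker: str, chromosome: int, bp: int) -> None:
        if bp < 1:
            raise ValueError(f"bp must be >= 1, got {bp} for {marker!r}")
        self.rows[marker] = (int(chromosome), int(bp))

    def __contains__(self, marker: str) -> bool:
        return marker in self.rows

    def __getitem__(self, marker: str) -> tuple[int, int]:
        return self.rows[marker]


@dataclass
class GeneRecord:
    """One gene locus from an annotation; coordinates 1-based inclusive."""

    locus_id: str
    chromosome: int
    start_bp: int
    end_bp: int
    strand: str = "."
    description: str = ""

    def __post_init__(self) -> None:
        # Some annotations list minus-strand loci with reversed coordinates.
        if self.start_bp > self.end_bp:
            self.start_bp, self.end_bp = self.end_bp, self.start_bp


@dataclass
class ProjectedQtl:
    """A QTL expressed on the consensus map with a Gaussian sd.

    ``ci95 == CI95_FACTOR * sigma`` always holds.
    """

    qtl_id: str
    chromosome: int
    position: float
    sigma: float
    ci95: float
    study_id: str = ""
    lod: float | None = None
    r2: float | None = None
    pop_size: int | None = None
    expansion: float = 1.0
    ci_source: str = "reported"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if abs(self.ci95 - CI95_FACTOR * self.sigma) > 1e-9 * max(1.0, self.ci95):
            raise ValueError("ci95 and sigma are inconsistent")


@dataclass
class PhysicalInterval:
    """Closed physical interval on a chromosome."""

    chromosome: int
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")

    @property
    def mb(self) -> float:
        return (self.end_bp - self.start_bp) / 1e6


@dataclass
class MetaQtl:
    """A consensus QTL summarizing one mixture component / cluster block."""

    mqtl_id: str
    chromosome: int
    position: float
    ci95_start: float
    ci95_end: float
    weight: float
    member_qtl: list[str] = field(default_factory=list)
    sigma: float = 0.0
    peak_marker: str | None = None
    flank_left: str | None = None
    flank_right: str | None = None
    physical_start: int | None = None
    physical_end: int | None = None

    @property
    def interval_mb(self) -> float | None:
        if self.physical_start is None or self.physical_end is None:
            return None
        return (self.physical_end - self.physical_start) / 1e6
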