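"""Shared annotation containers.

All coordinates are 0-based, half-open throughout the package; GFF3 emission
converts to 1-based closed at the boundary (see :mod:`genostruct.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

TE_CLASSES = ("DNA", "LTR", "non-LTR")
REPEAT_CLASSES = TE_CLASSES + ("satellite",)


@dataclass
class Gene:
    """Protein-coding gene model: one (longest-isoform) transcript per gene."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # sorted, non-overlapping, half-open
    cds: tuple[int, int]  # CDS extent within the transcript span

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)]

    def copy(self) -> "Gene":
        return replace(self, exons=list(self.exons))


@dataclass
class TRNAGene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    isotype: str  # one-letter amino acid
    anticodon: str  # DNA 3-mer
    pseudo: bool = False
    cluster: str = ""

    def copy(self) -> "TRNAGene":
        return replace(self)


@dataclass
class Repeat:
    """Classed repeat interval (TE or satellite)."""

    chrom: str
    start: int
    end: int
    strand: str
    family: str
    klass: str  # one of REPEAT_CLASSES
    repeat_id: str = ""
    source_event: str | None = None

    def copy(self) -> "Repeat":
        return replace(self)

    @property
    def length(self) -> int:
        return self.end - self.start


def interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Length of the intersection of two half-open intervals."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 for empty intervals."""
    la, lb = a[1] - a[0], b[1] - b[0]
    if la <= 0 or lb <= 0:
        return 0.0
    ov = interval_overlap(a, b)
    return min(ov / la, ov / lb)


@dataclass
class PlantedEvent:
    """One structural event planted by the simulator (truth-ledger row)."""

    event_id: str
    etype: str  # te_insertion | inversion | tandem_dup | dispersed_dup |
    #             satellite_change | trna_change | intron_indel
    branch: str
    taxa: tuple[str, ...]
    chrom: str
    start: int  # coordinates in the genome state at application time
    end: int
    payload: dict = field(default_factory=dict)


@dataclass
class TruthTable:
    """Planted events plus their lifted coordinates in each descendant taxon."""

    events: list[PlantedEvent]
    #: coords[taxon][event_id] -> (chrom, start, end) in that taxon's genome
    coords: dict[str, dict[str, tuple[str, int, int]]]

    def by_branch(self, branch: str, etype: str | None = None) -> list[PlantedEvent]:
        return [
            e
            for e in self.events
            if e.branch == branch and (etype is None or e.etype == etype)
        ]

    def by_type(self, etype: str) -> list[PlantedEvent]:
        return [e for e in self.events if e.etype == etype]
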