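"""Genomic domain objects shared across modules.

Coordinates are 0-based half-open internally; the GTF and RepeatMasker
readers/writers convert from/to the 1-based inclusive conventions of those
formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Interval:
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty/inverted interval [{self.start},{self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        """>=1 shared bp under half-open arithmetic."""
        return self.start < other.end and other.start < self.end

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass(frozen=True)
class RepeatFeature:
    """One RepeatMasker annotation row.

    ``family`` is the repeat name (e.g. "AluY", "AluSx", "L1MA4"); the
    ``is_alu`` property flags the Alu SINE families used for inverted-repeat
    pairing.
    """

    chrom: str
    start: int   # 0-based half-open
    end: int
    strand: str  # '+' or '-'
    family: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"repeat with start >= end: {self}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be +/-, got {self.strand!r}")

    @property
    def is_alu(self) -> bool:
        return self.family.startswith("Alu")

    @property
    def interval(self) -> Interval:
        return Interval(self.start, self.end)


@dataclass
class TranscriptModel:
    """A transcript: strand-aware exon chain plus an optional CDS span.

    Exons are genomic intervals, non-overlapping, stored sorted by start
    regardless of strand; transcript (5'->3') order is the reverse of genomic
    order on the minus strand.  ``cds_start``/``cds_end`` delimit the genomic
    span from the first base of the start codon to the last base of the stop
    codon.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval] = field(default_factory=list)
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be +/-, got {self.strand!r}")
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"overlapping exons in {self.transcript_id}: {a} vs {b}")

    @property
    def span(self) -> Interval:
        return Interval(self.exons[0].start, self.exons[-1].end)

    @property
    def introns(self) -> list[Interval]:
        return [Interval(a.end, b.start) for a, b in zip(self.exons, self.exons[1:])]

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None and self.cds_end is not None
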