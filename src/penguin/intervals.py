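"""Genomic intervals in 0-based half-open coordinates.

Every coordinate that enters the package is converted to this convention at
ingest (BED is read verbatim; FIMO and SNP positions, which are 1-based, are
shifted). Strand is carried for reporting but ignored by all overlap logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic span ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strand-agnostic >=1 bp overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def expand(self, pad: int) -> "GenomicInterval":
        """Pad both sides by ``pad`` bp, clipping the start at 0."""
        return GenomicInterval(self.chrom, max(0, self.start - pad), self.end + pad, self.strand)

    def distance(self, other: "GenomicInterval") -> int:
        """Gap in bp between two intervals on the same chromosome (0 if they overlap or touch)."""
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        if self.start < other.end and other.start < self.end:
            return 0
        return max(self.start - other.end, other.start - self.end, 0)


def check_chromosome_styles(*interval_groups) -> None:
    """Detect 'chr1' vs '1' naming mismatches across input files.

    Mismatches are reported, never silently harmonized.
    """
    prefixed, bare = set(), set()
    for group in interval_groups:
        for iv in group:
            (prefixed if iv.chrom.startswith("chr") else bare).add(iv.chrom)
    if prefixed and bare:
        raise ValueError(
            "chromosome naming styles differ between inputs: "
            f"{sorted(prefixed)[:3]} vs {sorted(bare)[:3]}"
        )
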