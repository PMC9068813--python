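"""Shared genomic data model.

Coordinates are 0-based, half-open everywhere in memory; 1-based labels
(e.g. the "1-200" crosslink distance window) appear only in report text.
Strand is one of ``+``, ``-`` or ``.`` (unstranded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def five_prime(self) -> int:
        """Position of the 5'-most base in transcript orientation."""
        return self.start if self.strand != "-" else self.end - 1

    def extended(self, flank: int) -> "GenomicInterval":
        """Interval widened by ``flank`` bp on both sides (clipped at 0)."""
        return GenomicInterval(
            self.chrom, max(0, self.start - flank), self.end + flank, self.strand,
            self.name, self.score,
        )

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptUnit:
    """A transcript unit (gene or eRNA) with per-condition expression density.

    ``expression`` maps a condition label (e.g. "KCl_30") to a non-negative
    read density in reads/bp.
    """

    id: str
    interval: GenomicInterval
    kind: str = "gene"  # "gene" or "eRNA"
    expression: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("gene", "eRNA"):
            raise ValueError(f"kind must be 'gene' or 'eRNA', got {self.kind!r}")
        for cond, value in self.expression.items():
            if value < 0:
                raise ValueError(f"expression[{cond!r}] must be >= 0, got {value}")

    @property
    def tss(self) -> int:
        return self.interval.five_prime()


@dataclass(frozen=True)
class SiteRecord:
    """A single-base event (5'-end read pileup or crosslink site)."""

    chrom: str
    position: int
    strand: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"position must be >= 0, got {self.position}")
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")


class CoverageTrack:
    """Per-chromosome, per-strand arrays of signal at single-base resolution.

    Arrays are allocated lazily per (chrom, strand) and always span the full
    chromosome length, so total signal is conserved under I/O round-trips.
    """

    def __init__(self, chrom_sizes: Mapping[str, int]):
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes)
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive size {size}")
        self._arrays: dict[tuple[str, str], np.ndarray] = {}

    def array(self, chrom: str, strand: str) -> np.ndarray:
        if chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if strand not in ("+", "-"):
            raise ValueError("tracks store explicit strands '+' and '-' only")
        key = (chrom, strand)
        if key not in self._arrays:
            self._arrays[key] = np.zeros(self.chrom_sizes[chrom], dtype=np.float64)
        return self._arrays[key]

    def add_interval(self, chrom: str, start: int, end: int, value: float,
                     strand: str) -> None:
        if value < 0:
            raise ValueError(f"coverage values must be >= 0, got {value}")
        size = self.chrom_sizes.get(chrom)
        if size is None:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > size or start >= end:
            raise ValueError(
                f"interval [{start}, {end}) out of bounds for {chrom} (size {size})"
            )
        self.array(chrom, strand)[start:end] += value

    def add_sites(self, sites: Iterable[SiteRecord]) -> None:
        for site in sites:
            strand = "+" if site.strand == "." else site.strand
            arr = self.array(site.chrom, strand)
            if site.position >= arr.size:
                raise ValueError(
                    f"position {site.position} out of bounds for {site.chrom}"
                )
            arr[site.position] += site.count

    def window_sum(self, chrom: str, start: int, end: int, strand: str = ".") -> float:
        size = self.chrom_sizes.get(chrom)
        if size is None:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > size:
            raise ValueError(
                f"window [{start}, {end}) out of bounds for {chrom} (size {size})"
            )
        strands = ("+", "-") if strand == "." else (strand,)
        total = 0.0
        for s in strands:
            if (chrom, s) in self._arrays:
                total += float(self._arrays[(chrom, s)][start:end].sum())
        return total

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self._arrays.values()))

    def scaled(self, factor: float) -> "CoverageTrack":
        """A copy with every value multiplied by ``factor`` (>= 0)."""
        if factor < 0:
            raise ValueError("scale factor must be >= 0")
        out = CoverageTrack(self.chrom_sizes)
        for key, arr in self._arrays.items():
            out._arrays[key] = arr * factor
        return out

    def items(self):
        return self._arrays.items()


def window_density(track: CoverageTrack, interval: GenomicInterval) -> float:
    """Read density (reads/bp) over an interval on its own strand.

    Unstranded intervals sum both strands.
    """
    if interval.length == 0:
        raise ValueError("zero-length window has no density")
    total = track.window_sum(interval.chrom, interval.start, interval.end,
                             interval.strand)
    return total / interval.length
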