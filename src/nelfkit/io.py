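"""Readers and writers for the plain-text genomic formats the pipeline touches.

Supported: BED6, strand-split bedGraph pairs, chrom.sizes, site tables
(BED6 with score = count), FASTA (via Biopython) and generic TSV tables.
bedGraph is accepted with space- or tab-separated columns and written
tab-separated.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CoverageTrack, GenomicInterval, SiteRecord


class ParseError(ValueError):
    """A malformed line in a text format, reported with its line number."""


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom.sizes`` TSV into a dict."""
    sizes: dict[str, int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad chromosome size") from exc
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as handle:
        for chrom, size in sizes.items():
            handle.write(f"{chrom}\t{size}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED (>=3 columns) preserving name, score and strand when present."""
    intervals: list[GenomicInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: BED line needs >= 3 tab-separated fields"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, strand, name, score)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as handle:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = _fmt_number(iv.score) if iv.score is not None else "0"
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


def _fmt_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def _read_bedgraph_into(track: CoverageTrack, path: str | Path, strand: str) -> None:
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()  # tolerate space or tab separation
            if len(fields) != 4:
                raise ParseError(
                    f"{path}:{lineno}: bedGraph line needs 4 fields, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed bedGraph line") from exc
            if value < 0:
                raise ParseError(f"{path}:{lineno}: negative coverage value {value}")
            try:
                track.add_interval(chrom, start, end, value, strand)
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc


def read_bedgraph_pair(path_plus: str | Path, path_minus: str | Path,
                       chrom_sizes: Mapping[str, int]) -> CoverageTrack:
    """Expand a plus/minus bedGraph file pair onto per-base strand arrays.

    Overlapping bedGraph lines are summed.
    """
    track = CoverageTrack(chrom_sizes)
    _read_bedgraph_into(track, path_plus, "+")
    _read_bedgraph_into(track, path_minus, "-")
    return track


def write_bedgraph_pair(track: CoverageTrack, path_plus: str | Path,
                        path_minus: str | Path) -> None:
    """Write one bedGraph per strand, run-length collapsing equal values."""
    for strand, path in (("+", path_plus), ("-", path_minus)):
        with open(path, "w") as handle:
            for (chrom, s), arr in sorted(track.items()):
                if s != strand:
                    continue
                start = None
                current = 0.0
                for pos, value in enumerate(arr):
                    if value != current:
                        if start is not None and current != 0.0:
                            handle.write(
                                f"{chrom}\t{start}\t{pos}\t{_fmt_number(current)}\n"
                            )
                        start, current = pos, float(value)
                if start is not None and current != 0.0:
                    handle.write(
                        f"{chrom}\t{start}\t{arr.size}\t{_fmt_number(current)}\n"
                    )


def read_sites(path: str | Path) -> list[SiteRecord]:
    """Read a site table stored as BED6 with score = count."""
    sites = []
    for iv in read_bed(path):
        if iv.length != 1:
            raise ParseError(f"{path}: site intervals must be 1 bp, got {iv.length}")
        count = int(iv.score) if iv.score is not None else 1
        sites.append(SiteRecord(iv.chrom, iv.start, iv.strand, count))
    return sites


def write_sites(sites: Iterable[SiteRecord], path: str | Path) -> None:
    write_bed(
        (
            GenomicInterval(s.chrom, s.position, s.position + 1, s.strand,
                            name=".", score=float(s.count))
            for s in sites
        ),
        path,
    )


def sites_to_frame(sites: Sequence[SiteRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "position": [s.position for s in sites],
            "strand": [s.strand for s in sites],
            "count": [s.count for s in sites],
        }
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_ground_truth(truth: Mapping, path: str | Path) -> None:
    """JSON sidecar carrying a generator's ground truth."""
    with open(path, "w") as handle:
        json.dump(truth, handle, indent=1, default=_jsonable)


def _jsonable(obj):
    if hasattr(obj, "tolist"):
        return obj.tolist()
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
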