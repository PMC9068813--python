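"""TSS calling from 5'-end read pileups and enhancer-TSS assignment.

Calling is strand-wise single-linkage clustering of site positions with an
explicit merge gap; the called TSS is the cluster's maximum-count position
(ties broken toward the 5'-most position in transcript orientation).  A
separate ">20 reads" flag marks well-defined TSSs; it is a flag, not a
filter, reflecting the two-tier usage of read support in enhancer-TSS
catalogs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .core import GenomicInterval, SiteRecord, TranscriptUnit

WELL_DEFINED_READS = 20  # strict "> 20 reads" rule


@dataclass
class TssCall:
    """A called transcription start site."""

    site: SiteRecord
    cluster_span: GenomicInterval
    read_count: int
    cluster_count: int
    well_defined: bool
    assigned_unit: str | None = None
    distance_to_unit_5p: int | None = None

    def __post_init__(self) -> None:
        if self.read_count > self.cluster_count:
            raise ValueError("called-position count cannot exceed cluster count")


def call_tss(
    sites: Sequence[SiteRecord],
    min_cluster_reads: int = 5,
    merge_gap: int = 25,
    well_defined_on: str = "position",
) -> list[TssCall]:
    """Cluster 5'-end sites and call one TSS per cluster.

    Positions on the same chromosome and strand whose gaps are <= merge_gap
    join one cluster (single linkage); clusters with total reads below
    ``min_cluster_reads`` are dropped.  ``well_defined_on`` selects whether
    the >20-read flag counts the called position or the whole cluster.
    """
    if well_defined_on not in ("position", "cluster"):
        raise ValueError("well_defined_on must be 'position' or 'cluster'")
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    by_group: dict[tuple[str, str], dict[int, int]] = {}
    for site in sites:
        group = by_group.setdefault((site.chrom, site.strand), {})
        group[site.position] = group.get(site.position, 0) + site.count

    calls: list[TssCall] = []
    for (chrom, strand), counts in sorted(by_group.items()):
        positions = sorted(counts)
        cluster: list[int] = []
        for pos in positions:
            if cluster and pos - cluster[-1] > merge_gap:
                calls.extend(
                    _emit(chrom, strand, cluster, counts, min_cluster_reads,
                          well_defined_on)
                )
                cluster = []
            cluster.append(pos)
        if cluster:
            calls.extend(
                _emit(chrom, strand, cluster, counts, min_cluster_reads,
                      well_defined_on)
            )
    return calls


def _emit(chrom, strand, cluster, counts, min_cluster_reads, well_defined_on):
    total = sum(counts[p] for p in cluster)
    if total < min_cluster_reads:
        return
    best = max(counts[p] for p in cluster)
    candidates = [p for p in cluster if counts[p] == best]
    # tie toward the 5'-most position in transcript orientation
    called = min(candidates) if strand != "-" else max(candidates)
    basis = counts[called] if well_defined_on == "position" else total
    yield TssCall(
        site=SiteRecord(chrom, called, strand, counts[called]),
        cluster_span=GenomicInterval(chrom, cluster[0], cluster[-1] + 1, strand),
        read_count=counts[called],
        cluster_count=total,
        well_defined=basis > WELL_DEFINED_READS,
    )


def filter_extragenic(
    calls: Iterable[TssCall],
    gene_annotations: Sequence[GenomicInterval],
    flank: int = 2_000,
) -> list[TssCall]:
    """Keep calls outside every gene extended by ``flank`` bp, strand-agnostic.

    The extension is half-open: a call exactly at gene_end + flank survives.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for gene in gene_annotations:
        by_chrom.setdefault(gene.chrom, []).append(
            (max(0, gene.start - flank), gene.end + flank)
        )
    kept = []
    for call in calls:
        spans = by_chrom.get(call.site.chrom, ())
        pos = call.site.position
        if not any(lo <= pos < hi for lo, hi in spans):
            kept.append(call)
    return kept


def filter_convergent(
    calls: Iterable[TssCall],
    sites: Sequence[SiteRecord],
    window: int = 200,
    max_antisense_fraction: float = 0.5,
) -> list[TssCall]:
    """Reject calls dominated by antisense 5'-end signal near the TSS.

    An explicit surrogate for curating away pervasive or convergent
    transcription: a call is dropped when antisense read counts within
    +/-window of the called position exceed ``max_antisense_fraction`` of
    the sense counts.
    """
    kept = []
    for call in calls:
        pos, strand = call.site.position, call.site.strand
        sense = antisense = 0
        for site in sites:
            if site.chrom != call.site.chrom or abs(site.position - pos) > window:
                continue
            if site.strand == strand:
                sense += site.count
            else:
                antisense += site.count
        if sense > 0 and antisense <= max_antisense_fraction * sense:
            kept.append(call)
    return kept


def _signed_distance(position: int, unit: TranscriptUnit) -> int:
    """Signed bp from the unit 5'-end, positive downstream in transcript frame."""
    if unit.interval.strand != "-":
        return position - unit.interval.start
    return (unit.interval.end - 1) - position


def assign_enhancer_tss(
    calls: Sequence[TssCall],
    enhancer_units: Sequence[TranscriptUnit],
    offset: int = 200,
) -> dict[str, TssCall]:
    """Pick one TSS call per enhancer unit.

    Candidates are same-strand calls within the unit extended by ``offset``
    nt.  The winner has the highest called-position read count; ties go to
    the smallest absolute distance to the unit 5'-end, then to the 5'-most
    (smallest signed distance).  Units with no candidate are absent from the
    mapping.  A call inside two overlapping units may win both.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    assigned: dict[str, TssCall] = {}
    for unit in enhancer_units:
        span = unit.interval.extended(offset)
        candidates = [
            call for call in calls
            if call.site.chrom == span.chrom
            and call.site.strand == unit.interval.strand
            and span.contains(call.site.position)
        ]
        if not candidates:
            continue
        def key(call: TssCall):
            d = _signed_distance(call.site.position, unit)
            return (-call.read_count, abs(d), d)
        winner = min(candidates, key=key)
        assigned[unit.id] = replace(
            winner,
            assigned_unit=unit.id,
            distance_to_unit_5p=_signed_distance(winner.site.position, unit),
        )
    return assigned


def classify_induction(
    units: Sequence[TranscriptUnit],
    baseline_condition: str,
    fold_threshold: float = 1.5,
    pseudocount: float = 0.0,
) -> dict[str, bool]:
    """Flag units whose expression rises >fold_threshold over baseline.

    Induction is strict (>): a fold change of exactly the threshold does not
    induce.  With the default pseudocount of 0, a unit with zero baseline
    and any nonzero stimulated signal is induced; a unit silent everywhere
    is not.
    """
    flags: dict[str, bool] = {}
    for unit in units:
        if baseline_condition not in unit.expression:
            raise KeyError(
                f"unit {unit.id} lacks baseline condition {baseline_condition!r}"
            )
        base = unit.expression[baseline_condition] + pseudocount
        induced = False
        for cond, value in unit.expression.items():
            if cond == baseline_condition:
                continue
            stim = value + pseudocount
            if base == 0:
                if stim > 0:
                    induced = True
            elif stim / base > fold_threshold:
                induced = True
        flags[unit.id] = induced
    return flags
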