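"""eCLIP crosslink-site extraction, transcript assignment and positional
statistics.

The first nucleotide of the eCLIP R2 read marks the protein-RNA crosslink
site.  Sites are assigned to transcript units on the same strand; the
distance from the unit 5'-end is reported 1-based (distance 1 = the 5'-most
nucleotide) so that window labels such as "1-200" read naturally, while all
genomic coordinates stay 0-based half-open internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import SiteRecord, TranscriptUnit

DEFAULT_EDGES = (200, 400, 600, 800, 1000, 2000)


@dataclass
class WindowDistribution:
    """Counts of crosslink distances per 1-based distance window."""

    edges: tuple[int, ...]
    counts: np.ndarray
    dropped: int = 0  # distances beyond the last edge

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.edges) != self.counts.size:
            raise ValueError("one count per window edge required")
        if any(e2 <= e1 for e1, e2 in zip(self.edges, self.edges[1:])):
            raise ValueError("window edges must be strictly increasing")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray | None:
        """Counts / total over retained sites; None when the total is zero."""
        if self.total == 0:
            warnings.warn("empty window distribution; proportions undefined")
            return None
        return self.counts / self.total

    @property
    def labels(self) -> list[str]:
        lo = 1
        out = []
        for edge in self.edges:
            out.append(f"{lo}-{edge}")
            lo = edge + 1
        return out


def extract_crosslink_sites(
    read_records: pd.DataFrame | Iterable[tuple[str, int, str]],
    dedup: bool = False,
) -> list[SiteRecord]:
    """Turn R2 first-nucleotide read records into per-position site counts.

    ``read_records`` carries (chrom, position, strand) per read, with the
    position being the 5'-most genomic position of R2 in transcript
    orientation.  ``dedup=True`` collapses byte-identical records to one
    event before counting (PCR-duplicate removal proper happens upstream).
    """
    if isinstance(read_records, pd.DataFrame):
        rows = list(zip(read_records["chrom"], read_records["position"],
                        read_records["strand"]))
    else:
        rows = [(c, int(p), s) for c, p, s in read_records]
    if dedup:
        rows = list(dict.fromkeys(rows))
    counts: dict[tuple[str, int, str], int] = {}
    for key in rows:
        counts[key] = counts.get(key, 0) + 1
    return [SiteRecord(c, p, s, n) for (c, p, s), n in sorted(counts.items())]


def assign_to_units(
    sites: Sequence[SiteRecord],
    units: Sequence[TranscriptUnit],
) -> tuple[pd.DataFrame, int]:
    """Assign sites to containing same-strand units with 1-based distances.

    Returns (assignment table, number of site records in no unit).  A site
    inside several overlapping units is assigned to each of them, flagged in
    the ``multi`` column.
    """
    rows = []
    unassigned = 0
    for site in sites:
        hits = []
        for unit in units:
            iv = unit.interval
            if (iv.chrom == site.chrom and iv.strand == site.strand
                    and iv.contains(site.position)):
                if iv.strand != "-":
                    distance = site.position - iv.start + 1
                else:
                    distance = (iv.end - 1) - site.position + 1
                hits.append((unit.id, distance))
        if not hits:
            unassigned += 1
            continue
        for unit_id, distance in hits:
            rows.append({
                "chrom": site.chrom,
                "position": site.position,
                "strand": site.strand,
                "count": site.count,
                "unit_id": unit_id,
                "distance": distance,
                "multi": len(hits) > 1,
            })
    columns = ["chrom", "position", "strand", "count", "unit_id", "distance",
               "multi"]
    return pd.DataFrame(rows, columns=columns), unassigned


def window_distribution(
    assignments: pd.DataFrame | Iterable[int],
    edges: Sequence[int] = DEFAULT_EDGES,
    weights: Iterable[int] | None = None,
) -> WindowDistribution:
    """Count crosslink distances per half-open window (prev_edge, edge].

    Accepts the assignment table (using its ``distance`` and ``count``
    columns) or a bare distance sequence.  Distances beyond the last edge
    are dropped and counted in ``dropped``.
    """
    if isinstance(assignments, pd.DataFrame):
        distances = assignments["distance"].to_numpy()
        w = assignments["count"].to_numpy()
    else:
        distances = np.asarray(list(assignments), dtype=int)
        w = (np.asarray(list(weights), dtype=int) if weights is not None
             else np.ones(distances.size, dtype=int))
    if np.any(distances < 1):
        raise ValueError("distances are 1-based and must be >= 1")
    edges = tuple(int(e) for e in edges)
    bounds = (0,) + edges
    counts = np.zeros(len(edges), dtype=int)
    for i in range(len(edges)):
        mask = (distances > bounds[i]) & (distances <= bounds[i + 1])
        counts[i] = int(w[mask].sum())
    dropped = int(w[distances > edges[-1]].sum())
    return WindowDistribution(edges, counts, dropped)


def normalized_profile(
    assignments: pd.DataFrame,
    expression: Mapping[str, float],
    span: int = 600,
    binsize: int = 10,
) -> pd.DataFrame:
    """Expression-normalized crosslink meta-profile over the first ``span`` nt.

    Each unit's per-position crosslink counts are divided by that unit's
    expression density (reads/bp) and the resulting curves are averaged over
    units that contain at least one crosslink; units with zero expression
    are excluded (their number is reported in the ``n_excluded`` attribute
    of the returned frame).  The curve is then averaged into ``binsize``-nt
    bins whose ``bin_start`` column is the 1-based first distance of the bin.
    """
    if span % binsize != 0:
        raise ValueError("span must be a multiple of binsize")
    unit_ids = assignments["unit_id"].unique()
    curves = []
    excluded = 0
    for uid in unit_ids:
        expr = expression.get(uid, 0.0)
        sub = assignments[assignments["unit_id"] == uid]
        if expr <= 0:
            excluded += 1
            continue
        curve = np.zeros(span, dtype=float)
        within = sub[sub["distance"] <= span]
        np.add.at(curve, within["distance"].to_numpy() - 1,
                  within["count"].to_numpy().astype(float))
        curves.append(curve / expr)
    if not curves:
        raise ValueError("no unit with crosslinks and positive expression")
    mean_curve = np.mean(curves, axis=0)
    binned = mean_curve.reshape(-1, binsize).mean(axis=1)
    frame = pd.DataFrame({
        "bin_start": np.arange(0, span, binsize) + 1,
        "normalized_coverage": binned,
    })
    frame.attrs["n_units"] = len(curves)
    frame.attrs["n_excluded"] = excluded
    return frame


def compare_window_distributions(
    dist_a: WindowDistribution,
    dist_b: WindowDistribution,
) -> tuple[float, float]:
    """Pearson chi-squared on the 2 x k table of window counts.

    No continuity correction (k is typically 3 or 6); expected cells below 1
    trigger a warning but the statistic is still returned.
    """
    if dist_a.edges != dist_b.edges:
        raise ValueError("distributions must share window edges")
    table = np.vstack([dist_a.counts, dist_b.counts])
    keep = table.sum(axis=0) > 0  # all-zero windows carry no information
    table = table[:, keep]
    if table.shape[1] < 2:
        raise ValueError("need at least two non-empty windows to compare")
    stat, p, _, expected = stats.chi2_contingency(table, correction=False)
    if np.any(expected < 1):
        warnings.warn("expected cell count < 1; chi-squared may be unreliable")
    return float(stat), float(p)


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values for report tables."""
    return stats.false_discovery_control(np.asarray(list(p_values), dtype=float))
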