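"""Pausing indices from strand-specific nascent coverage, NELF occupancy
grouping, and distribution comparisons.

The pausing index (PI) is the ratio of nascent-read density in a
promoter-proximal window (default TSS-100 .. TSS+200) to the density in a
gene-body window (default TSS+400 .. TSS+800), both taken on the unit's own
strand and flipped on minus-strand units.  A zero body density leaves the PI
undefined (not infinite); undefined PIs are excluded from distribution
comparisons and their number reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CoverageTrack, GenomicInterval, TranscriptUnit, window_density

PROMOTER_WINDOW = (-100, 200)  # bp relative to TSS, transcript frame
BODY_WINDOW = (400, 800)


@dataclass
class PausingIndex:
    unit_id: str
    promoter_density: float
    body_density: float
    pi: float | None  # None when body density is zero

    @property
    def defined(self) -> bool:
        return self.pi is not None


@dataclass
class NelfGroup:
    unit_id: str
    bound: bool
    tier: str  # high / mid / low / unbound


def _oriented_window(tss: int, strand: str, window: tuple[int, int],
                     chrom: str) -> GenomicInterval:
    """Genomic interval for a transcript-frame window [a, b) downstream of tss."""
    a, b = window
    if strand != "-":
        start, end = tss + a, tss + b
    else:
        start, end = tss - b + 1, tss - a + 1
    return GenomicInterval(chrom, start, end, strand if strand != "-" else "-")


def pausing_index(
    track: CoverageTrack,
    unit: TranscriptUnit,
    promoter_window: tuple[int, int] = PROMOTER_WINDOW,
    body_window: tuple[int, int] = BODY_WINDOW,
) -> PausingIndex | None:
    """PI of one unit; returns None (with a warning) if windows fall outside
    the chromosome."""
    iv = unit.interval
    tss = unit.tss
    try:
        prom = _oriented_window(tss, iv.strand, promoter_window, iv.chrom)
        body = _oriented_window(tss, iv.strand, body_window, iv.chrom)
        prom_d = window_density(track, prom)
        body_d = window_density(track, body)
    except (ValueError, KeyError) as exc:
        warnings.warn(f"unit {unit.id} skipped: {exc}")
        return None
    pi = prom_d / body_d if body_d > 0 else None
    return PausingIndex(unit.id, prom_d, body_d, pi)


def pausing_index_table(
    track: CoverageTrack,
    units: Sequence[TranscriptUnit],
    **kwargs,
) -> pd.DataFrame:
    """Per-unit PI table; undefined and skipped units are flagged, not dropped."""
    rows = []
    for unit in units:
        result = pausing_index(track, unit, **kwargs)
        if result is None:
            rows.append({"unit_id": unit.id, "promoter_density": math.nan,
                         "body_density": math.nan, "pi": math.nan,
                         "status": "skipped"})
        else:
            rows.append({
                "unit_id": result.unit_id,
                "promoter_density": result.promoter_density,
                "body_density": result.body_density,
                "pi": result.pi if result.defined else math.nan,
                "status": "ok" if result.defined else "undefined",
            })
    return pd.DataFrame(rows)


def nelf_tiers(
    chip_scores: Mapping[str, float],
    bound_threshold: float | None = None,
    bound_ids: Iterable[str] | None = None,
    tier_quantiles: tuple[float, float] = (1 / 3, 2 / 3),
) -> dict[str, NelfGroup]:
    """Group units by NELF promoter occupancy.

    A unit is bound when its ChIP score reaches ``bound_threshold`` or when
    its id is in ``bound_ids`` (e.g. derived from peak overlap); bound units
    are split at score quantiles (default tertiles) into low/mid/high.  The
    tertile default is a documented surrogate: published group sizes do not
    pin down the exact rule.
    """
    if bound_threshold is None and bound_ids is None:
        raise ValueError("supply bound_threshold or bound_ids")
    bound_set = set(bound_ids) if bound_ids is not None else None

    def is_bound(uid: str, score: float) -> bool:
        if bound_set is not None:
            return uid in bound_set
        return score >= bound_threshold

    bound_scores = [s for uid, s in chip_scores.items() if is_bound(uid, s)]
    groups: dict[str, NelfGroup] = {}
    if bound_scores:
        q_low, q_high = np.quantile(bound_scores, tier_quantiles)
    for uid, score in chip_scores.items():
        if not is_bound(uid, score):
            groups[uid] = NelfGroup(uid, False, "unbound")
        elif score <= q_low:
            groups[uid] = NelfGroup(uid, True, "low")
        elif score <= q_high:
            groups[uid] = NelfGroup(uid, True, "mid")
        else:
            groups[uid] = NelfGroup(uid, True, "high")
    return groups


def compare_pi_distributions(
    pis_a: Iterable[float | None],
    pis_b: Iterable[float | None],
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on defined PI values only."""
    a = _defined(pis_a)
    b = _defined(pis_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples need at least one defined PI")
    result = stats.ks_2samp(a, b)
    return float(result.statistic), float(result.pvalue)


def ecdf_table(values: Iterable[float | None]) -> pd.DataFrame:
    """Cumulative-probability curve of defined values, for plotting."""
    v = np.sort(_defined(values))
    return pd.DataFrame({
        "value": v,
        "cumulative_probability": np.arange(1, v.size + 1) / v.size,
    })


def _defined(values: Iterable[float | None]) -> np.ndarray:
    out = [v for v in values if v is not None and not math.isnan(v)]
    return np.asarray(out, dtype=float)
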