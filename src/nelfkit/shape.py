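"""SHAPE-MaP reactivities, structure classification and positional G-content.

Reactivity is computed from two channels (1M7-modified vs untreated/DMSO):
raw reactivity = modified mutation rate - untreated mutation rate, retained
unclamped by default.  Normalization follows the box-plot variant of the
2-8% rule: raw values above Q3 + 1.5*IQR are excluded as outliers, and the
scale is the mean of the remaining values between their 90th and 98th
percentiles; normalized reactivity = raw / scale.

An RNA is classified by its median normalized reactivity over unmasked
positions: structured below 0.1, intermediate below 0.15, flexible
otherwise (strict '<' at both cutoffs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

STRUCTURED_CUTOFF = 0.1
INTERMEDIATE_CUTOFF = 0.15

REQUIRED_COLUMNS = ("mod_count", "mod_depth", "unt_count", "unt_depth")


@dataclass
class ShapeProfile:
    """Per-nucleotide reactivity profile of one RNA."""

    rna_id: str
    raw: np.ndarray
    normalized: np.ndarray
    mask: np.ndarray  # True = masked (low depth), excluded from summaries
    scale: float
    sequence: str | None = None

    @property
    def n_unmasked(self) -> int:
        return int((~self.mask).sum())

    def median_reactivity(self, which: str = "normalized") -> float:
        values = self.normalized if which == "normalized" else self.raw
        return float(np.median(values[~self.mask]))


def boxplot_normalization_scale(raw: np.ndarray) -> float:
    """Normalization scale by the box-plot / 2-8% rule.

    Excludes values above Q3 + 1.5*IQR — but never more than the top 10% of
    positions, so a large reactive fraction cannot be discarded wholesale —
    then averages the survivors lying between their 90th and 98th
    percentiles.
    """
    values = np.sort(np.asarray(raw, dtype=float))
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("no values to normalize")
    q1, q3 = np.percentile(values, [25, 75])
    n_out = int((values > q3 + 1.5 * (q3 - q1)).sum())
    n_out = min(n_out, values.size // 10)
    kept = values[:values.size - n_out] if n_out else values
    lo, hi = np.percentile(kept, [90, 98])
    window = kept[(kept >= lo) & (kept <= hi)]
    scale = float(window.mean())
    if scale <= 0:
        raise ValueError("non-positive normalization scale; profile has no signal")
    return scale


def shape_reactivity(
    counts: pd.DataFrame,
    min_depth: int = 1_000,
    rna_id: str = "rna",
    clamp_negative: bool = False,
) -> ShapeProfile:
    """Reactivities from a mutation-count table.

    ``counts`` needs columns mod_count, mod_depth, unt_count, unt_depth (one
    row per nucleotide, in order).  Positions where either channel's depth is
    below ``min_depth`` are masked.  Negative raw reactivities are retained
    unless ``clamp_negative``.
    """
    for col in REQUIRED_COLUMNS:
        if col not in counts.columns:
            raise ValueError(f"missing column {col!r}")
    mod_count = counts["mod_count"].to_numpy(dtype=float)
    mod_depth = counts["mod_depth"].to_numpy(dtype=float)
    unt_count = counts["unt_count"].to_numpy(dtype=float)
    unt_depth = counts["unt_depth"].to_numpy(dtype=float)
    if np.any(mod_count > mod_depth) or np.any(unt_count > unt_depth):
        raise ValueError("mutation counts cannot exceed depths")

    mask = (mod_depth < min_depth) | (unt_depth < min_depth)
    if mask.all():
        raise ValueError("insufficient depth: every position is masked")
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mod_depth > 0, mod_count / mod_depth, np.nan) - \
            np.where(unt_depth > 0, unt_count / unt_depth, np.nan)
    raw = np.where(mask, np.nan, raw)
    if clamp_negative:
        raw = np.where(raw < 0, 0.0, raw)
    scale = boxplot_normalization_scale(raw[~mask])
    normalized = raw / scale
    sequence = "".join(counts["seq"]) if "seq" in counts.columns else None
    return ShapeProfile(rna_id, raw, normalized, mask, scale, sequence)


def median_reactivity_class(
    profile: ShapeProfile,
    structured_cutoff: float = STRUCTURED_CUTOFF,
    intermediate_cutoff: float = INTERMEDIATE_CUTOFF,
    which: str = "normalized",
) -> tuple[str, float]:
    """Classify an RNA by median reactivity over unmasked positions."""
    median = profile.median_reactivity(which)
    if median < structured_cutoff:
        return "structured", median
    if median < intermediate_cutoff:
        return "intermediate", median
    return "flexible", median


def reactivity_auc(profile: ShapeProfile, paired_mask: Sequence[bool]) -> float:
    """AUC for ranking unpaired above paired positions by normalized reactivity.

    Probability (via the Mann-Whitney U statistic) that a random unpaired
    position is more reactive than a random paired one; 0.5 means no
    structural signal.
    """
    paired = np.asarray(paired_mask, dtype=bool)
    keep = ~profile.mask
    x = profile.normalized[keep & ~paired]  # unpaired
    y = profile.normalized[keep & paired]
    if x.size == 0 or y.size == 0:
        raise ValueError("need both paired and unpaired unmasked positions")
    u, _ = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(u / (x.size * y.size))


def _clean_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def dedup_alternative_tss(
    tss_positions: Mapping[str, tuple[str, int]],
    dedup_distance: int = 40,
) -> list[str]:
    """Collapse alternative TSSs closer than ``dedup_distance`` nt.

    Within each chromosome, TSSs are scanned in position order and a TSS
    closer than the threshold to the previously retained one is dropped
    (the 5'-most of a close pair survives; ties keep the first id sorted
    lexicographically).
    """
    kept: list[str] = []
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for rna_id, (chrom, pos) in tss_positions.items():
        by_chrom.setdefault(chrom, []).append((pos, rna_id))
    for chrom in sorted(by_chrom):
        last_pos = None
        for pos, rna_id in sorted(by_chrom[chrom]):
            if last_pos is not None and pos - last_pos < dedup_distance:
                continue
            kept.append(rna_id)
            last_pos = pos
    return kept


def g_content_bins(
    sequences: Mapping[str, str],
    tss_positions: Mapping[str, tuple[str, int]] | None = None,
    dedup_distance: int = 40,
    bin_size: int = 200,
    n_bins: int = 5,
    include_partial: bool = False,
) -> pd.DataFrame:
    """Per-RNA nucleotide frequencies in fixed-size bins from the 5'-end.

    Defaults follow the positional G-content analysis: 200-nt bins over the
    first kilobase, with alternative TSSs within 40 nt collapsed to one.
    Sequences shorter than the full extent contribute only complete bins
    unless ``include_partial``; partial bins are flagged.
    """
    if tss_positions is not None:
        keep = set(dedup_alternative_tss(tss_positions, dedup_distance))
        sequences = {k: v for k, v in sequences.items() if k in keep}
    rows = []
    for rna_id in sorted(sequences):
        seq = _clean_rna(sequences[rna_id])
        for b in range(n_bins):
            chunk = seq[b * bin_size:(b + 1) * bin_size]
            if not chunk:
                break
            partial = len(chunk) < bin_size
            if partial and not include_partial:
                break
            counted = [c for c in chunk if c in "ACGU"]
            total = len(counted)
            if total == 0:
                continue
            rows.append({
                "rna_id": rna_id,
                "bin": b,
                "bin_label": f"{b * bin_size + 1}-{(b + 1) * bin_size}",
                "A": counted.count("A") / total,
                "C": counted.count("C") / total,
                "G": counted.count("G") / total,
                "U": counted.count("U") / total,
                "n_bases": total,
                "partial": partial,
            })
    return pd.DataFrame(rows, columns=["rna_id", "bin", "bin_label",
                                       "A", "C", "G", "U", "n_bases", "partial"])


def g_enrichment_test(bins: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests of G frequency against A, C and U, per bin.

    Pairs are RNAs present in the bin; two-sided p-values plus BH-adjusted
    values (across all bin x comparison cells) are reported.
    """
    rows = []
    for b in sorted(bins["bin"].unique()):
        sub = bins[bins["bin"] == b]
        g = sub["G"].to_numpy()
        for other in ("A", "C", "U"):
            o = sub[other].to_numpy()
            t, p = _paired_t(g, o)
            rows.append({"bin": int(b), "comparison": f"{other}/G",
                         "n": g.size, "t": t, "p": p})
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame["p_adj"] = stats.false_discovery_control(frame["p"].to_numpy())
    return frame


def _paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    diff = x - y
    if np.allclose(diff, 0.0):
        return 0.0, 1.0  # identical frequencies: no evidence either way
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)
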