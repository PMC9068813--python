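"""Synthetic data generators for every pipeline stage.

Each generator emits ground truth alongside the data so that downstream
stages can be tested for parameter recovery without any download.  All
generators are deterministic for a fixed seed; independent stages draw from
per-generator substreams derived from the global seed by fixed offsets, so
they stay reproducible when run alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import emsa
from .core import CoverageTrack, GenomicInterval, SiteRecord, TranscriptUnit

# substream offsets, one per generator
_NASCENT, _FIVEPRIME, _CROSSLINK, _BINDING, _SHAPE, _XLMS = range(1, 7)


@dataclass
class SimConfig:
    """Parameters of the synthetic study conditions.

    Defaults mirror the assay conditions the analyses assume: a 0.1 uM PEC
    titrated with 0.15-1.8 uM eRNA, ~70% of NELF crosslink sites within the
    first 200 nt of a transcript, paused genes probed at the standard
    pausing-index windows, and SHAPE modification rates that separate paired
    from unpaired nucleotides at realistic depth.
    """

    seed: int = 0
    # genome layout
    chrom: str = "chrS"
    chrom_length: int = 300_000
    n_genes: int = 12
    gene_length: int = 2_000
    n_enhancers: int = 10
    enhancer_length: int = 600
    # nascent transcription
    pausing_index_true: float = 5.0
    reads_per_gene: int = 100_000
    conditions: tuple[str, ...] = ("KCl_0", "KCl_10", "KCl_30", "KCl_60")
    baseline_condition: str = "KCl_0"
    induction_fold: float | Mapping[str, Mapping[str, float]] = 1.0
    promoter_window: tuple[int, int] = (-100, 200)
    # 5'-end reads
    tss_positions: Sequence[int] | None = None
    tss_read_mean: float = 50.0
    tss_jitter_mass: float = 0.2  # read mass landing within +/-2 nt but off the TSS
    background_rate: float = 0.01  # uniform background, reads per bp
    # eCLIP crosslinks
    crosslink_5prime_fraction: float = 0.7
    crosslinks_per_unit: int = 200
    first_window: int = 200  # nt
    # binding curves
    kd_true: float = 0.14  # uM
    amplitude_true: float = 1.0
    noise_sd: float = 0.05
    receptor_total: float = emsa.STANDARD_RECEPTOR_TOTAL
    concentrations: tuple[float, ...] = emsa.STANDARD_CONCENTRATIONS
    # SHAPE-MaP
    mod_rate_unpaired: float = 0.05
    mod_rate_paired: float = 0.005
    untreated_rate: float = 0.002
    shape_depth: int = 10_000
    # crosslinking MS
    xlms_rows: int = 500
    xlms_fail_fraction: float = 0.3
    xlms_decoy_fraction: float = 0.1
    xlms_subunits: tuple[str, ...] = ("NELF-A", "NELF-B", "NELF-C", "NELF-E")
    xlms_max_residue: int = 400

    def __post_init__(self) -> None:
        for name in ("tss_jitter_mass", "crosslink_5prime_fraction",
                     "mod_rate_unpaired", "mod_rate_paired", "untreated_rate",
                     "xlms_fail_fraction", "xlms_decoy_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.kd_true <= 0:
            raise ValueError("kd_true must be positive")
        if not 0 < self.amplitude_true <= 1:
            raise ValueError("amplitude_true must be in (0, 1]")
        if self.pausing_index_true <= 0:
            raise ValueError("pausing_index_true must be positive")
        if self.gene_length < 1_200:
            raise ValueError("genes must be >= 1200 bp so both PI windows fit")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _fold(config: SimConfig, unit_id: str, condition: str) -> float:
    if condition == config.baseline_condition:
        return 1.0
    if isinstance(config.induction_fold, Mapping):
        return float(config.induction_fold.get(unit_id, {}).get(condition, 1.0))
    return float(config.induction_fold)


def gene_units(config: SimConfig) -> list[TranscriptUnit]:
    """Evenly spaced gene units on alternating strands."""
    spacing = config.chrom_length // (config.n_genes + config.n_enhancers + 1)
    if spacing < config.gene_length + 400:
        raise ValueError("chromosome too short for the requested gene layout")
    units = []
    for i in range(config.n_genes):
        start = spacing * (i + 1)
        strand = "+" if i % 2 == 0 else "-"
        iv = GenomicInterval(config.chrom, start, start + config.gene_length, strand)
        units.append(TranscriptUnit(f"gene{i:03d}", iv, "gene"))
    return units


def enhancer_units(config: SimConfig) -> list[TranscriptUnit]:
    """eRNA units placed downstream of the gene block, clear of gene +/-2 kb."""
    spacing = config.chrom_length // (config.n_genes + config.n_enhancers + 1)
    units = []
    for i in range(config.n_enhancers):
        start = spacing * (config.n_genes + 1 + i)
        strand = "+" if i % 2 == 0 else "-"
        iv = GenomicInterval(config.chrom, start, start + config.enhancer_length,
                             strand)
        units.append(TranscriptUnit(f"eRNA{i:03d}", iv, "eRNA"))
    return units


def simulate_nascent_coverage(
    config: SimConfig,
    units: list[TranscriptUnit] | None = None,
) -> tuple[dict[str, CoverageTrack], list[TranscriptUnit], dict]:
    """Nascent coverage with a promoter-proximal peak of known pausing index.

    Reads over each gene are split between the promoter-proximal window
    (-100..+200 around the TSS) and the remainder of the gene so that the
    expected promoter/body density ratio equals ``pausing_index_true``; a
    ratio of 1 reduces to a flat profile.  Per-condition tracks scale each
    gene's read count by its induction fold.
    """
    rng = config.rng(_NASCENT)
    if units is None:
        units = gene_units(config)
    up, down = config.promoter_window
    prom_len = down - up
    rest_len = config.gene_length - down
    if rest_len <= 0:
        raise ValueError("gene shorter than the promoter window")
    pi = config.pausing_index_true
    p_prom = (prom_len * pi) / (prom_len * pi + rest_len)

    tracks = {cond: CoverageTrack({config.chrom: config.chrom_length})
              for cond in config.conditions}
    for unit in units:
        tss = unit.tss
        sign = 1 if unit.interval.strand != "-" else -1
        # transcript-frame bounds of the read span: [up, gene_length)
        if unit.interval.strand != "-":
            span_lo, span_hi = tss + up, tss + config.gene_length
        else:
            span_lo, span_hi = tss - config.gene_length + 1, tss - up + 1
        if span_lo < 0 or span_hi > config.chrom_length:
            raise ValueError(
                f"pausing windows of {unit.id} overflow the chromosome"
            )
        for cond in config.conditions:
            n = int(round(config.reads_per_gene * _fold(config, unit.id, cond)))
            if n == 0:
                unit.expression[cond] = 0.0
                continue
            n_prom = rng.binomial(n, p_prom)
            d_prom = rng.integers(up, down, size=n_prom)
            d_rest = rng.integers(down, config.gene_length, size=n - n_prom)
            offsets = np.concatenate([d_prom, d_rest])
            positions = tss + sign * offsets
            strand = unit.interval.strand if unit.interval.strand != "." else "+"
            np.add.at(tracks[cond].array(config.chrom, strand), positions, 1.0)
            unit.expression[cond] = n / unit.interval.length
    truth = {
        "pausing_index_true": pi,
        "reads_per_gene": config.reads_per_gene,
        "promoter_mass": p_prom,
        "units": [u.id for u in units],
    }
    return tracks, units, truth


def simulate_5prime_reads(
    config: SimConfig,
    units: list[TranscriptUnit] | None = None,
) -> tuple[list[SiteRecord], dict]:
    """5'-end read pileups at known TSSs over uniform background.

    Per-TSS read counts are Poisson around ``tss_read_mean``; a fraction
    ``tss_jitter_mass`` of reads lands uniformly within +/-2 nt of (but not
    on) the TSS.  Background reads arrive uniformly at ``background_rate``
    reads/bp on each strand.
    """
    rng = config.rng(_FIVEPRIME)
    if config.tss_positions is not None:
        tss_list = [(int(p), "+") for p in config.tss_positions]
    else:
        if units is None:
            units = gene_units(config) + enhancer_units(config)
        tss_list = [(u.tss, u.interval.strand if u.interval.strand != "." else "+")
                    for u in units]
    for pos, _ in tss_list:
        if not 0 <= pos < config.chrom_length:
            raise ValueError(f"TSS position {pos} out of chromosome bounds")

    counts: dict[tuple[str, int, str], int] = {}

    def bump(pos: int, strand: str, n: int = 1) -> None:
        if 0 <= pos < config.chrom_length and n > 0:
            key = (config.chrom, pos, strand)
            counts[key] = counts.get(key, 0) + n

    for pos, strand in tss_list:
        n = rng.poisson(config.tss_read_mean)
        jittered = rng.random(n) < config.tss_jitter_mass
        offsets = np.where(jittered,
                           rng.choice([-2, -1, 1, 2], size=n), 0)
        for off in offsets:
            bump(pos + int(off), strand)
    n_bg = rng.poisson(config.background_rate * config.chrom_length)
    bg_pos = rng.integers(0, config.chrom_length, size=n_bg)
    bg_strand = rng.choice(["+", "-"], size=n_bg)
    for pos, strand in zip(bg_pos, bg_strand):
        bump(int(pos), str(strand))

    sites = [SiteRecord(c, p, s, n)
             for (c, p, s), n in sorted(counts.items())]
    truth = {
        "tss": [{"position": pos, "strand": strand} for pos, strand in tss_list],
        "tss_read_mean": config.tss_read_mean,
        "background_rate": config.background_rate,
    }
    return sites, truth


def simulate_crosslink_sites(
    config: SimConfig,
    units: list[TranscriptUnit],
) -> tuple[list[SiteRecord], dict]:
    """Crosslink sites drawn from a 5'-biased mixture over transcript bodies.

    With probability ``crosslink_5prime_fraction`` a site's distance from the
    unit 5'-end is uniform on the first window (default 200 nt); otherwise it
    is uniform on the remaining transcript length.  Units shorter than the
    first window collapse to a uniform draw, with a warning.
    """
    rng = config.rng(_CROSSLINK)
    w = config.first_window
    counts: dict[tuple[str, int, str], int] = {}
    per_unit: dict[str, int] = {}
    for unit in units:
        L = unit.interval.length
        n = config.crosslinks_per_unit
        per_unit[unit.id] = n
        if L <= w:
            warnings.warn(
                f"unit {unit.id} ({L} nt) shorter than the first window; "
                "mixture collapses to uniform"
            )
            dist = rng.integers(0, L, size=n)
        else:
            in_first = rng.random(n) < config.crosslink_5prime_fraction
            dist = np.where(in_first,
                            rng.integers(0, w, size=n),
                            rng.integers(w, L, size=n))
        if unit.interval.strand != "-":
            positions = unit.interval.start + dist
            strand = "+"
        else:
            positions = unit.interval.end - 1 - dist
            strand = "-"
        for pos in positions:
            key = (unit.interval.chrom, int(pos), strand)
            counts[key] = counts.get(key, 0) + 1
    sites = [SiteRecord(c, p, s, n) for (c, p, s), n in sorted(counts.items())]
    truth = {
        "crosslink_5prime_fraction": config.crosslink_5prime_fraction,
        "first_window": w,
        "crosslinks_per_unit": per_unit,
    }
    return sites, truth


def simulate_binding_curve(
    config: SimConfig,
    concentrations: Sequence[float] | None = None,
) -> tuple[emsa.BindingCurve, dict]:
    """Release fractions from the quadratic model plus truncated Gaussian noise."""
    rng = config.rng(_BINDING)
    L = np.asarray(concentrations if concentrations is not None
                   else config.concentrations, dtype=float)
    clean = emsa.quadratic_model(L, config.kd_true, config.amplitude_true,
                                 config.receptor_total)
    noisy = clean + rng.normal(0.0, config.noise_sd, size=L.size) \
        if config.noise_sd > 0 else clean
    noisy = np.clip(noisy, 0.0, 1.0)
    curve = emsa.BindingCurve(L, noisy, config.receptor_total)
    truth = {
        "kd_true": config.kd_true,
        "amplitude_true": config.amplitude_true,
        "noise_sd": config.noise_sd,
        "receptor_total": config.receptor_total,
    }
    return curve, truth


_UNPAIRED_CHARS = frozenset(".uU")
_PAIRED_CHARS = frozenset("()<>{}pP")


def simulate_mutation_counts(
    structure: str,
    config: SimConfig,
) -> tuple[pd.DataFrame, dict]:
    """Per-nucleotide mutation counts for a SHAPE-MaP experiment.

    ``structure`` marks each position paired ('(' ')' or 'p') or unpaired
    ('.' or 'u').  Modified-channel counts are Binomial(depth, rate) with the
    rate chosen by pairing state; the untreated channel uses a single rate.
    """
    rng = config.rng(_SHAPE)
    states = []
    for i, ch in enumerate(structure):
        if ch in _UNPAIRED_CHARS:
            states.append("unpaired")
        elif ch in _PAIRED_CHARS:
            states.append("paired")
        else:
            raise ValueError(f"position {i}: unknown structure symbol {ch!r}")
    n = len(states)
    depth = np.full(n, config.shape_depth, dtype=int)
    rates = np.where(np.array(states) == "unpaired",
                     config.mod_rate_unpaired, config.mod_rate_paired)
    frame = pd.DataFrame({
        "position": np.arange(1, n + 1),
        "state": states,
        "mod_count": rng.binomial(depth, rates),
        "mod_depth": depth,
        "unt_count": rng.binomial(depth, config.untreated_rate),
        "unt_depth": depth,
    })
    truth = {
        "mod_rate_unpaired": config.mod_rate_unpaired,
        "mod_rate_paired": config.mod_rate_paired,
        "untreated_rate": config.untreated_rate,
        "n_unpaired": int((frame["state"] == "unpaired").sum()),
        "n_paired": int((frame["state"] == "paired").sum()),
    }
    return frame, truth


def simulate_xlms_table(
    config: SimConfig,
    thresholds: tuple[float, float, float] = (7, 0.15, 20),
) -> tuple[pd.DataFrame, dict]:
    """Crosslink-search result rows with known pass/fail structure.

    A fraction ``xlms_fail_fraction`` of rows is planted below exactly one of
    the three quality thresholds (minions, TIC subscore, ID score); the rest
    passes all three.  Ground truth records the planned surviving per-residue
    spectral-count totals over non-decoy rows.
    """
    rng = config.rng(_XLMS)
    n = config.xlms_rows
    min_minions, min_tic, min_score = thresholds
    subunit = rng.choice(config.xlms_subunits, size=n)
    residue = rng.integers(1, config.xlms_max_residue + 1, size=n)
    nseen = 1 + rng.poisson(2.0, size=n)
    decoy = rng.random(n) < config.xlms_decoy_fraction
    fails = rng.random(n) < config.xlms_fail_fraction
    which = rng.integers(0, 3, size=n)  # which threshold a failing row misses

    minions = min_minions + rng.poisson(5.0, size=n)
    tic = rng.uniform(min_tic, 1.0, size=n)
    score = min_score + rng.exponential(10.0, size=n)
    fail_minions = fails & (which == 0)
    fail_tic = fails & (which == 1)
    fail_score = fails & (which == 2)
    minions[fail_minions] = rng.integers(0, min_minions, size=fail_minions.sum())
    tic[fail_tic] = rng.uniform(0.0, min_tic * 0.999, size=fail_tic.sum())
    score[fail_score] = rng.uniform(0.0, min_score * 0.999, size=fail_score.sum())

    frame = pd.DataFrame({
        "subunit": subunit,
        "residue": residue,
        "nseen": nseen,
        "minions": minions,
        "tic": tic,
        "id_score": score,
        "decoy": decoy,
    })
    passing = frame[~fails & ~decoy]
    totals = (passing.groupby(["subunit", "residue"])["nseen"].sum()
              .reset_index())
    truth = {
        "n_planned_fail": int(fails.sum()),
        "n_decoy": int(decoy.sum()),
        "per_residue_totals": {
            f"{row.subunit}:{row.residue}": int(row.nseen)
            for row in totals.itertuples()
        },
    }
    return frame, truth
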