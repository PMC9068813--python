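"""Crosslinking-MS post-search filtering and per-residue aggregation.

Search-result rows (one per crosslinked peptide-nucleotide identification)
are filtered by three quality thresholds — matched-ion count (minions),
TIC subscore, and search ID score, all with >= semantics — and redundant
spectral counts (nseen) are then summed per (subunit, residue).  Decoy rows
survive filtering flagged, feeding the decoy/target FDR estimate, but never
enter the aggregated totals.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

MIN_MINIONS = 7
MIN_TIC = 0.15
MIN_ID_SCORE = 20

REQUIRED_COLUMNS = ("subunit", "residue", "nseen", "minions", "tic", "id_score")

#: Default domain spans (1-based residue intervals, inclusive).
DEFAULT_DOMAIN_SPANS: dict[str, dict[str, tuple[int, int]]] = {
    "NELF-E": {"N-terminal": (1, 137), "tentacle": (138, 380)},
    "NELF-A": {"lobe": (1, 187), "tentacle": (188, 528)},
}

#: Met1 of NELF-E is strongly overrepresented and treated as an outlier.
DEFAULT_EXCLUSIONS: tuple[tuple[str, int], ...] = (("NELF-E", 1),)


def _validate(records: pd.DataFrame) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in records.columns:
            raise ValueError(f"missing column {col!r}")
    if (records["nseen"] < 1).any():
        raise ValueError("nseen must be >= 1")
    if ((records["tic"] < 0) | (records["tic"] > 1)).any():
        raise ValueError("tic must lie in [0, 1]")


def filter_xl(
    records: pd.DataFrame,
    min_minions: float = MIN_MINIONS,
    min_tic: float = MIN_TIC,
    min_score: float = MIN_ID_SCORE,
    ppm_window: float | None = None,
) -> pd.DataFrame:
    """Keep rows meeting all quality thresholds (>= at each boundary).

    Decoy rows are retained (flagged in the ``decoy`` column) for FDR
    reporting.  ``ppm_window`` optionally applies |mass_error_ppm| <= window
    when that column is present; there is no default because the observed
    mass deviation is dataset-specific.
    """
    _validate(records)
    keep = (
        (records["minions"] >= min_minions)
        & (records["tic"] >= min_tic)
        & (records["id_score"] >= min_score)
    )
    if ppm_window is not None:
        if "mass_error_ppm" not in records.columns:
            raise ValueError("ppm_window given but no mass_error_ppm column")
        keep &= records["mass_error_ppm"].abs() <= ppm_window
    return records[keep].copy()


def aggregate_per_residue(
    records: pd.DataFrame,
    exclusions: Iterable[tuple[str, int]] = DEFAULT_EXCLUSIONS,
) -> pd.DataFrame:
    """Total nseen per (subunit, residue) over non-decoy rows.

    Excluded (subunit, residue) pairs are omitted; the returned frame notes
    how many spectral counts each exclusion removed in ``attrs['excluded']``.
    """
    _validate(records)
    data = records
    if "decoy" in data.columns:
        data = data[~data["decoy"].astype(bool)]
    totals = (data.groupby(["subunit", "residue"], as_index=False)["nseen"]
              .sum().sort_values(["subunit", "residue"], ignore_index=True))
    removed: dict[str, int] = {}
    for subunit, residue in exclusions:
        hit = totals[(totals["subunit"] == subunit)
                     & (totals["residue"] == residue)]
        if not hit.empty:
            removed[f"{subunit}:{residue}"] = int(hit["nseen"].sum())
            totals = totals.drop(hit.index)
    totals = totals.reset_index(drop=True)
    totals.attrs["excluded"] = removed
    return totals


def fdr_estimate(records: pd.DataFrame) -> float:
    """Decoy/target ratio among surviving identifications."""
    if "decoy" not in records.columns:
        raise ValueError("records carry no decoy column")
    decoys = int(records["decoy"].astype(bool).sum())
    targets = len(records) - decoys
    if targets == 0:
        raise ValueError("no target identifications survive")
    return decoys / targets


def subunit_proportions(
    per_residue_totals: pd.DataFrame,
    domain_spans: Mapping[str, Mapping[str, tuple[int, int]]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Crosslink proportions per subunit, and per domain within a subunit.

    Domain spans are 1-based inclusive residue intervals.  Subunit
    proportions sum to 1 over all subunits; within a subunit, domain shares
    sum to that subunit's share (residues outside every span fall into an
    ``other`` row).
    """
    if domain_spans is None:
        domain_spans = DEFAULT_DOMAIN_SPANS
    grand_total = per_residue_totals["nseen"].sum()
    if grand_total == 0:
        raise ValueError("no crosslinks to apportion")
    by_subunit = (per_residue_totals.groupby("subunit", as_index=False)["nseen"]
                  .sum())
    by_subunit["proportion"] = by_subunit["nseen"] / grand_total

    domain_rows = []
    for subunit, spans in domain_spans.items():
        sub = per_residue_totals[per_residue_totals["subunit"] == subunit]
        if sub.empty:
            continue
        seen = pd.Series(False, index=sub.index)
        for domain, (lo, hi) in spans.items():
            mask = (sub["residue"] >= lo) & (sub["residue"] <= hi)
            domain_rows.append({
                "subunit": subunit,
                "domain": domain,
                "nseen": int(sub.loc[mask, "nseen"].sum()),
            })
            seen |= mask
        leftover = int(sub.loc[~seen, "nseen"].sum())
        if leftover:
            domain_rows.append({"subunit": subunit, "domain": "other",
                                "nseen": leftover})
    by_domain = pd.DataFrame(domain_rows,
                             columns=["subunit", "domain", "nseen"])
    if not by_domain.empty:
        by_domain["proportion"] = by_domain["nseen"] / grand_total
    return by_subunit, by_domain
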