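"""Crosslink-site extraction, assignment, window statistics."""

import numpy as np
import pandas as pd
import pytest

from nelfkit import simulate
from nelfkit.core import GenomicInterval, SiteRecord, TranscriptUnit
from nelfkit.eclip import (assign_to_units, compare_window_distributions,
                           extract_crosslink_sites, normalized_profile,
                           window_distribution)
from nelfkit.simulate import SimConfig


def _unit(uid="u1", start=1_000, length=600, strand="+"):
    return TranscriptUnit(uid, GenomicInterval("chr1", start, start + length,
                                               strand), "eRNA")


class TestExtractCrosslinkSites:
    def test_r2_first_nucleotide_becomes_site(self):
        (site,) = extract_crosslink_sites([("chr1", 1_000, "+")])
        assert (site.position, site.strand, site.count) == (1_000, "+", 1)

    def test_dedup_collapses_identical_reads(self):
        reads = [("chr1", 1_000, "+"), ("chr1", 1_000, "+")]
        (site,) = extract_crosslink_sites(reads, dedup=True)
        assert site.count == 1
        (site,) = extract_crosslink_sites(reads, dedup=False)
        assert site.count == 2

    def test_totals_match_brute_force_tally(self):
        rng = np.random.default_rng(2)
        reads = [("chr1", int(p), str(s))
                 for p, s in zip(rng.integers(0, 500, 10_000),
                                 rng.choice(["+", "-"], 10_000))]
        sites = extract_crosslink_sites(reads)
        tally = {}
        for key in reads:
            tally[key] = tally.get(key, 0) + 1
        assert {(s.chrom, s.position, s.strand): s.count
                for s in sites} == tally


class TestAssignToUnits:
    def test_site_at_unit_5prime_has_distance_one(self):
        frame, _ = assign_to_units([SiteRecord("chr1", 1_000, "+", 1)],
                                   [_unit()])
        assert frame["distance"].iloc[0] == 1

    def test_149nt_downstream_is_distance_150(self):
        frame, _ = assign_to_units([SiteRecord("chr1", 1_149, "+", 1)],
                                   [_unit()])
        assert frame["distance"].iloc[0] == 150
        dist = window_distribution(frame, edges=(200, 400, 600))
        assert dist.counts[0] == 1

    def test_minus_strand_distance_runs_from_3prime_end(self):
        unit = _unit(strand="-")
        frame, _ = assign_to_units([SiteRecord("chr1", 1_599, "-", 1)], [unit])
        assert frame["distance"].iloc[0] == 1  # end-1 is the 5' base

    def test_unassigned_sites_counted(self):
        _, dropped = assign_to_units([SiteRecord("chr1", 10, "+", 1)],
                                     [_unit()])
        assert dropped == 1

    def test_wrong_strand_not_assigned(self):
        _, dropped = assign_to_units([SiteRecord("chr1", 1_100, "-", 1)],
                                     [_unit()])
        assert dropped == 1

    def test_overlapping_units_flagged_multi(self):
        units = [_unit("a"), _unit("b", start=1_100)]
        frame, _ = assign_to_units([SiteRecord("chr1", 1_200, "+", 1)], units)
        assert set(frame["unit_id"]) == {"a", "b"}
        assert frame["multi"].all()

    def test_matches_brute_force_interval_scan(self):
        rng = np.random.default_rng(4)
        units = []
        for i in range(50):
            start = int(rng.integers(0, 50_000))
            units.append(TranscriptUnit(
                f"u{i}", GenomicInterval("chr1", start,
                                         start + int(rng.integers(100, 2_000)),
                                         str(rng.choice(["+", "-"]))), "eRNA"))
        sites = [SiteRecord("chr1", int(p), str(s), 1)
                 for p, s in zip(rng.integers(0, 55_000, 1_000),
                                 rng.choice(["+", "-"], 1_000))]
        frame, dropped = assign_to_units(sites, units)
        expected = []
        for site in sites:
            for unit in units:
                iv = unit.interval
                if (iv.strand == site.strand
                        and iv.start <= site.position < iv.end):
                    if iv.strand == "+":
                        d = site.position - iv.start + 1
                    else:
                        d = iv.end - site.position
                    expected.append((site.position, unit.id, d))
        got = list(zip(frame["position"], frame["unit_id"], frame["distance"]))
        assert sorted(got) == sorted(expected)
        assert dropped == sum(
            1 for site in sites
            if not any(u.interval.strand == site.strand
                       and u.interval.contains(site.position) for u in units))


class TestWindowDistribution:
    def test_example_proportions(self):
        dist = window_distribution([50, 150, 250], edges=(200, 400, 600))
        np.testing.assert_allclose(dist.proportions, [2 / 3, 1 / 3, 0.0])
        assert dist.labels == ["1-200", "201-400", "401-600"]

    def test_boundary_distance_falls_in_lower_window(self):
        dist = window_distribution([200, 201], edges=(200, 400))
        assert list(dist.counts) == [1, 1]

    def test_empty_input_flagged_undefined(self):
        dist = window_distribution([], edges=(200, 400))
        assert dist.total == 0
        with pytest.warns(UserWarning, match="undefined"):
            assert dist.proportions is None

    def test_beyond_last_edge_dropped_and_counted(self):
        dist = window_distribution([100, 700], edges=(200, 400, 600))
        assert dist.dropped == 1
        assert dist.total == 1

    def test_proportions_sum_to_one_over_retained(self):
        rng = np.random.default_rng(8)
        dist = window_distribution(rng.integers(1, 3_000, 500))
        assert dist.proportions.sum() == pytest.approx(1.0)


class TestPipelineMixtureRecovery:
    def test_simulated_mixture_recovered_within_binomial_interval(self):
        from scipy import stats
        cfg = SimConfig(seed=21, crosslink_5prime_fraction=0.7,
                        crosslinks_per_unit=1_000)
        units = [_unit(f"u{i}", start=10_000 * (i + 1)) for i in range(10)]
        sites, truth = simulate.simulate_crosslink_sites(cfg, units)
        frame, dropped = assign_to_units(sites, units)
        assert dropped == 0
        dist = window_distribution(frame, edges=(200, 400, 600))
        n = dist.total
        p_hat = dist.proportions[0]
        p = truth["crosslink_5prime_fraction"]
        halfwidth = stats.norm.ppf(0.995) * np.sqrt(p * (1 - p) / n)
        assert abs(p_hat - p) < halfwidth


class TestNormalizedProfile:
    def _assignments(self, spec):
        rows = []
        for uid, positions in spec.items():
            for distance in positions:
                rows.append({"chrom": "chr1", "position": 0, "strand": "+",
                             "count": 1, "unit_id": uid, "distance": distance,
                             "multi": False})
        return pd.DataFrame(rows)

    def test_equal_expression_is_scaled_raw_mean(self):
        asg = self._assignments({"a": [1, 5], "b": [5, 9]})
        prof = normalized_profile(asg, {"a": 2.0, "b": 2.0}, span=10,
                                  binsize=1)
        raw = normalized_profile(asg, {"a": 1.0, "b": 1.0}, span=10, binsize=1)
        np.testing.assert_allclose(prof["normalized_coverage"],
                                   raw["normalized_coverage"] / 2.0)

    def test_doubling_expression_halves_contribution(self):
        asg = self._assignments({"a": [1]})
        lo = normalized_profile(asg, {"a": 1.0}, span=10, binsize=1)
        hi = normalized_profile(asg, {"a": 2.0}, span=10, binsize=1)
        assert hi["normalized_coverage"].iloc[0] == pytest.approx(
            lo["normalized_coverage"].iloc[0] / 2.0)

    def test_zero_expression_units_excluded(self):
        asg = self._assignments({"a": [1], "b": [2]})
        prof = normalized_profile(asg, {"a": 1.0, "b": 0.0}, span=10,
                                  binsize=1)
        assert prof.attrs["n_excluded"] == 1
        assert prof.attrs["n_units"] == 1

    def test_matches_brute_force_on_synthetic_units(self):
        rng = np.random.default_rng(13)
        spec = {f"u{i}": list(rng.integers(1, 601, rng.integers(1, 30)))
                for i in range(20)}
        expression = {f"u{i}": float(rng.uniform(0.5, 4.0)) for i in range(20)}
        asg = self._assignments(spec)
        prof = normalized_profile(asg, expression, span=600, binsize=10)
        expected = np.zeros(600)
        for uid, positions in spec.items():
            curve = np.zeros(600)
            for d in positions:
                curve[d - 1] += 1
            expected += curve / expression[uid]
        expected /= len(spec)
        expected = expected.reshape(-1, 10).mean(axis=1)
        np.testing.assert_allclose(prof["normalized_coverage"], expected)


class TestCompareWindowDistributions:
    def _dist(self, counts, edges=(200, 400)):
        from nelfkit.eclip import WindowDistribution
        return WindowDistribution(tuple(edges), np.asarray(counts))

    def test_identical_counts_give_zero_statistic(self):
        stat, p = compare_window_distributions(self._dist([10, 20]),
                                               self._dist([10, 20]))
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x2_pearson(self):
        stat, _ = compare_window_distributions(self._dist([10, 0]),
                                               self._dist([0, 10]))
        assert stat == pytest.approx(20.0)

    def test_symmetric_in_arguments(self):
        a, b = self._dist([30, 12]), self._dist([5, 25])
        assert compare_window_distributions(a, b) == \
            compare_window_distributions(b, a)

    def test_matches_brute_force_pearson_sum(self):
        rng = np.random.default_rng(14)
        edges = (200, 400, 600)
        for _ in range(50):
            a = rng.integers(1, 100, 3)
            b = rng.integers(1, 100, 3)
            stat, _ = compare_window_distributions(self._dist(a, edges),
                                                   self._dist(b, edges))
            table = np.vstack([a, b]).astype(float)
            expected_cells = (table.sum(axis=1, keepdims=True)
                              * table.sum(axis=0, keepdims=True)
                              / table.sum())
            oracle = ((table - expected_cells) ** 2 / expected_cells).sum()
            assert stat == pytest.approx(oracle, abs=1e-9)

    def test_low_expected_cells_warn_but_return(self):
        with pytest.warns(UserWarning, match="expected cell"):
            stat, _ = compare_window_distributions(self._dist([1, 400]),
                                                   self._dist([1, 1]))
        assert np.isfinite(stat)
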