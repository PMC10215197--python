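"""Replicate aggregation, filtering, and sensitivity classification."""

import math
import random

import numpy as np
import pytest

from mitoredox.isotop import (
    aggregate_replicates,
    classify_dose_series,
    classify_sensitivity,
    filter_changed,
    implied_oxidation,
    median_summary,
)
from mitoredox.model import RatioObservation, SiteSummary
from mitoredox.synthetic_data import sample_truths, simulate_isotop

from conftest import make_site, make_truth


def obs(site, ratio, replicate, condition="c", capped=False):
    return RatioObservation(
        site=site,
        condition=condition,
        replicate=replicate,
        light_area=ratio * 100.0,
        heavy_area=100.0,
        ratio_LH=ratio,
        capped=capped,
    )


class TestAggregateReplicates:
    def test_mean_and_cv_by_hand(self):
        site = make_site()
        (summary,) = aggregate_replicates([obs(site, 2.0, 1), obs(site, 4.0, 2)], (2, 2))
        assert summary.mean_ratio == pytest.approx(3.0)
        # sd(sqrt(2)) / mean(3)
        assert summary.cv == pytest.approx(math.sqrt(2.0) / 3.0, abs=1e-4)
        assert summary.cv == pytest.approx(0.4714, abs=1e-4)
        assert summary.n_present == 2
        assert summary.retained

    def test_presence_rule_two_of_three(self):
        site = make_site()
        (summary,) = aggregate_replicates([obs(site, 1.5, 1)], (2, 3))
        assert "PRESENCE_FAIL" in summary.flags
        assert summary.mean_ratio is None
        assert not summary.retained

    def test_zero_dispersion(self):
        site = make_site()
        (summary,) = aggregate_replicates(
            [obs(site, 5.0, r) for r in (1, 2, 3)], (2, 3)
        )
        assert summary.mean_ratio == pytest.approx(5.0)
        assert summary.cv == 0.0

    def test_duplicate_rows_rejected_with_name(self):
        site = make_site()
        with pytest.raises(ValueError, match=f"{site.site_id} / c / replicate 1"):
            aggregate_replicates([obs(site, 2.0, 1), obs(site, 3.0, 1)], (2, 2))

    def test_capped_flag_carried_through(self):
        site = make_site()
        (summary,) = aggregate_replicates(
            [obs(site, 20.0, 1, capped=True), obs(site, 18.0, 2)], (2, 2)
        )
        assert "CAPPED" in summary.flags
        assert summary.retained  # capped ratios aggregate like ordinary ones

    def test_invalid_presence_rule(self):
        with pytest.raises(ValueError, match="presence rule"):
            aggregate_replicates([], (3, 2))

    def test_output_order_deterministic(self):
        sites = [make_site(residue=r) for r in (30, 10, 20)]
        rows = [obs(s, 2.0, r) for s in sites for r in (1, 2)]
        random.Random(0).shuffle(rows)
        summaries = aggregate_replicates(rows, (2, 2))
        assert [s.site.residue for s in summaries] == [10, 20, 30]


class TestFilterChanged:
    def _summary(self, mean, cv, site=None):
        return SiteSummary(
            site=site or make_site(), condition="c", n_present=2, mean_ratio=mean, cv=cv
        )

    def test_changed_but_reproducible_is_retained(self):
        (out,) = filter_changed([self._summary(3.0, 0.47)])
        assert out.retained

    def test_changed_and_noisy_is_flagged(self):
        # ratios {1.0, 3.5}: mean 2.25, sd 1.7678, cv 0.786
        (out,) = filter_changed([self._summary(2.25, 0.7857)])
        assert "CV_FAIL" in out.flags
        assert not out.retained

    def test_unchanged_kept_regardless_of_cv(self):
        (out,) = filter_changed([self._summary(1.1, 0.9)])
        assert out.retained

    def test_cv_only_mode(self):
        (out,) = filter_changed([self._summary(1.1, 0.9)], mode="cv_only")
        assert "CV_FAIL" in out.flags

    def test_thresholds_validated(self):
        with pytest.raises(ValueError, match="positive"):
            filter_changed([], fold_threshold=0.0)

    def test_flag_counts_match_brute_force_recount(self, toy_sites, rng):
        truths = sample_truths(toy_sites, rng)
        observations = simulate_isotop(
            truths, {"c": 10.0}, 2, noise_cv=0.5, dropout_rate=0.2, seed=21
        )
        summaries = filter_changed(aggregate_replicates(observations, (2, 2)))
        # brute-force recount straight from the raw rows
        by_site = {}
        for o in observations:
            by_site.setdefault(o.site, []).append(o.ratio_LH)
        expect_presence = {s for s, v in by_site.items() if len(v) < 2}
        expect_cv = set()
        for site, vals in by_site.items():
            if len(vals) < 2:
                continue
            mean = sum(vals) / len(vals)
            sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
            if mean > 2.0 and sd / mean > 0.5:
                expect_cv.add(site)
        assert {s.site for s in summaries if "PRESENCE_FAIL" in s.flags} == expect_presence
        assert {s.site for s in summaries if "CV_FAIL" in s.flags} == expect_cv


class TestClassifySensitivity:
    def test_flat_profile_is_resistant(self):
        cls, _ = classify_sensitivity({1: 1.0, 2.5: 1.1, 5: 1.0, 10: 1.2})
        assert cls == "resistant"

    def test_steep_profile_is_high(self):
        cls, slope = classify_sensitivity({1: 2.1, 2.5: 3.5, 5: 8.0, 10: 13.0})
        assert cls == "high"
        assert slope > 0

    def test_single_dose_boundary_case(self):
        cls, slope = classify_sensitivity({10: 3.0})
        assert cls == "moderate"
        assert math.isnan(slope)

    def test_exact_boundaries(self):
        assert classify_sensitivity({10: 5.0})[0] == "high"
        assert classify_sensitivity({10: 2.0})[0] == "moderate"
        assert classify_sensitivity({10: 1.999})[0] == "resistant"

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="no doses"):
            classify_sensitivity({})


class TestImpliedOxidation:
    def test_unit_ratio_is_zero(self):
        assert implied_oxidation(1.0) == 0.0

    def test_ratio_two_is_fifty(self):
        assert implied_oxidation(2.0) == pytest.approx(50.0)

    def test_printed_example_ratio(self):
        assert implied_oxidation(13.3) == pytest.approx(92.48, abs=0.01)

    def test_subunit_ratio_clamps_to_zero(self):
        assert implied_oxidation(0.5) == 0.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            implied_oxidation(0.0)

    def test_monotone(self):
        ratios = np.linspace(1.0, 20.0, 100)
        pcts = [implied_oxidation(r) for r in ratios]
        assert all(b > a for a, b in zip(pcts, pcts[1:]))


class TestMedianSummary:
    def _summaries(self, ratios, condition="c"):
        return [
            SiteSummary(
                site=make_site(residue=i + 1),
                condition=condition,
                n_present=2,
                mean_ratio=r,
                cv=0.0,
            )
            for i, r in enumerate(ratios)
        ]

    def test_odd_count(self):
        df = median_summary(self._summaries([1.0, 2.0, 3.0]))
        assert df.loc[0, "median_ratio"] == pytest.approx(2.0)

    def test_even_count_midpoint(self):
        df = median_summary(self._summaries([1.0, 2.0, 3.0, 10.0]))
        assert df.loc[0, "median_ratio"] == pytest.approx(2.5)

    def test_flagged_rows_excluded(self):
        rows = self._summaries([1.0, 2.0, 3.0])
        rows.append(
            SiteSummary(
                site=make_site(residue=99),
                condition="c",
                n_present=2,
                mean_ratio=1000.0,
                cv=2.0,
                flags=frozenset({"CV_FAIL"}),
            )
        )
        df = median_summary(rows)
        assert df.loc[0, "median_ratio"] == pytest.approx(2.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no retained"):
            median_summary([])

    def test_zero_noise_uniform_truth_gives_closed_form_median(self):
        truths = [
            make_truth(site=make_site(residue=i), fmax_rev=0.5, K=1.0, basal_ox=0.0)
            for i in range(1, 21)
        ]
        observations = simulate_isotop(truths, {"c": 1e12}, 2, noise_cv=0.0, seed=0)
        df = median_summary(aggregate_replicates(observations, (2, 2)))
        assert df.loc[0, "median_ratio"] == pytest.approx(2.0, rel=1e-9)


class TestDoseSeries:
    def test_zero_noise_medians_monotone_in_dose(self, toy_sites, rng):
        truths = sample_truths(toy_sites, rng, detect_isotop=1.0)
        doses = {"d1": 1.0, "d2": 2.5, "d3": 5.0, "d4": 10.0}
        observations = simulate_isotop(truths, doses, 2, noise_cv=0.0, seed=5)
        df = median_summary(aggregate_replicates(observations, (2, 2)))
        medians = df.set_index("condition")["median_ratio"]
        values = [medians[c] for c in ("d1", "d2", "d3", "d4")]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_pipeline_invariant_to_row_order(self, toy_sites, rng):
        truths = sample_truths(toy_sites, rng)
        doses = {"d1": 1.0, "d4": 10.0}
        observations = simulate_isotop(truths, doses, 2, noise_cv=0.3, seed=6)
        shuffled = observations.copy()
        random.Random(1).shuffle(shuffled)
        a = classify_dose_series(
            filter_changed(aggregate_replicates(observations, (2, 2))),
            {"d1": 1.0, "d4": 10.0},
        )
        b = classify_dose_series(
            filter_changed(aggregate_replicates(shuffled, (2, 2))),
            {"d1": 1.0, "d4": 10.0},
        )
        assert a.equals(b)

    def test_parameter_recovery_at_default_noise(self, rng):
        sites = [make_site(protein_id=f"P{i:05d}", residue=1) for i in range(300)]
        truths = sample_truths(
            sites,
            rng,
            class_probs={"resistant": 1 / 3, "moderate": 1 / 3, "high": 1 / 3},
            firr_range=(0.0, 0.0),
            detect_isotop=1.0,
        )
        doses = {"d1": 1.0, "d2": 2.5, "d3": 5.0, "d4": 10.0}
        observations = simulate_isotop(truths, doses, 2, noise_cv=0.2, seed=33)
        df = classify_dose_series(
            filter_changed(aggregate_replicates(observations, (2, 2))),
            {c: d for c, d in doses.items()},
        )
        truth_class = {t.site.site_id: t.sensitivity_class for t in truths}
        hits = [
            row.sensitivity_class == truth_class[row.site_id] for row in df.itertuples()
        ]
        assert len(hits) > 200
        assert np.mean(hits) >= 0.9
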