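"""Dose-response model and the two observation simulators."""

import math

import numpy as np
import pytest

from mitoredox.isotop import implied_oxidation
from mitoredox.model import CysteineSite, TruthRecord
from mitoredox.oxicat import percent_oxidation
from mitoredox.quantify import integrate_eic
from mitoredox.synthetic_data import (
    build_sites,
    classify_truth,
    oxidized_fraction,
    random_proteome,
    sample_annotations,
    sample_truths,
    simulate_chromatograms,
    simulate_isotop,
    simulate_oxicat,
)

from conftest import gaussian_area, make_site, make_truth


class TestOxidizedFraction:
    def test_zero_dose_returns_basal(self):
        assert oxidized_fraction(make_truth(basal_ox=0.0), 0.0) == 0.0
        assert oxidized_fraction(make_truth(basal_ox=0.05), 0.0) == 0.05

    def test_half_saturation_at_K(self):
        truth = make_truth(fmax_rev=0.8, K=2.5, hill=1.0, basal_ox=0.0)
        assert oxidized_fraction(truth, 2.5) == pytest.approx(0.4)

    def test_direct_evaluation(self):
        truth = make_truth(fmax_rev=0.9, K=2.5, hill=1.0, basal_ox=0.0)
        assert oxidized_fraction(truth, 10.0) == pytest.approx(0.72)

    def test_monotone_in_dose(self):
        truth = make_truth(fmax_rev=0.7, K=1.3, hill=2.0, basal_ox=0.02)
        doses = np.linspace(0, 20, 50)
        f = [oxidized_fraction(truth, d) for d in doses]
        assert all(b >= a for a, b in zip(f, f[1:]))

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            oxidized_fraction(make_truth(), -1.0)

    def test_nonpositive_K_rejected_at_truth_construction(self):
        with pytest.raises(ValueError, match="K must be positive"):
            make_truth(K=0.0)


class TestTruthSampling:
    def test_classes_consistent_with_parameters(self, toy_sites, rng):
        truths = sample_truths(toy_sites, rng)
        for t in truths:
            assert t.basal_ox + t.fmax_rev <= 1.0 + 1e-12
            assert t.sensitivity_class == classify_truth(
                t.fmax_rev, t.K, t.hill, t.basal_ox
            )

    def test_seeded_draws_reproducible(self, toy_sites):
        a = sample_truths(toy_sites, seed=5)
        b = sample_truths(toy_sites, seed=5)
        assert a == b


class TestSimulateIsotop:
    def test_no_oxidation_no_noise_gives_unit_ratio(self):
        truth = make_truth(fmax_rev=0.0, basal_ox=0.0)
        obs = simulate_isotop([truth], {"c": 10.0}, 1, noise_cv=0.0, seed=0)
        assert len(obs) == 1
        assert obs[0].ratio_LH == pytest.approx(1.0)

    def test_half_oxidation_gives_ratio_two(self):
        truth = make_truth(fmax_rev=0.5, K=1.0, basal_ox=0.0)
        obs = simulate_isotop([truth], {"c": 1e12}, 1, noise_cv=0.0, seed=0)
        assert obs[0].ratio_LH == pytest.approx(2.0, rel=1e-9)

    def test_monte_carlo_mean_matches_closed_form(self):
        # E[L:H] = 1/(1-f); f = 0.9 at saturating dose
        truth = make_truth(fmax_rev=0.9, K=1.0, basal_ox=0.0, sensitivity_class="high")
        obs = simulate_isotop([truth] * 1000, {"c": 1e9}, 1, noise_cv=0.2, seed=42)
        mean = np.mean([o.ratio_LH for o in obs])
        assert mean == pytest.approx(10.0, rel=0.05)

    def test_fully_oxidized_sites_are_censored(self):
        truth = make_truth(fmax_rev=0.99, K=0.01, basal_ox=0.01)
        obs = simulate_isotop([truth], {"c": 100.0}, 3, noise_cv=0.0, seed=0)
        assert obs == []

    def test_roundtrip_implied_oxidation_recovers_f_total(self):
        truth = make_truth(fmax_rev=0.6, K=2.0, basal_ox=0.05, firr_frac=0.3)
        for dose in (0.5, 2.0, 8.0):
            f = oxidized_fraction(truth, dose)
            obs = simulate_isotop([truth], {"c": dose}, 1, noise_cv=0.0, seed=0)
            assert implied_oxidation(obs[0].ratio_LH) == pytest.approx(
                100.0 * f, abs=1e-9
            )

    def test_identical_seeds_identical_output(self, toy_sites, rng):
        truths = sample_truths(toy_sites, rng)
        kwargs = dict(noise_cv=0.3, dropout_rate=0.1)
        a = simulate_isotop(truths, {"c": 5.0}, 2, seed=7, **kwargs)
        b = simulate_isotop(truths, {"c": 5.0}, 2, seed=7, **kwargs)
        c = simulate_isotop(truths, {"c": 5.0}, 2, seed=8, **kwargs)
        assert a == b
        assert [o.ratio_LH for o in a] != [o.ratio_LH for o in c]

    def test_replicate_count_validated(self):
        with pytest.raises(ValueError, match="n_replicates"):
            simulate_isotop([make_truth()], {"c": 1.0}, 0)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            simulate_isotop([make_truth()], {"c": -1.0}, 1)

    def test_detection_probability_thins_sites(self):
        truths = [
            make_truth(site=make_site(residue=i), detect_isotop=0.5)
            for i in range(1, 401)
        ]
        obs = simulate_isotop(truths, {"c": 1.0}, 1, noise_cv=0.0, seed=3)
        detected = {o.site for o in obs}
        assert 140 < len(detected) < 260  # ~ Binomial(400, 0.5)


class TestSimulateOxicat:
    def test_half_reversible_gives_fifty_percent(self):
        truth = make_truth(fmax_rev=0.5, K=1.0, basal_ox=0.0, firr_frac=0.0)
        obs = simulate_oxicat([truth], {"c": 1e12}, 1, noise_cv=0.0, seed=0)
        assert percent_oxidation(obs[0].ratio_LH, "LH") == pytest.approx(50.0, abs=1e-6)

    def test_irreversible_component_inflates_reversible_estimate(self):
        # f_total = 0.7 with 4/7 irreversible -> f_rev 0.3, f_irr 0.4 ->
        # heavy share 0.3/(0.3+0.3) = 50%
        truth = make_truth(fmax_rev=0.7, K=1.0, basal_ox=0.0, firr_frac=4.0 / 7.0)
        obs = simulate_oxicat([truth], {"c": 1e12}, 1, noise_cv=0.0, seed=0)
        assert percent_oxidation(obs[0].ratio_LH, "LH") == pytest.approx(50.0, abs=1e-6)

    def test_no_oxidation_gives_zero_percent(self):
        truth = make_truth(fmax_rev=0.0, basal_ox=0.0)
        obs = simulate_oxicat([truth], {"c": 10.0}, 1, noise_cv=0.0, seed=0, cap=1e12)
        assert percent_oxidation(obs[0].ratio_LH, "LH") == pytest.approx(0.0, abs=1e-9)

    def test_roundtrip_recovers_reversible_over_one_minus_irreversible(self):
        truth = make_truth(fmax_rev=0.6, K=2.0, basal_ox=0.05, firr_frac=0.25)
        for dose in (1.0, 5.0, 20.0):
            f_tot = oxidized_fraction(truth, dose)
            f_irr = truth.firr_frac * f_tot
            f_rev = f_tot - f_irr
            obs = simulate_oxicat([truth], {"c": dose}, 1, noise_cv=0.0, seed=0)
            assert percent_oxidation(obs[0].ratio_LH, "LH") == pytest.approx(
                100.0 * f_rev / (1.0 - f_irr), abs=1e-9
            )

    def test_detection_independent_of_isotop(self):
        truths = [
            make_truth(site=make_site(residue=i), detect_isotop=1.0, detect_oxicat=0.0)
            for i in range(1, 51)
        ]
        assert simulate_oxicat(truths, {"c": 1.0}, 1, seed=0) == []
        assert len(simulate_isotop(truths, {"c": 1.0}, 1, noise_cv=0.0, seed=0)) == 50


class TestSimulateChromatograms:
    def _one_obs(self):
        truth = make_truth(fmax_rev=0.5, K=1.0, basal_ox=0.0)
        return simulate_isotop([truth], {"c": 1e12}, 1, noise_cv=0.0, seed=0)

    def test_trapezoidal_integral_recovers_area(self):
        obs = self._one_obs()
        traces = simulate_chromatograms(obs, peak_sigma=2.0, sampling_interval=0.05, seed=1)
        for tr in traces:
            want = obs[0].light_area if tr.channel == "LIGHT" else obs[0].heavy_area
            got = integrate_eic(tr, subtract_baseline=False)
            assert got == pytest.approx(want, rel=0.005)

    def test_channels_share_apex(self):
        obs = self._one_obs()
        light, heavy = simulate_chromatograms(obs, seed=2)
        t_light = light.times[np.argmax(light.intensities)]
        t_heavy = heavy.times[np.argmax(heavy.intensities)]
        assert t_light == t_heavy

    def test_equal_areas_give_unit_ratio(self):
        site = make_site()
        from mitoredox.model import RatioObservation
        from mitoredox.quantify import compute_ratio

        obs = RatioObservation(site, "c", 1, 500.0, 500.0, 1.0, False)
        light, heavy = simulate_chromatograms([obs], seed=3)
        ratio, capped = compute_ratio(
            integrate_eic(light, subtract_baseline=False),
            integrate_eic(heavy, subtract_baseline=False),
        )
        assert not capped
        assert ratio == pytest.approx(1.0, rel=1e-6)

    def test_zero_abundance_channel_stays_at_baseline(self):
        site = make_site()
        from mitoredox.model import RatioObservation

        obs = RatioObservation(site, "c", 1, 300.0, 0.0, 20.0, True)
        _, heavy = simulate_chromatograms([obs], seed=4, baseline=0.5)
        assert np.all(heavy.intensities <= 0.5 + 1e-12)
        area = integrate_eic(heavy, subtract_baseline=False)
        span = heavy.times[-1] - heavy.times[0]
        assert area <= 0.5 * span + 1e-9

    def test_undersampled_peak_rejected(self):
        with pytest.raises(ValueError, match="undersample"):
            simulate_chromatograms(self._one_obs(), peak_sigma=1.0, sampling_interval=1.5)


class TestProteomeScaffolding:
    def test_sites_are_unique_and_on_cysteines(self, toy_proteome, toy_sites):
        assert len({(s.protein_id, s.residue) for s in toy_sites}) == len(toy_sites)
        for s in toy_sites:
            assert toy_proteome[s.protein_id][s.residue - 1] == "C"
            assert "C" in s.peptide

    def test_annotations_cover_all_proteins(self, toy_sites):
        ann = sample_annotations([s.protein_id for s in toy_sites], seed=1)
        assert {a.protein_id for a in ann} == {s.protein_id for s in toy_sites}
        for a in ann:
            if not a.is_mitochondrial:
                assert a.pathway_bin == "other"
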