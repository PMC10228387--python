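"""Generators: determinism, degenerate cases, and agreement of ground-truth
closed forms with independent numerical oracles."""

import math

import numpy as np
import pytest
from scipy import integrate, stats as sps

from nvuq import io, synth


class TestAmtScene:
    def test_zero_densities_empty_processes(self, small_geometry):
        stack, truth = synth.generate_amt_scene(
            small_geometry, {t: 0.0 for t in synth.VESSEL_TYPES},
            plaque_density=0.0, noise_sd=0.0, size_um=(40, 40, 20), seed=3)
        assert sum(s.n_punctae for s in truth.segments) == 0
        assert len(truth.plaque_centers) == 0
        assert not truth.punctae_mask.any()
        # tracer channel still contains the vessels themselves
        assert stack.channel("tracer").max() > 0

    def test_seed_determinism(self, small_geometry):
        a = synth.generate_amt_scene(small_geometry, size_um=(40, 40, 20), seed=11)
        b = synth.generate_amt_scene(small_geometry, size_um=(40, 40, 20), seed=11)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        assert [s.n_punctae for s in a[1].segments] == \
               [s.n_punctae for s in b[1].segments]

    def test_poisson_mean_of_punctae_counts(self):
        """One d=10, l=200 segment at rho=0.005 has Poisson(31.42) counts."""
        # a 16x210x12 um field fits exactly one capillary-override tube;
        # use the capillary slot with an overridden diameter via densities
        mean_expected = 0.005 * math.pi * 10 * 210
        counts = []
        for seed in range(500):
            _, truth = synth.generate_amt_scene(
                io.VoxelGeometry(0.5, 1.0),
                {"ascending venule (parenchymal)": 0.005}, plaque_density=0.0,
                size_um=(16, 210, 12), seed=seed, render=False)
            (seg,) = truth.segments
            assert seg.diameter_um == 9.0 and seg.length_um == 210.0
            counts.append(seg.n_punctae)
        mean_expected = 0.005 * math.pi * 9.0 * 210.0
        se = math.sqrt(mean_expected / 500)
        assert abs(np.mean(counts) - mean_expected) < 3 * se

    def test_counts_are_poisson_chi2(self):
        """Chi-square goodness of fit of realized counts to the Poisson law."""
        lam = 0.003 * math.pi * 9.0 * 210.0  # ~17.8
        counts = np.array([
            synth.generate_amt_scene(
                io.VoxelGeometry(0.5, 1.0),
                {"ascending venule (parenchymal)": 0.003}, plaque_density=0.0,
                size_um=(16, 210, 12), seed=s, render=False)[1].segments[0].n_punctae
            for s in range(300)])
        edges = [0, 13, 16, 18, 20, 23, np.inf]
        obs = np.histogram(counts, bins=edges)[0]
        cdf = sps.poisson(lam).cdf
        probs = np.diff([0] + [cdf(e - 1) if np.isfinite(e) else 1.0
                               for e in edges[1:]])
        chi2 = ((obs - 300 * probs) ** 2 / (300 * probs)).sum()
        assert chi2 < sps.chi2(len(obs) - 1).ppf(0.99)

    def test_negative_density_rejected(self, small_geometry):
        with pytest.raises(ValueError):
            synth.generate_amt_scene(small_geometry, {"capillary": -1.0})

    def test_too_small_field_rejected(self, small_geometry):
        with pytest.raises(ValueError):
            synth.generate_amt_scene(small_geometry, size_um=(2, 2, 1))


class TestLeakageTimelapse:
    def test_no_uptake_means_flat_parenchyma(self):
        stack, truth = synth.generate_leakage_timelapse(0.0, noise_sd=0.0, seed=0,
                                                        with_obstacles=False)
        assert truth.expected_ratio == 0.0
        par = stack.data[:, 1:, 0]  # below the pial plane
        assert np.all(par == 0)

    def test_closed_form_worked_example(self):
        """k=0.001/min, tau=20, T=45: AUC_b=17.892, AUC_p=0.5422, ratio 0.03030."""
        r = synth.leakage_expected_ratio(0.001, 20.0, 45.0)
        auc_b = 20 * (1 - math.exp(-2.25))
        assert auc_b == pytest.approx(17.892, abs=5e-4)
        assert 0.001 * 20 * (45 - auc_b) == pytest.approx(0.5422, abs=5e-4)
        assert r == pytest.approx(0.03030, abs=5e-5)

    def test_expected_ratio_matches_quadrature(self):
        """Closed form vs numerical integration of the kinetic model, 1e-6."""
        for k, tau, T in [(1e-3, 20, 45), (5e-4, 12, 45), (2e-3, 30, 60)]:
            cb = lambda t: math.exp(-t / tau)
            cp = lambda t: k * tau * (1 - math.exp(-t / tau))
            num = integrate.quad(cp, 0, T)[0] / integrate.quad(cb, 0, T)[0]
            assert synth.leakage_expected_ratio(k, tau, T) == \
                pytest.approx(num, rel=1e-6)

    def test_ratio_independent_of_c0(self):
        a = synth.generate_leakage_timelapse(1e-3, c0=1000.0)[1].expected_ratio
        b = synth.generate_leakage_timelapse(1e-3, c0=2000.0)[1].expected_ratio
        assert a == b

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_leakage_timelapse(1e-3, tau_blood=0.0)


class TestNvcTimelapse:
    def test_null_dilation_frames_identical(self):
        movie, _ = synth.generate_nvc_timelapse(
            synth.NvcTruth(12.0, 0.0), noise_sd=0.0, seed=0)
        first = movie.data[0]
        for t in range(movie.n_frames):
            np.testing.assert_array_equal(movie.data[t], first)

    def test_peak_diameter_arithmetic(self):
        truth = synth.NvcTruth(12.0, 0.2)
        times = np.array([truth.onset_s + truth.rise_s + 0.1])
        assert truth.diameter_at(times, 1.5)[0] == pytest.approx(14.4)

    def test_seed_determinism(self):
        a, _ = synth.generate_nvc_timelapse(synth.NvcTruth(10.0, 0.1),
                                            noise_sd=5.0, seed=9)
        b, _ = synth.generate_nvc_timelapse(synth.NvcTruth(10.0, 0.1),
                                            noise_sd=5.0, seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    def test_invalid_dilation_rejected(self):
        with pytest.raises(ValueError):
            synth.NvcTruth(10.0, -1.5)

    def test_short_plateau_rejected(self):
        with pytest.raises(ValueError):
            synth.NvcTruth(10.0, 0.1, plateau_len=3)


class TestFibrinogenSection:
    def test_step_model_without_enrichment(self):
        truth = synth.SectionTruth(enrich_amp=0.0, n_nuclei=0)
        img, truth = synth.generate_fibrinogen_section(truth, seed=0)
        inv_blue = 255.0 - img[..., 2].astype(float)
        wall_px = int(truth.wall_x_um / truth.pixel_size_um)
        assert inv_blue[:, : wall_px - 4].mean() == pytest.approx(
            truth.lumen_level, abs=2)
        assert inv_blue[:, wall_px + 4:].mean() == pytest.approx(
            truth.background_level, abs=2)

    def test_exponential_enrichment_value(self):
        """One decay length past the wall the excess is amp/e ~ 11.04."""
        truth = synth.SectionTruth(enrich_amp=30.0, enrich_decay=3.0, n_nuclei=0)
        img, truth = synth.generate_fibrinogen_section(truth, seed=0)
        inv_blue = 255.0 - img[..., 2].astype(float)
        col = int((truth.wall_x_um + 3.0) / truth.pixel_size_um)
        excess = inv_blue[:, col].mean() - truth.background_level
        assert excess == pytest.approx(30.0 / math.e, abs=1.0)

    def test_seed_determinism(self):
        t1 = synth.SectionTruth(enrich_amp=20.0, n_nuclei=10)
        t2 = synth.SectionTruth(enrich_amp=20.0, n_nuclei=10)
        a, _ = synth.generate_fibrinogen_section(t1, seed=4)
        b, _ = synth.generate_fibrinogen_section(t2, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_boundary_outside_image_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_fibrinogen_section(
                synth.SectionTruth(wall_x_um=1000.0), size=(64, 64))


class TestLfpTrain:
    def test_programmed_amplitudes(self):
        train = synth.generate_lfp_train(1.2, 1.0, noise_sd=0.0, seed=0)
        fs = train.sample_rate
        for i, ts in enumerate(train.stimulus_times):
            seg = train.trace[int(ts * fs): int((ts + 0.1) * fs)]
            assert -seg.min() == pytest.approx(1.2 if i == 0 else 1.0, rel=1e-3)

    def test_stimulus_span(self):
        train = synth.generate_lfp_train(n_pulses=30, rate_hz=2.0)
        assert train.stimulus_times[-1] - train.stimulus_times[0] == \
            pytest.approx(14.5)

    def test_single_pulse_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_lfp_train(n_pulses=1)


class TestCohort:
    def test_equal_params_symmetric(self):
        table = synth.generate_cohort(
            50, {"WT": {"m": (2.0, 0.3)}, "TG": {"m": (2.0, 0.3)}}, seed=0)
        df = table.df
        means = df.groupby("group")["true_value"].mean()
        pooled_sd = df["true_value"].std()
        assert abs(means["WT"] - means["TG"]) < pooled_sd / 2

    def test_zero_cv_degenerate(self):
        table = synth.generate_cohort(4, {"WT": {"m": (3.0, 0.0)}}, seed=1)
        assert (table.df["true_value"] == 3.0).all()

    def test_seed_determinism(self):
        p = {"WT": {"m": (1.0, 0.2)}}
        a = synth.generate_cohort(5, p, seed=2).df
        b = synth.generate_cohort(5, p, seed=2).df
        assert a.equals(b)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            synth.generate_cohort(1, {"WT": {"m": (1.0, 0.1)}})
        with pytest.raises(ValueError):
            synth.generate_cohort(3, {"WT": {"m": (1.0, -0.1)}})
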