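"""Generator tests: length quantization, release thinning, rendering physics."""

import math

import numpy as np
import pytest

from granule_sizer import (
    AcquisitionModel,
    LengthLaw,
    PlateDesign,
    ReleaseModel,
    apply_release,
    calibrate_release_model,
    expected_retained_long_area_fraction,
    render_exosite_field,
    render_field,
    sample_exosite_population,
    sample_granule_population,
)
from granule_sizer.synthgen import (
    SiteAreaLaw,
    SiteTruth,
    sample_exosite_field,
    simulate_truth_statistics,
)

from conftest import make_field, rod


class TestLengthLaw:
    def test_quantized_support(self):
        law = LengthLaw.truncated_geometric(p=0.35, max_quanta=12)
        assert np.allclose(law.lengths, np.arange(1, 13) * 0.5)
        draws = law.sample(np.random.default_rng(0), 5000) * 0.5
        assert set(np.round(draws * 2)) <= set(range(1, 13))

    def test_point_mass_has_no_long_granules(self):
        law = LengthLaw.point_mass(1)
        assert law.long_area_fraction() == 0.0
        assert law.mean_length() == 0.5

    def test_empirical_mean_matches_analytic(self):
        # oracle: closed-form mean of the truncated geometric via direct
        # pmf summation, computed independently of LengthLaw internals
        p, kmax = 0.35, 12
        k = np.arange(1, kmax + 1)
        w = (1 - p) ** (k - 1) * p
        analytic_mean = float((k * w).sum() / w.sum()) * 0.5
        analytic_var = float((k * k * w).sum() / w.sum()) * 0.25 - analytic_mean**2

        law = LengthLaw.truncated_geometric(p=p, max_quanta=kmax)
        n = 10_000
        draws = law.sample(np.random.default_rng(7), n) * 0.5
        se = math.sqrt(analytic_var / n)
        assert abs(draws.mean() - analytic_mean) < 3 * se

    def test_invalid_pmf_rejected(self):
        with pytest.raises(ValueError):
            LengthLaw(pmf=(0.5, 0.6))
        with pytest.raises(ValueError):
            LengthLaw.truncated_geometric(p=1.5)


class TestPopulationSampling:
    def test_lengths_are_quanta_and_placement_avoids_nuclei(self, tiny_design, acq_small):
        truth = sample_granule_population(tiny_design, acq=acq_small, seed=3)
        assert len(truth) == 4
        for f in truth:
            for g in f.granules:
                assert g.length == g.n_quanta * 0.5
                assert not any(nu.contains(*g.centroid) for nu in f.nuclei)

    def test_law_without_long_mass_rejected(self, tiny_design, acq_small):
        with pytest.raises(ValueError, match="long"):
            sample_granule_population(
                tiny_design, LengthLaw.point_mass(2), acq_small, seed=0)

    def test_seed_determinism(self, tiny_design, acq_small):
        t1 = sample_granule_population(tiny_design, acq=acq_small, seed=11)
        t2 = sample_granule_population(tiny_design, acq=acq_small, seed=11)
        g1 = [g.to_dict() for f in t1 for g in f.granules]
        g2 = [g.to_dict() for f in t2 for g in f.granules]
        assert g1 == g2


class TestReleaseModel:
    def test_probability_monotone_in_length(self):
        m = ReleaseModel(p_base=0.1, p_max=0.5, midpoint_length=2.0,
                        steepness=0.3)
        lengths = np.arange(1, 13) * 0.5
        p = m.probability(lengths)
        assert np.all(np.diff(p) >= 0)
        assert np.all((p >= 0) & (p <= 1))

    def test_infinite_steepness_is_length_independent(self):
        m = ReleaseModel(p_base=0.1, p_max=0.4, steepness=math.inf)
        p = m.probability(np.array([0.5, 2.0, 6.0]))
        assert np.allclose(p, 0.3)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ReleaseModel(p_base=0.8, p_max=0.5)
        with pytest.raises(ValueError):
            ReleaseModel(steepness=0.0)

    def test_length_independent_release_preserves_long_fraction(self, default_law):
        m = ReleaseModel.random_release(0.5)
        assert expected_retained_long_area_fraction(default_law, m) == \
            pytest.approx(default_law.long_area_fraction())

    def test_total_release_of_long_granules_zeroes_fraction(self, default_law):
        # p(L) -> 1 for L > 2 um, 0 otherwise (steep logistic)
        m = ReleaseModel(p_base=0.0, p_max=1.0, midpoint_length=2.25,
                        steepness=1e-4)
        assert expected_retained_long_area_fraction(default_law, m) == \
            pytest.approx(0.0, abs=1e-12)

    def test_monotone_selection_in_p_max(self, default_law):
        fracs = [expected_retained_long_area_fraction(
            default_law, ReleaseModel(p_base=0.1, p_max=pm, steepness=0.3))
            for pm in np.linspace(0.0, 0.9, 10)]
        assert all(a >= b - 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_calibration_hits_relative_fall(self, default_law):
        m = calibrate_release_model(default_law, 0.15, p_base=0.2)
        got = expected_retained_long_area_fraction(default_law, m)
        assert got == pytest.approx(default_law.long_area_fraction() * 0.85,
                                    rel=1e-6)


class TestApplyRelease:
    def test_rejects_already_released(self, tiny_design, acq_small):
        truth = sample_granule_population(tiny_design, acq=acq_small, seed=1)
        released = apply_release(truth, ReleaseModel.random_release(0.5), 2)
        with pytest.raises(ValueError):
            apply_release(released, ReleaseModel.random_release(0.5), 3)

    def test_logistic_release_matches_brute_force_expectation(
            self, tiny_design, acq_small, default_law):
        # oracle: exhaustive expectation over the sampled population,
        # Sum a_i (1-p(L_i)) [L_i > 2] / Sum a_i (1-p(L_i))
        truth = sample_granule_population(
            tiny_design, default_law, acq_small, seed=21)
        model = ReleaseModel(p_base=0.1, p_max=0.5, midpoint_length=2.0,
                             steepness=0.3)
        areas = np.array([g.area for f in truth for g in f.granules])
        lengths = np.array([g.length for f in truth for g in f.granules])
        keep_w = areas * (1.0 - model.probability(lengths))
        expect = keep_w[lengths > 2.0].sum() / keep_w.sum()

        fracs = []
        for s in range(200):
            rel = apply_release(truth, model, seed=s)
            kept_a, kept_l = [], []
            for f in rel:
                for g in f.retained_granules():
                    kept_a.append(g.area)
                    kept_l.append(g.length)
            kept_a, kept_l = np.array(kept_a), np.array(kept_l)
            fracs.append(kept_a[kept_l > 2.0].sum() / kept_a.sum())
        fracs = np.array(fracs)
        se = fracs.std(ddof=1) / math.sqrt(len(fracs))
        assert abs(fracs.mean() - expect) < 3 * se

    def test_thinning_invariance_unbiased(self, default_law):
        # length-independent release: retained long-area fraction is an
        # unbiased estimator of the population's, over >= 200 seeds
        design = PlateDesign(conditions=("c",), wells_per_condition=2,
                             fields_per_well=2)
        models = {"c": ReleaseModel.random_release(0.5)}
        fracs = []
        for s in range(200):
            df = simulate_truth_statistics(design, default_law, models, seed=s)
            fracs.append(df["long_area_fraction"].mean())
        fracs = np.array(fracs)
        se = fracs.std(ddof=1) / math.sqrt(len(fracs))
        assert abs(fracs.mean() - default_law.long_area_fraction()) < 3 * se


class TestRenderField:
    def test_empty_noiseless_field_is_constant_background(self):
        acq = AcquisitionModel(field_shape=(64, 64))
        img = render_field(make_field([]), acq, seed=0, noise=False)
        assert np.all(img.vwf == round(acq.background_level))

    def test_flux_conservation(self):
        # blur redistributes but conserves integrated signal
        acq = AcquisitionModel(field_shape=(128, 128), photon_scale=5000.0)
        g = rod(20.0, 20.0, 6, orientation=0.4)
        img = render_field(make_field([g]), acq, seed=1, noise=False)
        total = (img.vwf.astype(float) - acq.background_level).sum()
        expected = g.amplitude * acq.photon_scale * g.area / acq.pixel_size**2
        assert abs(total - expected) / expected < 1e-3

    def test_snr_matches_configuration(self):
        # (peak - background) / read_noise_sd measured over 50 seeds
        acq = AcquisitionModel(field_shape=(96, 96), read_noise_sd=4.0)
        g = rod(15.0, 15.0, 6, orientation=0.2)
        field = make_field([g])
        ideal = render_field(field, acq, seed=0, noise=False)
        peak_idx = np.unravel_index(np.argmax(ideal.vwf), ideal.vwf.shape)
        target_snr = (float(ideal.vwf[peak_idx]) - acq.background_level) \
            / acq.read_noise_sd
        peaks = [float(render_field(field, acq, seed=s).vwf[peak_idx])
                 for s in range(50)]
        measured = (np.mean(peaks) - acq.background_level) / acq.read_noise_sd
        assert measured == pytest.approx(target_snr, rel=0.10)

    def test_render_determinism_bit_exact(self, tiny_design, acq_small):
        truth = sample_granule_population(tiny_design, acq=acq_small, seed=5)
        a = render_field(truth.fields[0], acq_small, seed=9)
        b = render_field(truth.fields[0], acq_small, seed=9)
        assert np.array_equal(a.vwf, b.vwf)
        assert np.array_equal(a.nuclear, b.nuclear)

    def test_out_of_field_granule_raises(self, acq_small):
        g = rod(1.0, 1.0, 10)  # 5 um rod centered 1 um from the corner
        with pytest.raises(ValueError, match="beyond the field"):
            render_field(make_field([g]), acq_small, seed=0, noise=False)

    def test_released_granules_not_rendered(self, acq_small):
        kept = rod(10.0, 10.0, 4)
        gone = rod(30.0, 30.0, 4)
        gone.released = True
        img = render_field(make_field([kept, gone]), acq_small, seed=0,
                           noise=False)
        sig = img.vwf.astype(float) - acq_small.background_level
        h = np.array(img.vwf.shape) // 2
        assert sig[: h[0], : h[1]].sum() > 100
        assert sig[h[0]:, h[1]:].sum() == 0


class TestExositeGeneration:
    def test_fusion_fraction_zero_gives_disjoint_sites(self, acq_small):
        rng = np.random.default_rng(4)
        sites = sample_exosite_field(rng, 25, SiteAreaLaw(), acq_small,
                                     fusion_fraction=0.0)
        for i, a in enumerate(sites):
            for b in sites[i + 1:]:
                d = math.hypot(a.centroid[0] - b.centroid[0],
                               a.centroid[1] - b.centroid[1])
                assert d > a.radius + b.radius

    def test_adjacent_sites_form_single_component(self, acq_small):
        from scipy import ndimage
        px = acq_small.pixel_size
        s1 = SiteTruth((12.0, 12.0), 2.0)
        s2 = SiteTruth((12.0 + 2 * px, 12.0), 2.0)
        img = render_exosite_field(make_field([], sites=[s1, s2]), acq_small,
                                   seed=0, noise=False)
        mask = img.vwf.astype(float) > acq_small.background_level + 10
        _, n = ndimage.label(mask)
        assert n == 1

    def test_blurred_disk_halfmax_area_recovers_truth(self, acq_small):
        s = SiteTruth((12.0, 12.0), 3.0)
        img = render_exosite_field(make_field([], sites=[s]), acq_small,
                                   seed=0, noise=False)
        sig = img.vwf.astype(float) - acq_small.background_level
        area = (sig > sig.max() / 2).sum() * acq_small.pixel_size**2
        assert area == pytest.approx(3.0, rel=0.15)

    def test_per_condition_area_laws(self, acq_small):
        design = PlateDesign(conditions=("DMSO", "mini"),
                             wells_per_condition=1, fields_per_well=1,
                             cells_per_field=(3, 4))
        laws = {"mini": SiteAreaLaw(large_prevalence=0.0)}
        truth = sample_exosite_population(design, acq=acq_small, seed=0,
                                          sites_per_field=(8, 12),
                                          area_laws=laws)
        mini = [s.area for f in truth.by_condition("mini") for s in f.sites]
        assert max(mini) < 3.0 or np.mean(np.array(mini) > 2.0) < 0.1
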