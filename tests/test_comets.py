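import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

import cometkit as ck
from cometkit.comets import IntensityProfile
from conftest import make_comets


def _profile(values, step=0.1, background=0.0):
    values = np.asarray(values, dtype=float)
    return IntensityProfile(np.arange(len(values)) * step, values, background)


class TestEstimateBackground:
    def test_constant_image(self, clean_config, straight_trace):
        clean_config.bg_offset = 7.0
        img = ck.render_still(straight_trace, [], 1.0, clean_config)
        assert ck.estimate_background(img, straight_trace) == pytest.approx(7.0)

    def test_median_of_mixed_profile(self):
        prof = _profile([10] * 10 + [20] * 10)
        assert ck.estimate_background(prof) == 15.0

    def test_synthetic_offset_recovered(self, clean_config, straight_trace):
        comets = make_comets([10.0, 20.0])
        img = ck.render_still(straight_trace, comets, 1.0, clean_config)
        est = ck.estimate_background(img, straight_trace,
                                     comet_positions_um=[10.0, 20.0],
                                     exclusion_radius_um=3.0)
        assert est == pytest.approx(clean_config.bg_offset, rel=0.02)

    def test_too_few_samples_outside_exclusions(self):
        prof = _profile(np.ones(20))
        with pytest.raises(ValueError, match="25%"):
            ck.estimate_background(prof, comet_positions_um=[1.0],
                                   exclusion_radius_um=10.0)


class TestDetectComets:
    def test_three_well_separated_comets(self, clean_config, straight_trace):
        truth = [6.0, 15.0, 24.0]
        img = ck.render_still(straight_trace, make_comets(truth), 1.0,
                              clean_config)
        detected = ck.detect_comets(img, straight_trace)
        assert len(detected) == 3
        for d, t in zip(detected, truth):
            assert abs(d - t) <= 0.2

    def test_blank_image_no_detections(self, clean_config, straight_trace):
        img = ck.render_still(straight_trace, [], 1.0, clean_config)
        assert ck.detect_comets(img, straight_trace) == []

    def test_min_separation_merges_close_pair(self, clean_config, straight_trace):
        img = ck.render_still(straight_trace, make_comets([15.0, 15.1]), 1.0,
                              clean_config)
        params = ck.DetectionParams(min_sep_um=0.5)
        assert len(ck.detect_comets(img, straight_trace, params)) == 1


class TestMeasureComet:
    def test_rectangular_profile_forced_values(self):
        values = np.zeros(60)
        values[20:40] = 100.0
        m = ck.measure_comet(_profile(values), peak_position_um=3.0)
        assert m.length_um == pytest.approx(2.0)
        assert m.mean_intensity == pytest.approx(100.0)
        assert m.amount == pytest.approx(200.0)

    def test_no_comet_raises(self):
        with pytest.raises(ValueError, match="no comet"):
            ck.measure_comet(_profile(np.zeros(30)), peak_position_um=1.0)

    def test_length_matches_analytic_threshold_oracle(self, clean_config,
                                                      straight_trace):
        img = ck.render_still(straight_trace, make_comets([15.0]), 1.0,
                              clean_config)
        measured, _ = ck.measure_comets(img, straight_trace)
        assert len(measured) == 1

        # independent oracle: threshold crossing on the analytic axial
        # profile (Gaussian front + exponential tail) blurred by the PSF
        sigma = clean_config.psf_sigma_um
        tail = clean_config.comet_tail_length_um
        du = 0.001
        u = np.arange(-8 * tail, 6 * sigma, du)
        p = np.where(u >= 0, np.exp(-0.5 * (u / sigma) ** 2), np.exp(u / tail))
        blurred = gaussian_filter1d(p, sigma / du)
        oracle = (blurred > 0.2 * blurred.max()).sum() * du
        assert measured[0].length_um == pytest.approx(oracle, rel=0.15)

    def test_amount_identity_on_every_measurement(self, clean_config,
                                                  straight_trace):
        img = ck.render_still(straight_trace, make_comets([8.0, 16.0, 24.0]),
                              1.0, clean_config)
        measured, _ = ck.measure_comets(img, straight_trace)
        for m in measured:
            assert m.amount == m.mean_intensity * m.length_um

    def test_intensity_scale_equivariance(self, clean_config, straight_trace):
        img = ck.render_still(straight_trace, make_comets([15.0]), 1.0,
                              clean_config)
        scaled = ck.Image2D(img.pixels * 3.0, img.pixel_size_um)
        m1, _ = ck.measure_comets(img, straight_trace)
        m3, _ = ck.measure_comets(scaled, straight_trace)
        assert m3[0].length_um == pytest.approx(m1[0].length_um, abs=0.11)
        assert m3[0].mean_intensity == pytest.approx(3 * m1[0].mean_intensity,
                                                     rel=0.05)

    def test_resolution_robustness(self):
        # same physical scene at half the pixel size; the averaging band is
        # held constant in physical width (band_px counts pixels)
        lengths, amounts = [], []
        for px, band in ((0.1, 3), (0.05, 6)):
            cfg = ck.SimConfig(axon_length_um=30.0, pixel_size_um=px,
                               lattice_intensity=0.0, bg_offset=50.0,
                               poisson_noise=False, gaussian_noise_sd=0.0)
            trace, _ = ck.simulate_axon_trace(cfg)
            img = ck.render_still(trace, make_comets([15.0]), 1.0, cfg)
            params = ck.DetectionParams(band_px=band)
            measured, _ = ck.measure_comets(img, trace, params)
            lengths.append(measured[0].length_um)
            amounts.append(measured[0].amount)
        assert abs(lengths[0] - lengths[1]) < 0.1  # one coarse pixel
        assert amounts[1] == pytest.approx(amounts[0], rel=0.05)


class TestLatticeIntensity:
    def test_uniform_lattice_recovered(self, clean_config, straight_trace):
        img = ck.Image2D(np.full(clean_config.image_shape, 3.0), 0.1)
        val = ck.lattice_intensity(img, straight_trace, background=0.0)
        assert val == pytest.approx(3.0)

    def test_comet_exclusion_restores_comet_free_value(self):
        # same exclusion mask on both images isolates comet leakage; the
        # exclusion must cover the full exponential tail
        cfg = ck.SimConfig(axon_length_um=60.0, lattice_intensity=150.0,
                           bg_offset=50.0, poisson_noise=False,
                           gaussian_noise_sd=0.0)
        trace, _ = ck.simulate_axon_trace(cfg)
        kwargs = dict(comet_positions_um=[20.0, 40.0],
                      background=cfg.bg_offset, exclusion_radius_um=6.0)
        bare = ck.render_still(trace, [], 1.0, cfg)
        with_comets = ck.render_still(trace, make_comets([20.0, 40.0]), 1.0, cfg)
        ref = ck.lattice_intensity(bare, trace, **kwargs)
        excl = ck.lattice_intensity(with_comets, trace, **kwargs)
        assert excl == pytest.approx(ref, rel=0.03)

    def test_no_exclusion_is_strictly_larger(self, clean_config, straight_trace):
        cfg = clean_config
        cfg.lattice_intensity = 150.0
        img = ck.render_still(straight_trace, make_comets([10.0, 20.0]), 1.0, cfg)
        incl = ck.lattice_intensity(img, straight_trace, background=cfg.bg_offset)
        excl = ck.lattice_intensity(img, straight_trace,
                                    comet_positions_um=[10.0, 20.0],
                                    background=cfg.bg_offset,
                                    exclusion_radius_um=3.0)
        assert incl > excl

    def test_full_exclusion_raises(self, clean_config, straight_trace):
        img = ck.Image2D(np.full(clean_config.image_shape, 3.0), 0.1)
        with pytest.raises(ValueError, match="entire trace"):
            ck.lattice_intensity(img, straight_trace,
                                 comet_positions_um=[15.0],
                                 exclusion_radius_um=100.0)
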