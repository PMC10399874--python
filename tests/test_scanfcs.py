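"""Scanning-FCS pipeline: localization, alignment, trace, correlator, fits."""

import numpy as np
import pytest

from ffskit.fcs_models import CorrelationCurve
from ffskit.scanfcs import (
    StageError,
    align_lines,
    compute_acf,
    detect_membrane,
    direct_acf,
    membrane_trace,
    run_sfcs,
    sfcs_brightness,
)
from ffskit.simulate import (
    IntensityTrace,
    Kymograph,
    SimConfig,
    simulate_kymograph,
    simulate_membrane_trace,
)


def background_kymo(n_lines=4000, n_pixels=256, rate=0.02, seed=31):
    rng = np.random.default_rng(seed)
    return Kymograph(rng.poisson(rate, (n_lines, n_pixels)).astype(np.int64),
                     line_time=472.73e-6, pixel_size=0.08)


class TestDetectMembrane:
    def test_static_center_recovered(self, membrane_setup):
        _, _, kymo = membrane_setup
        loc = detect_membrane(kymo, block_size=1000)
        assert loc.ok.all()
        assert np.all(np.abs(loc.centers - 128.0) < 0.3)
        assert np.all(np.abs(loc.sigmas - 3.0) < 0.5)

    def test_flat_kymograph_rejected(self):
        with pytest.raises(ValueError, match="peak"):
            detect_membrane(background_kymo())

    def test_drift_slope_recovered(self, membrane_setup):
        cfg, trace, _ = membrane_setup
        drift = 5e-4
        kymo = simulate_kymograph(trace, cfg, membrane_center=110.0, drift=drift)
        loc = detect_membrane(kymo, block_size=1000)
        slope = np.polyfit(loc.block_mid_lines[loc.ok], loc.centers[loc.ok], 1)[0]
        assert slope == pytest.approx(drift, rel=0.2)
        assert np.all(np.diff(loc.centers[loc.ok]) > -0.3)


class TestAlignLines:
    def test_zero_drift_is_identity(self, membrane_setup):
        _, _, kymo = membrane_setup
        loc = detect_membrane(kymo)
        res = align_lines(kymo, loc)
        assert np.array_equal(res.kymograph.counts, kymo.counts)
        assert np.all(res.shifts == 0)

    def test_drift_removed_and_counts_conserved(self, membrane_setup):
        cfg, trace, _ = membrane_setup
        kymo = simulate_kymograph(trace, cfg, membrane_center=110.0, drift=5e-4)
        loc = detect_membrane(kymo)
        res = align_lines(kymo, loc)
        assert np.array_equal(res.kymograph.counts.sum(axis=1),
                              kymo.counts.sum(axis=1))
        loc2 = detect_membrane(res.kymograph)
        centers = loc2.centers[loc2.ok]
        assert np.all(np.abs(centers - centers.mean()) < 0.5)
        assert np.all(np.abs(res.fractional_residual) <= 0.5)

    def test_large_shift_rejected(self, membrane_setup):
        _, _, kymo = membrane_setup
        loc = detect_membrane(kymo)
        loc.centers[loc.ok] += np.linspace(0, 60, loc.ok.sum())
        with pytest.raises(ValueError, match="10%"):
            align_lines(kymo, loc)


class TestMembraneTrace:
    def test_full_window_conserves_counts(self, membrane_setup):
        cfg, trace, _ = membrane_setup
        quiet = SimConfig(**{**cfg.__dict__, "background_rate": 0.0})
        kymo = simulate_kymograph(trace, quiet)
        loc = detect_membrane(kymo)
        res = align_lines(kymo, loc)
        ext = membrane_trace(res.kymograph, loc, halfwidth_sigmas=40.0,
                             background_exclusion=10.0)
        assert ext.background_per_pixel == 0.0
        assert np.array_equal(ext.trace.counts.astype(np.int64), trace.counts)

    def test_recovered_trace_correlates_with_generator(self, membrane_setup):
        cfg, trace, kymo = membrane_setup
        loc = detect_membrane(kymo)
        res = align_lines(kymo, loc)
        ext = membrane_trace(res.kymograph, loc)
        r = np.corrcoef(ext.trace.counts, trace.counts)[0, 1]
        assert r > 0.95

    def test_edge_window_rejected(self, membrane_setup):
        cfg, trace, _ = membrane_setup
        kymo = simulate_kymograph(trace, cfg, membrane_center=12.0)
        loc = detect_membrane(kymo)
        res = align_lines(kymo, loc)
        with pytest.raises(ValueError, match="edge"):
            membrane_trace(res.kymograph, loc, halfwidth_sigmas=6.0)


class TestComputeAcf:
    def test_constant_trace_gives_zero(self):
        trace = IntensityTrace(np.full(2048, 9, dtype=np.int64), 1e-3)
        curve = compute_acf(trace, n_segments=1)
        assert np.allclose(curve.G, 0.0, atol=1e-14)

    def test_multitau_equals_direct_at_unbinned_lags(self):
        rng = np.random.default_rng(32)
        trace = IntensityTrace(rng.poisson(4.0, 4096).astype(np.int64), 1e-3)
        mt = compute_acf(trace, m=16, n_segments=1)
        dr = direct_acf(trace, 32)
        np.testing.assert_allclose(mt.G[:32], dr.G, rtol=1e-12, atol=1e-15)
        np.testing.assert_allclose(mt.lags[:32], dr.lags, rtol=1e-12)

    def test_iid_poisson_has_no_correlation(self):
        rng = np.random.default_rng(33)
        trace = IntensityTrace(rng.poisson(5.0, 1 << 15).astype(np.int64), 1e-3)
        curve = compute_acf(trace, n_segments=8)
        assert np.all(np.abs(curve.G) < 4 * np.maximum(curve.sd_G, 1e-6))

    def test_zero_trace_rejected(self):
        trace = IntensityTrace(np.zeros(2048, dtype=np.int64), 1e-3)
        with pytest.raises(ValueError, match="zero-mean"):
            compute_acf(trace)

    def test_first_lag_is_one_bin(self):
        rng = np.random.default_rng(34)
        trace = IntensityTrace(rng.poisson(4.0, 4096).astype(np.int64), 472.73e-6)
        curve = compute_acf(trace, n_segments=1)
        assert curve.lags[0] == pytest.approx(472.73e-6)

    def test_segment_sd_present(self):
        rng = np.random.default_rng(35)
        trace = IntensityTrace(rng.poisson(4.0, 1 << 14).astype(np.int64), 1e-3)
        curve = compute_acf(trace, n_segments=8)
        assert curve.sd_G is not None and np.all(curve.sd_G >= 0)
        assert curve.n_segments + curve.n_rejected == 8


class TestBrightness:
    def test_division(self):
        from ffskit.fcs_models import FitResult
        trace = IntensityTrace(np.full(1000, 5, dtype=np.int64), 5e-4)
        fit = FitResult(model="2d", params={"N": 5.0}, stderr={}, redchi=1.0,
                        converged=True)
        assert sfcs_brightness(trace, fit) == pytest.approx(10_000 / 5.0)
        fit2 = FitResult(model="2d", params={"N": 10.0}, stderr={}, redchi=1.0,
                         converged=True)
        assert sfcs_brightness(trace, fit2) == pytest.approx(
            sfcs_brightness(trace, fit) / 2)

    def test_unconverged_rejected(self):
        from ffskit.fcs_models import FitResult
        trace = IntensityTrace(np.full(1000, 5, dtype=np.int64), 5e-4)
        fit = FitResult(model="2d", params={"N": 5.0}, stderr={}, redchi=1.0,
                        converged=False)
        with pytest.raises(ValueError, match="converge"):
            sfcs_brightness(trace, fit)


class TestRunSfcs:
    def test_end_to_end_recovery(self, membrane_setup):
        cfg, _, kymo = membrane_setup
        res = run_sfcs(kymo, s_fixed=1.0)
        assert res.fit.converged
        assert res.fit.params["N"] == pytest.approx(cfg.n_particles_mean, rel=0.15)
        assert res.fit.params["tau_d"] == pytest.approx(cfg.tau_d_2d, rel=0.25)
        assert res.brightness == pytest.approx(cfg.molecular_brightness / 2, rel=0.15)

    def test_background_only_fails_at_detection(self):
        with pytest.raises(StageError, match="detect_membrane"):
            run_sfcs(background_kymo())

    def test_same_input_same_record(self, membrane_setup):
        _, _, kymo = membrane_setup
        a = run_sfcs(kymo, s_fixed=1.0)
        b = run_sfcs(kymo, s_fixed=1.0)
        assert a.fit.params == b.fit.params
        assert a.brightness == b.brightness
        assert np.array_equal(a.extraction.trace.counts, b.extraction.trace.counts)


class TestOligomerBrightnessRatio:
    def test_dimer_to_monomer_ratio_is_one_plus_p(self):
        """FCS brightness weights emitters by q^2/q, so partially labelled
        dimers are brighter by 1+p relative to monomers."""
        p = 0.7
        brightness = {}
        for label, subunits in (("monomer", 1), ("dimer", 2)):
            cfg = SimConfig(seed=91, geometry="membrane2d", subunits=subunits,
                            fluorescence_probability=p, n_particles_mean=10.0,
                            molecular_brightness=3000.0,
                            diffusion_coefficient=1.0, background_rate=1000.0)
            trace = simulate_membrane_trace(cfg, duration=60_000 * cfg.line_time)
            kymo = simulate_kymograph(trace, cfg)
            brightness[label] = run_sfcs(kymo, s_fixed=1.0).brightness
        ratio = brightness["dimer"] / brightness["monomer"]
        assert ratio == pytest.approx(1 + p, rel=0.15)
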