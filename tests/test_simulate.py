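"""Statistical and structural checks of the synthetic photon-count generators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from ffskit.simulate import (
    SimConfig,
    simulate_kymograph,
    simulate_membrane_trace,
    simulate_nb_stack,
    simulate_point_trace,
)


def enumerated_apparent_brightness(subunits: int, p: float, lam: float) -> float:
    """Independent oracle for the apparent brightness of binomially labelled
    oligomers: sum_q f(q) q^2 lam^2 / sum_q f(q) q lam over q = 0..subunits."""
    q = np.arange(subunits + 1)
    f = binom.pmf(q, subunits, p)
    num = float((f * q**2).sum()) * lam**2
    den = float((f * q).sum()) * lam
    return num / den if den > 0 else 0.0


class TestSimConfig:
    @pytest.mark.parametrize("bad", [
        dict(fluorescence_probability=1.2),
        dict(fluorescence_probability=-0.1),
        dict(subunits=0),
        dict(bleach_rate=-1.0),
        dict(geometry="widefield"),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            SimConfig(**bad)

    @given(s=st.integers(1, 3), p=st.floats(0.01, 1.0),
           lam=st.floats(0.01, 2.0))
    @settings(max_examples=60, deadline=None)
    def test_apparent_brightness_closed_form(self, s, p, lam):
        """lambda*(1+(s-1)p) equals the exhaustive-enumeration oracle."""
        cfg = SimConfig(subunits=s, fluorescence_probability=p,
                        molecular_brightness=lam / 50e-6)
        expected = enumerated_apparent_brightness(s, p, lam)
        assert cfg.apparent_brightness_per_dwell == pytest.approx(expected, rel=1e-9, abs=1e-12)


class TestNbStack:
    def test_dark_stack_is_all_zero(self):
        cfg = SimConfig(seed=0, molecular_brightness=0.0, background_rate=0.0,
                        height=16, width=16, n_frames=10)
        assert not simulate_nb_stack(cfg).counts.any()

    def test_mean_counts_match_occupancy_times_rate(self):
        # n=5 emitters, 0.5 counts/dwell each -> 2.5 counts mean
        cfg = SimConfig(seed=2, n_particles_mean=5.0, height=64, width=64,
                        n_frames=40)
        stack = simulate_nb_stack(cfg)
        n_samples = stack.counts.size
        se = np.sqrt(2.5 * (1.5) / n_samples) * 3  # generous bound
        assert stack.counts.mean() == pytest.approx(2.5, abs=5 * se)

    def test_dimer_apparent_brightness_matches_enumeration(self):
        """(sigma^2-k)/k pooled over >=1e6 pixel-frames -> (1+p)*lambda within 2%."""
        cfg = SimConfig(seed=3, subunits=2, fluorescence_probability=0.7,
                        n_particles_mean=5.0, height=128, width=128, n_frames=100)
        stack = simulate_nb_stack(cfg)
        counts = stack.counts.astype(float)
        k = counts.mean(axis=0)
        s2 = counts.var(axis=0, ddof=1)
        pooled = (s2 - k).sum() / k.sum()
        expected = enumerated_apparent_brightness(2, 0.7, cfg.counts_per_dwell)
        assert expected == pytest.approx(1.7 * cfg.counts_per_dwell)
        assert pooled == pytest.approx(expected, rel=0.02)

    def test_bleaching_reduces_late_frames(self):
        cfg = SimConfig(seed=4, bleach_rate=0.01, height=64, width=64,
                        n_frames=100)
        stack = simulate_nb_stack(cfg)
        totals = stack.counts.sum(axis=(1, 2))
        expected_drop = np.exp(-cfg.bleach_rate * 99 * cfg.raster_frame_interval)
        ratio = totals[-10:].mean() / totals[:10].mean()
        assert ratio == pytest.approx(expected_drop, rel=0.05)

    def test_stationary_without_bleaching(self):
        cfg = SimConfig(seed=5, height=64, width=64, n_frames=100)
        totals = simulate_nb_stack(cfg).counts.sum(axis=(1, 2)).astype(float)
        dec = totals.size // 10
        first, last = totals[:dec], totals[-dec:]
        se = np.sqrt(first.var(ddof=1) / dec + last.var(ddof=1) / dec)
        assert abs(first.mean() - last.mean()) < 3 * se

    def test_geometry_guard(self):
        with pytest.raises(ValueError, match="raster3d"):
            simulate_nb_stack(SimConfig(geometry="membrane2d"))

    def test_deterministic(self):
        cfg = SimConfig(seed=6, height=32, width=32, n_frames=10)
        assert np.array_equal(simulate_nb_stack(cfg).counts,
                              simulate_nb_stack(cfg).counts)


class TestMembraneTrace:
    def test_frozen_particles_give_flat_trace(self):
        """D=0: no number fluctuations, so the fluctuation ACF vanishes."""
        cfg = SimConfig(seed=7, geometry="membrane2d", diffusion_coefficient=0.0,
                        n_particles_mean=5.0, molecular_brightness=3000.0)
        trace = simulate_membrane_trace(cfg, duration=2048 * cfg.line_time)
        x = trace.counts.astype(float)
        if x.mean() == 0:  # all emitters may sit far from the spot
            pytest.skip("no emitter near the detection spot for this seed")
        d = x - x.mean()
        acf1 = (d[:-1] * d[1:]).mean() / x.mean() ** 2
        se = 3.0 / (x.mean() * np.sqrt(x.size))  # shot-noise scale
        assert abs(acf1) < 3 * se + 1e-3

    def test_stationary_mean(self):
        cfg = SimConfig(seed=8, geometry="membrane2d", n_particles_mean=10.0,
                        molecular_brightness=3000.0)
        trace = simulate_membrane_trace(cfg, duration=20_000 * cfg.line_time)
        half = trace.counts.size // 2
        a, b = trace.counts[:half], trace.counts[half:]
        se = np.sqrt(a.var(ddof=1) / half + b.var(ddof=1) / half)
        # temporal correlation inflates the naive SE; allow a wide factor
        assert abs(a.mean() - b.mean()) < 12 * se

    def test_small_box_rejected(self):
        cfg = SimConfig(geometry="membrane2d", box_factor=8.0)
        with pytest.raises(ValueError, match="10"):
            simulate_membrane_trace(cfg, duration=1.0)

    def test_deterministic(self, membrane_setup):
        cfg, trace, _ = membrane_setup
        again = simulate_membrane_trace(cfg, duration=80_000 * cfg.line_time)
        assert np.array_equal(trace.counts, again.counts)


class TestKymograph:
    def test_line_sums_conserved_without_background(self, membrane_setup):
        cfg, trace, _ = membrane_setup
        quiet = SimConfig(**{**cfg.__dict__, "background_rate": 0.0})
        kymo = simulate_kymograph(trace, quiet)
        assert np.array_equal(kymo.counts.sum(axis=1), trace.counts)

    def test_pure_background_level(self):
        cfg = SimConfig(seed=9, geometry="membrane2d", background_rate=50_000.0)
        from ffskit.simulate import IntensityTrace
        zeros = IntensityTrace(np.zeros(20_000, dtype=np.int64), cfg.line_time)
        kymo = simulate_kymograph(zeros, cfg)
        per_pixel = cfg.background_rate * cfg.line_time / cfg.scan_pixels
        measured = kymo.counts.mean(axis=0)
        se = np.sqrt(per_pixel / kymo.n_lines)
        assert np.all(np.abs(measured - per_pixel) < 5 * se)

    def test_drift_out_of_frame_rejected(self, membrane_setup):
        cfg, trace, _ = membrane_setup
        with pytest.raises(ValueError, match="centre"):
            simulate_kymograph(trace, cfg, membrane_center=128.0, drift=0.01)

    def test_deterministic(self, membrane_setup):
        cfg, trace, kymo = membrane_setup
        assert np.array_equal(kymo.counts, simulate_kymograph(trace, cfg).counts)


class TestPointTrace:
    def test_counts_and_determinism(self):
        cfg = SimConfig(seed=10, geometry="point3d", n_particles_mean=1.5,
                        molecular_brightness=50_000.0, diffusion_coefficient=333.0)
        t1 = simulate_point_trace(cfg, duration=0.05, dt=2e-6)
        t2 = simulate_point_trace(cfg, duration=0.05, dt=2e-6)
        assert t1.counts.min() >= 0 and t1.counts.sum() > 0
        assert np.array_equal(t1.counts, t2.counts)

    def test_bad_dt_rejected(self):
        cfg = SimConfig(geometry="point3d")
        with pytest.raises(ValueError, match="dt"):
            simulate_point_trace(cfg, duration=1.0, dt=0.0)

    def test_geometry_guard(self):
        with pytest.raises(ValueError, match="point3d"):
            simulate_point_trace(SimConfig(), duration=1.0, dt=1e-6)


class TestBleachingAndBlinking:
    def test_membrane_bleaching_causes_decay(self):
        cfg = SimConfig(seed=12, geometry="membrane2d", n_particles_mean=10.0,
                        molecular_brightness=5000.0, diffusion_coefficient=1.0,
                        bleach_rate=50.0)
        trace = simulate_membrane_trace(cfg, duration=20_000 * cfg.line_time)
        third = trace.counts.size // 3
        assert trace.counts[:third].mean() > 1.5 * trace.counts[-third:].mean()

    def test_membrane_bleaching_deterministic(self):
        cfg = SimConfig(seed=13, geometry="membrane2d", bleach_rate=20.0,
                        molecular_brightness=5000.0)
        a = simulate_membrane_trace(cfg, duration=2048 * cfg.line_time)
        b = simulate_membrane_trace(cfg, duration=2048 * cfg.line_time)
        assert np.array_equal(a.counts, b.counts)

    def test_point_blinking_reduces_mean_rate(self):
        base = dict(geometry="point3d", n_particles_mean=2.0,
                    molecular_brightness=80_000.0, diffusion_coefficient=50.0)
        steady = simulate_point_trace(SimConfig(seed=14, **base), 0.05, 2e-6)
        blinky = simulate_point_trace(
            SimConfig(seed=14, blink_off_rate=5e4, blink_on_rate=5e4, **base),
            0.05, 2e-6)
        # equal on/off rates -> half the emitters dark on average
        ratio = blinky.counts.mean() / steady.counts.mean()
        assert 0.3 < ratio < 0.7
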