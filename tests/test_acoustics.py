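"""Spherical-head acoustics, ground reflection, and ITD metrics."""

import numpy as np
import pytest

from itdfreq import acoustics as ac
from itdfreq.circstats import wrap_phase
from itdfreq.cpcd import PhaseFrequencyCurve
from itdfreq.exceptions import UndefinedStatisticError
from itdfreq.synthetic import generate_ipd_set


class TestSphere:
    def test_midline_source_gives_zero_ipd(self, freq_grid):
        cfg = ac.HeadModelConfig(source_azimuth=0.0)
        g = ac.sphere_hrtf(cfg, freq_grid)
        spec = ac.ipd_spectrum(g, freq_grid, 0.0)
        assert np.abs(spec.ipd).max() < 1e-9

    def test_low_frequency_diffraction_limit(self, sphere_spec_90):
        # ITD_p -> 3 (a/c) sin(theta) as ka -> 0
        a, c = 0.073 / 2, 343.0
        itd_p_100 = sphere_spec_90.ipd[0] / sphere_spec_90.freqs[0]
        assert itd_p_100 == pytest.approx(3 * a / c, rel=0.05)

    def test_antisymmetry_in_azimuth(self, freq_grid):
        gp = ac.sphere_hrtf(ac.HeadModelConfig(source_azimuth=40.0), freq_grid)
        gm = ac.sphere_hrtf(ac.HeadModelConfig(source_azimuth=-40.0), freq_grid)
        ip = ac.ipd_spectrum(gp, freq_grid, 40.0).ipd
        im = ac.ipd_spectrum(gm, freq_grid, -40.0).ipd
        assert np.abs(ip + im).max() < 1e-9

    def test_head_shadow_at_high_frequency(self, freq_grid):
        cfg = ac.HeadModelConfig(source_azimuth=90.0)
        g_ipsi, g_contra = ac.sphere_hrtf(cfg, freq_grid)
        i3k = np.searchsorted(freq_grid, 3000.0)
        assert abs(g_ipsi[i3k]) > abs(g_contra[i3k])

    def test_series_convergence_reference(self):
        # fine-quadrature reference: same series summed far past the
        # adaptive cut must agree to the requested tolerance
        freqs = np.array([500.0, 1500.0, 3000.0])
        a = 0.0365
        lo = ac.sphere_pressure(freqs, 1.5, 0.5, a, max_order=120)
        hi = ac.sphere_pressure(freqs, 1.5, 0.5, a, max_order=120, rtol=1e-12)
        assert np.abs(lo - hi).max() / np.abs(hi).max() < 1e-6


class TestGround:
    def test_extra_path_delay_near_150_us(self):
        ground = ac.GroundConfig(head_height=0.2, source_height=0.2,
                                 horizontal_distance=1.5)
        tau = ac.extra_path_delay(ground, speed_of_sound=343.0)
        assert tau * 1e6 == pytest.approx(153.0, abs=10.0)

    def test_perfect_reflector_comb_nulls(self, freq_grid):
        # R = 1, free-field reflected ray: |1 + e^{-i 2 pi f tau}| vanishes
        # at odd multiples of 1/(2 tau)
        ground = ac.GroundConfig(flow_resistivity=np.inf)
        cfg = ac.HeadModelConfig(source_azimuth=0.0,
                                 source_distance=ground.horizontal_distance)
        tau = ac.extra_path_delay(ground, cfg.speed_of_sound)
        g = ac.sphere_hrtf(cfg, freq_grid)
        gg = ac.add_ground_reflection(g, cfg, ground, freq_grid,
                                      diffract_reflection=False)
        ratio = np.abs(gg[0] / g[0])
        null_freqs = [(2 * k + 1) / (2 * tau) for k in range(2)]
        for fn in null_freqs:
            if freq_grid[0] < fn < freq_grid[-1]:
                i = np.argmin(np.abs(freq_grid - fn))
                spread = cfg.source_distance / (cfg.source_distance
                                                + tau * cfg.speed_of_sound)
                assert ratio[i] < (1 - spread) + 0.05

    def test_rigid_ground_limit_of_reflection_coefficient(self, freq_grid):
        ground = ac.GroundConfig(flow_resistivity=1e12)
        R = ac.ground_reflection_coefficient(freq_grid, ground)
        assert np.abs(R - 1.0).max() < 1e-2

    def test_reflection_coefficient_recomputed_independently(self, freq_grid):
        # second implementation of the impedance formula
        ground = ac.GroundConfig()
        R = ac.ground_reflection_coefficient(freq_grid, ground)
        x = ground.horizontal_distance
        cos_i = (ground.source_height + ground.head_height) / np.hypot(
            x, ground.source_height + ground.head_height)
        X = 1.2 * freq_grid / ground.flow_resistivity
        zeta = 1 + 0.0571 * X ** (-0.754) + 1j * 0.087 * X ** (-0.732)
        R2 = (zeta * cos_i - 1) / (zeta * cos_i + 1)
        assert np.abs(R - R2).max() < 1e-10

    def test_ground_adds_local_ipd_structure(self, freq_grid):
        # core contrast: the bare sphere's band-wise characteristic phase
        # is ~0 at low CF, while the ground reflection drives |cp| beyond
        # 0.1 cycles at some (azimuth, CF)
        ground = ac.GroundConfig()
        d = float(np.hypot(ground.horizontal_distance,
                           ground.source_height - ground.head_height))
        cfg = ac.HeadModelConfig(source_azimuth=40.0, source_distance=d)
        g = ac.sphere_hrtf(cfg, freq_grid)
        bare = ac.ipd_spectrum(g, freq_grid, 40.0)
        gnd = ac.ipd_spectrum(
            ac.add_ground_reflection(g, cfg, ground, freq_grid),
            freq_grid, 40.0)
        low_cfs = np.geomspace(350, 500, 4)
        assert max(abs(ac.acoustical_cpcd(bare, cf).cp)
                   for cf in low_cfs) < 0.02
        cfs = np.geomspace(350, 2800, 12)
        assert max(abs(ac.acoustical_cpcd(gnd, cf).cp) for cf in cfs) > 0.1


class TestIpdSpectrum:
    def test_pure_delay_filter(self, freq_grid):
        tau = 300e-6
        g_ipsi = np.ones(freq_grid.size, dtype=complex)
        g_contra = np.exp(2j * np.pi * freq_grid * tau)  # delayed by tau
        spec = ac.ipd_spectrum((g_ipsi, g_contra), freq_grid, 0.0)
        assert np.abs(spec.ipd - tau * freq_grid).max() < 1e-9

    def test_zero_gain_rejected(self, freq_grid):
        g = np.ones(freq_grid.size, dtype=complex)
        bad = g.copy()
        bad[5] = 0.0
        with pytest.raises(UndefinedStatisticError):
            ac.ipd_spectrum((g, bad), freq_grid, 0.0)


class TestItdMetrics:
    def test_pure_delay(self):
        spec = generate_ipd_set("pure_delay", tau_s=250e-6)[0]
        m = ac.itd_metrics(spec)
        assert np.abs(m.itd_p - 250e-6).max() < 1e-9
        assert np.abs(m.itd_g - 250e-6).max() < 1e-7
        assert np.abs(m.idi).max() < 1e-3

    def test_affine_phase(self):
        # ipd = tau f + 0.5: itd_g = tau, idi = 0.5, itd_p = tau + 0.5/f
        spec = generate_ipd_set("affine", cp=0.5, cd_ms=0.25)[0]
        m = ac.itd_metrics(spec)
        assert np.abs(m.itd_g - 250e-6).max() < 1e-7
        assert np.abs(m.idi - 0.5).max() < 1e-3
        assert np.abs(m.itd_p - (250e-6 + 0.5 / spec.freqs)).max() < 1e-9

    def test_identity_on_ground_spectrum(self, ground_spec_70):
        m = ac.itd_metrics(ground_spec_70)
        assert np.abs(m.itd_p - (m.itd_g + m.idi / m.freqs)).max() < 1e-9

    def test_window_intercept_cross_checks_idi(self, ground_spec_70):
        m = ac.itd_metrics(ground_spec_70)
        dev = np.abs(wrap_phase(m.window_intercepts - m.idi))
        assert np.percentile(dev, 95) < 0.02


class TestAcousticalCpcd:
    def test_pure_delay_window(self):
        spec = generate_ipd_set("pure_delay", tau_s=325e-6)[0]
        r = ac.acoustical_cpcd(spec, 800.0)
        assert r.cp == pytest.approx(0.0, abs=1e-6)
        assert r.cd == pytest.approx(0.325, abs=1e-6)

    def test_affine_window_recovery(self):
        # affine IPD built from the measured-HRTF band readout:
        # intercept 0.12 cycle, slope 167 us
        spec = generate_ipd_set("affine", cp=0.12, cd_ms=0.167)[0]
        r = ac.acoustical_cpcd(spec, 800.0)
        assert r.cp == pytest.approx(0.12, abs=1e-6)
        assert r.cd == pytest.approx(0.167, abs=1e-6)
        assert r.bandwidth == pytest.approx(800.0 / (1.04 + 3.8e-4 * 800.0))

    def test_window_outside_grid_rejected(self):
        spec = generate_ipd_set("affine", cp=0.0, cd_ms=0.1)[0]
        with pytest.raises(ValueError):
            ac.acoustical_cpcd(spec, 50.0)


class TestBestAzimuth:
    def _specs(self, freq_grid):
        azs = [10.0, 30.0, 50.0, 70.0, 90.0]
        return generate_ipd_set("sphere", azimuths=azs, freqs=freq_grid)

    def test_exact_match_recovers_azimuth(self, freq_grid):
        specs = self._specs(freq_grid)
        target = specs[2]
        freqs = np.linspace(300, 1500, 7)
        idx = np.searchsorted(target.freqs, freqs)
        curve = PhaseFrequencyCurve(
            "c", freqs, wrap_phase(target.ipd[idx]), np.ones(7))
        assert ac.best_azimuth(curve, specs) == 50.0

    def test_noisy_recovery(self, freq_grid):
        specs = self._specs(freq_grid)
        rng = np.random.default_rng(0)
        hits = 0
        freqs = np.linspace(300, 1500, 7)
        for t in range(60):
            target = specs[rng.integers(len(specs))]
            idx = np.searchsorted(target.freqs, freqs)
            curve = PhaseFrequencyCurve(
                "c", freqs,
                wrap_phase(target.ipd[idx] + rng.normal(0, 0.02, 7)),
                np.ones(7))
            ba = ac.best_azimuth(curve, specs)
            hits += abs(ba - target.azimuth) <= 20.0
        assert hits >= 57  # >= 95% within one azimuth step

    def test_needs_two_azimuths(self, freq_grid):
        specs = self._specs(freq_grid)[:1]
        curve = PhaseFrequencyCurve("c", np.linspace(300, 1500, 5),
                                    np.zeros(5), np.ones(5))
        with pytest.raises(ValueError):
            ac.best_azimuth(curve, specs)
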