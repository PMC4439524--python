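"""Circular-linear CP/CD regression: objective, fit, residual, linearity."""

import numpy as np
import pytest

from itdfreq.circstats import wrap_phase
from itdfreq.cpcd import (
    CPCDFit,
    PhaseFrequencyCurve,
    best_itd_per_freq,
    best_itd_range,
    fit_cpcd,
    linearity_significance,
    null_residual_bank,
    objective,
    residual_error,
)
from itdfreq.exceptions import InsufficientDataError


def linear_curve(cp, cd_ms, freqs=None, srs=None, noise=0.0, seed=None):
    freqs = np.linspace(400, 1200, 9) if freqs is None else np.asarray(freqs)
    rng = np.random.default_rng(seed)
    bps = wrap_phase(cp + cd_ms * freqs / 1000.0
                     + (rng.normal(0, noise, freqs.size) if noise else 0.0))
    srs = np.ones(freqs.size) if srs is None else np.asarray(srs)
    return PhaseFrequencyCurve("cell", freqs, bps, srs)


class TestObjective:
    def test_zero_on_perfect_line(self):
        c = linear_curve(0.0, 0.0)
        assert objective(c, 0.0, 0.0) == 0.0

    def test_antiphase_sums_weights(self):
        c = PhaseFrequencyCurve("c", np.linspace(400, 1200, 5),
                                np.zeros(5), np.ones(5))
        assert objective(c, 0.5, 0.0) == pytest.approx(5.0)

    def test_termwise_oracle(self):
        rng = np.random.default_rng(0)
        c = PhaseFrequencyCurve(
            "c", np.sort(rng.uniform(300, 3000, 9)),
            rng.uniform(-0.5, 0.5, 9), rng.uniform(0, 30, 9),
        )
        cp, cd = 0.21, -0.6
        expected = sum(
            w * 0.5 * (1 - np.cos(2 * np.pi * (bp - cp - cd * f / 1000)))
            for f, bp, w in zip(c.freqs, c.bps, c.srs)
        )
        assert objective(c, cp, cd) == pytest.approx(expected, abs=1e-12)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            PhaseFrequencyCurve("c", np.linspace(400, 1200, 5),
                                np.zeros(5), -np.ones(5))


class TestFit:
    def test_recovers_example_cell_parameters(self):
        # generated from the example cell's values: CP 0.27 cyc, CD -0.102 ms
        fit = fit_cpcd(linear_curve(0.27, -0.102))
        assert fit.cp == pytest.approx(0.27, abs=1e-6)
        assert fit.cd == pytest.approx(-0.102, abs=1e-6)
        assert fit.residual < 1e-12

    def test_constant_phase_gives_zero_cp_cd(self):
        fit = fit_cpcd(linear_curve(0.0, 0.0))
        assert fit.cp == pytest.approx(0.0, abs=1e-9)
        assert fit.cd == pytest.approx(0.0, abs=1e-9)

    def test_recovers_wrapping_delay_where_ols_fails(self):
        # cd = 1.5 ms over 400-1200 Hz wraps BP several times
        c = linear_curve(0.1, 1.5)
        fit = fit_cpcd(c)
        assert fit.cp == pytest.approx(0.1, abs=1e-6)
        assert fit.cd == pytest.approx(1.5, abs=1e-6)
        ols = np.polyfit(c.freqs / 1000.0, c.bps, 1)
        assert abs(ols[0] - 1.5) > 0.5  # unwrapped OLS misses the slope

    def test_matches_brute_force_fine_grid(self):
        rng = np.random.default_rng(1)
        cp_g = np.arange(-0.5, 0.5, 1e-3)
        cd_g = np.arange(-2.0, 2.0, 1e-3)
        for i in range(4):
            c = linear_curve(
                rng.uniform(-0.5, 0.5), rng.uniform(-1.5, 1.5),
                noise=0.08, seed=100 + i,
            )
            fit = fit_cpcd(c)
            # brute force on the fine grid (oracle): best E within one cell
            pred = (cp_g[:, None, None] + cd_g[None, :, None]
                    * c.freqs[None, None, :] / 1000.0)
            E = (c.srs * 0.5 * (1 - np.cos(2 * np.pi * (c.bps - pred)))).sum(-1)
            j, k = np.unravel_index(np.argmin(E), E.shape)
            assert abs(wrap_phase(fit.cp - cp_g[j])) <= 2e-3
            assert abs(fit.cd - cd_g[k]) <= 2e-3

    def test_refinement_never_worse_than_grid(self):
        rng = np.random.default_rng(2)
        for i in range(20):
            c = linear_curve(rng.uniform(-0.5, 0.5), rng.uniform(-1, 1),
                             noise=0.15, seed=200 + i)
            fit = fit_cpcd(c)
            # compare against every grid node
            cps = np.linspace(-0.5, 0.5, 51)
            cds = np.linspace(-2, 2, 201)
            pred = (cps[:, None, None] + cds[None, :, None]
                    * c.freqs[None, None, :] / 1000.0)
            E = (c.srs * 0.5 * (1 - np.cos(2 * np.pi * (c.bps - pred)))).sum(-1)
            assert fit.objective <= E.min() + 1e-12

    def test_equivariance_phase_and_delay(self):
        base = linear_curve(0.1, -0.3, noise=0.05, seed=3)
        f0 = fit_cpcd(base)
        shifted = PhaseFrequencyCurve(
            "cell", base.freqs, wrap_phase(base.bps + 0.2), base.srs)
        fs = fit_cpcd(shifted)
        assert wrap_phase(fs.cp - f0.cp) == pytest.approx(0.2, abs=1e-6)
        assert fs.cd == pytest.approx(f0.cd, abs=1e-6)
        delayed = PhaseFrequencyCurve(
            "cell", base.freqs,
            wrap_phase(base.bps + 0.4 * base.freqs / 1000.0), base.srs)
        fd = fit_cpcd(delayed)
        assert fd.cd - f0.cd == pytest.approx(0.4, abs=1e-6)
        assert wrap_phase(fd.cp - f0.cp) == pytest.approx(0.0, abs=1e-6)

    def test_zero_weights_rejected(self):
        c = PhaseFrequencyCurve("c", np.linspace(400, 1200, 5),
                                np.zeros(5), np.zeros(5))
        with pytest.raises(InsufficientDataError):
            fit_cpcd(c)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            PhaseFrequencyCurve("c", np.linspace(400, 1200, 4),
                                np.zeros(4), np.ones(4))


class TestResidual:
    def test_perfect_and_antiphase_extremes(self):
        c = linear_curve(0.2, -0.4)
        fit = fit_cpcd(c)
        assert residual_error(c, fit) == pytest.approx(0.0, abs=1e-12)
        anti = CPCDFit(cp=wrap_phase(0.7), cd=-0.4, residual=np.nan,
                       linearity_p=None, n_points=9)
        assert residual_error(c, anti) == pytest.approx(1.0, abs=1e-12)

    def test_termwise_oracle(self):
        rng = np.random.default_rng(4)
        c = PhaseFrequencyCurve("c", np.linspace(300, 2500, 8),
                                rng.uniform(-0.5, 0.5, 8), np.ones(8))
        fit = CPCDFit(cp=0.11, cd=0.3, residual=np.nan, linearity_p=None,
                      n_points=8)
        manual = np.mean(
            [0.5 * (1 - np.cos(2 * np.pi * (bp - 0.11 - 0.3 * f / 1000)))
             for f, bp in zip(c.freqs, c.bps)]
        )
        assert residual_error(c, fit) == pytest.approx(manual, abs=1e-12)


class TestLinearitySignificance:
    def test_zero_residual_has_minimal_p(self):
        p = linearity_significance(9, 0.0, n_surrogates=999, seed=0)
        assert p == pytest.approx(1.0 / 1000.0)

    def test_noiseless_line_highly_significant(self):
        c = linear_curve(0.27, -0.102)
        fit = fit_cpcd(c)
        p = linearity_significance(9, fit.residual, n_surrogates=1999, seed=1)
        assert p <= 1.0 / 2000.0

    def test_null_p_values_uniform(self):
        # residuals drawn from the null scored against an independent bank
        bank = null_residual_bank(7, 1999, seed=100)
        obs = null_residual_bank(7, 300, seed=200)
        ps = np.array([linearity_significance(7, r, bank=bank) for r in obs])
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01


class TestBestItd:
    def test_constant_itd_gives_zero_range(self):
        c = linear_curve(0.0, 0.0, freqs=[400, 600, 900, 1000, 1100])
        assert best_itd_range(c, [345.0] * 5) == 0.0

    def test_max_minus_min(self):
        c = PhaseFrequencyCurve("c", np.array([400, 600, 900, 1000, 1100]),
                                np.zeros(5), np.ones(5))
        r = best_itd_range(c, [500.0, 345.0, 158.0, 200.0, 300.0])
        assert r == pytest.approx(342.0)

    def test_threshold_excludes_weak_points(self):
        c = PhaseFrequencyCurve("c", np.array([400., 600, 900, 1000, 1100]),
                                np.zeros(5),
                                np.array([0.1, 1.0, 0.2, 0.3, 0.4]))
        r = best_itd_range(c, [500.0, 345.0, 158.0, 120.0, 130.0])
        assert r == 0.0  # only the peak-SR point passes the 80% cut

    def test_minimal_itd_candidate(self):
        c = PhaseFrequencyCurve("c", np.array([500., 800, 1000, 1600, 2000]),
                                np.array([0.4, -0.45, 0.1, 0.2, -0.2]),
                                np.ones(5))
        itds = best_itd_per_freq(c)
        # every reported ITD is within half a period of zero
        assert np.all(np.abs(itds) <= 0.5 / c.freqs * 1e6 + 1e-9)
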