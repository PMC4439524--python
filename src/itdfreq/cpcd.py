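"""Weighted circular-linear regression of best phase on frequency.

A binaural cell's best phase BP(f), measured at several tone frequencies,
is modeled as a line in phase space::

    BP(f) ~ CP + CD * f        (phases in cycles, CD in time units)

The intercept is the characteristic phase (CP, cycles) and the slope the
characteristic delay (CD, ms).  Because phase is circular, the fit
minimizes a sum of circular distances rather than squared residuals of an
unwrapped phase::

    E(CP, CD) = sum_f  SR(f) * d(BP(f), CP + CD * f)

with ``d(x, y) = (1 - cos(2 pi (x - y))) / 2`` and sync-rate weights SR.
The objective is smooth but multimodal, so the minimization proceeds in
two stages: an exhaustive scan of a regular (CP, CD) grid (CP in
[-0.5, 0.5] cycles, CD in [-2, 2] ms), followed by damped-Newton descent
from the best node.  Internally CD is handled in ms and frequency in kHz
so both parameters are O(1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from itdfreq.circstats import circular_distance, wrap_phase
from itdfreq.exceptions import InsufficientDataError

__all__ = [
    "PhaseFrequencyCurve",
    "CPCDFit",
    "objective",
    "fit_cpcd",
    "fit_phase_line",
    "residual_error",
    "null_residual_bank",
    "linearity_significance",
    "best_itd_per_freq",
    "best_itd_range",
]

#: default grid steps (cycles, ms) for the exhaustive stage
DEFAULT_CP_STEP = 0.02
DEFAULT_CD_STEP = 0.02
DEFAULT_CD_RANGE = 2.0
MIN_POINTS = 5


@dataclass
class PhaseFrequencyCurve:
    """Per-cell (frequency, best phase, sync-rate) triples.

    Frequencies must be strictly increasing and at least 5 points are
    required (cells with fewer significant points are not fit).
    """

    cell_id: str
    freqs: np.ndarray
    bps: np.ndarray
    srs: np.ndarray
    cf: float | None = None
    bf: float | None = None

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.bps = np.asarray(self.bps, dtype=float)
        self.srs = np.asarray(self.srs, dtype=float)
        if not (self.freqs.size == self.bps.size == self.srs.size):
            raise ValueError("freqs, bps and srs must have equal length")
        if self.freqs.size < MIN_POINTS:
            raise InsufficientDataError(
                f"cell {self.cell_id}: {self.freqs.size} points "
                f"(at least {MIN_POINTS} required)"
            )
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.srs < 0):
            raise ValueError("sync-rate weights must be nonnegative")


@dataclass
class CPCDFit:
    """Result of the circular-linear fit for one cell."""

    cp: float  # cycles, wrapped to [-0.5, 0.5)
    cd: float  # ms
    residual: float  # unweighted mean circular distance, in [0, 1]
    linearity_p: float | None
    n_points: int
    objective: float = np.nan  # weighted objective at the optimum


def objective(curve: PhaseFrequencyCurve, cp: float, cd: float) -> float:
    """Sync-rate-weighted sum of circular distances to the line ``cp + cd*f``.

    ``cd`` is in ms; the product ``cd * f`` is evaluated in cycles
    (ms * kHz).  Zero iff every BP lies exactly on the wrapped line.
    """
    pred = cp + cd * (curve.freqs / 1000.0)
    return float(np.sum(curve.srs * circular_distance(curve.bps, pred)))


def _grid_nodes(cp_step: float, cd_step: float, cd_range: float):
    n_cp = int(round(1.0 / cp_step)) + 1
    n_cd = int(round(2.0 * cd_range / cd_step)) + 1
    cp = np.linspace(-0.5, 0.5, n_cp)
    cd = np.linspace(-cd_range, cd_range, n_cd)
    cpg, cdg = np.meshgrid(cp, cd, indexing="ij")
    return cpg.ravel(), cdg.ravel()


def _batch_objective(f_khz, bps, w, cp_nodes, cd_nodes, chunk=256):
    """Objective of every curve (rows) at every grid node (columns)."""
    B, n = bps.shape
    out = np.empty((B, cp_nodes.size))
    for lo in range(0, B, chunk):
        hi = min(lo + chunk, B)
        acc = np.zeros((hi - lo, cp_nodes.size))
        for i in range(n):
            pred = cp_nodes[None, :] + cd_nodes[None, :] * f_khz[lo:hi, i, None]
            acc += w[lo:hi, i, None] * 0.5 * (
                1.0 - np.cos(2.0 * np.pi * (bps[lo:hi, i, None] - pred))
            )
        out[lo:hi] = acc
    return out


def _eval_E_g_H(f_khz, bps, w, cp, cd):
    """Objective, gradient and Hessian at (cp, cd), vectorized over rows."""
    u = 2.0 * np.pi * (bps - cp[:, None] - cd[:, None] * f_khz)
    cu, su = np.cos(u), np.sin(u)
    E = np.sum(w * 0.5 * (1.0 - cu), axis=1)
    g_cp = -np.pi * np.sum(w * su, axis=1)
    g_cd = -np.pi * np.sum(w * f_khz * su, axis=1)
    tp2 = 2.0 * np.pi**2
    h00 = tp2 * np.sum(w * cu, axis=1)
    h01 = tp2 * np.sum(w * f_khz * cu, axis=1)
    h11 = tp2 * np.sum(w * f_khz**2 * cu, axis=1)
    return E, g_cp, g_cd, h00, h01, h11


def _eval_E(f_khz, bps, w, cp, cd):
    u = 2.0 * np.pi * (bps - cp[:, None] - cd[:, None] * f_khz)
    return np.sum(w * 0.5 * (1.0 - np.cos(u)), axis=1)


def _refine_newton(f_khz, bps, w, cp0, cd0, max_iter=200, gtol=1e-10):
    """Damped (Levenberg-style) Newton descent from (cp0, cd0), per row.

    Never returns a point worse than the start; terminates on gradient
    norm < gtol or objective improvement < 1e-14.
    """
    cp, cd = cp0.copy(), cd0.copy()
    lam = np.full(cp.shape, 1e-8)
    E = _eval_E(f_khz, bps, w, cp, cd)
    for _ in range(max_iter):
        E, gcp, gcd, h00, h01, h11 = _eval_E_g_H(f_khz, bps, w, cp, cd)
        gnorm = np.hypot(gcp, gcd)
        active = gnorm >= gtol
        if not np.any(active):
            break
        a = h00 + lam
        c = h11 + lam
        det = a * c - h01**2
        bad = (det <= 0) | (a <= 0)
        det = np.where(bad, 1.0, det)
        dcp = -(c * gcp - h01 * gcd) / det
        dcd = -(a * gcd - h01 * gcp) / det
        # fall back to a scaled gradient step where the model is not convex
        scale = np.maximum(np.abs(h00) + np.abs(h11), 1.0)
        dcp = np.where(bad, -gcp / scale, dcp)
        dcd = np.where(bad, -gcd / scale, dcd)
        E_new = _eval_E(f_khz, bps, w, cp + dcp, cd + dcd)
        improved = (E_new <= E) & active
        cp = np.where(improved, cp + dcp, cp)
        cd = np.where(improved, cd + dcd, cd)
        lam = np.where(improved, lam / 3.0, np.where(active, lam * 10.0, lam))
        lam = np.clip(lam, 1e-12, 1e8)
        stalled = improved & (E - E_new < 1e-14)
        E = np.where(improved, E_new, E)
        if np.all(~active | stalled):
            break
    return cp, cd, E


def _fit_batch(
    f_khz,
    bps,
    w,
    cp_step=DEFAULT_CP_STEP,
    cd_step=DEFAULT_CD_STEP,
    cd_range=DEFAULT_CD_RANGE,
):
    """Grid scan + Newton refinement for a batch of curves.

    Parameters are (B, n) arrays; returns wrapped cp (cycles), cd (ms)
    and the final objective per row.  Grid ties are broken toward the
    smallest |cd| then smallest |cp|.
    """
    f_khz = np.atleast_2d(np.asarray(f_khz, dtype=float))
    bps = np.atleast_2d(np.asarray(bps, dtype=float))
    w = np.atleast_2d(np.asarray(w, dtype=float))
    cp_nodes, cd_nodes = _grid_nodes(cp_step, cd_step, cd_range)
    E_grid = _batch_objective(f_khz, bps, w, cp_nodes, cd_nodes)
    # tie-break: sort node order by (|cd|, |cp|) and take the first argmin
    order = np.lexsort((np.abs(cp_nodes), np.abs(cd_nodes)))
    best = order[np.argmin(E_grid[:, order], axis=1)]
    cp0, cd0 = cp_nodes[best], cd_nodes[best]
    E0 = E_grid[np.arange(bps.shape[0]), best]
    cp, cd, E = _refine_newton(f_khz, bps, w, cp0, cd0)
    # refinement never worsens the grid optimum
    worse = E > E0
    cp = np.where(worse, cp0, cp)
    cd = np.where(worse, cd0, cd)
    E = np.where(worse, E0, E)
    return wrap_phase(cp), cd, E


def fit_phase_line(freqs_hz, phases, weights=None, **grid_kw):
    """Circular-linear fit of ``phases`` (cycles) on ``freqs_hz``.

    Low-level entry point shared by cell fits, acoustical band fits and
    pseudobinaural pair fits.  Returns ``(cp_cycles, cd_ms, objective)``.
    """
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    phases = np.asarray(phases, dtype=float)
    if weights is None:
        weights = np.ones_like(phases)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    if not np.any(weights > 0):
        raise InsufficientDataError("all regression weights are zero")
    cp, cd, E = _fit_batch(
        freqs_hz[None, :] / 1000.0, phases[None, :], weights[None, :], **grid_kw
    )
    return float(cp[0]), float(cd[0]), float(E[0])


def residual_error(curve: PhaseFrequencyCurve, fit: CPCDFit) -> float:
    """Unweighted mean circular distance between BP(f) and the fitted line.

    0 means a perfect fit, 1 that every point is antiphase to the line.
    """
    pred = fit.cp + fit.cd * (curve.freqs / 1000.0)
    return float(np.mean(circular_distance(curve.bps, pred)))


def fit_cpcd(
    curve: PhaseFrequencyCurve,
    grid_cp_step: float = DEFAULT_CP_STEP,
    grid_cd_step: float = DEFAULT_CD_STEP,
    linearity_surrogates: int | None = None,
    seed: int | None = None,
) -> CPCDFit:
    """Fit CP and CD to a cell's phase-frequency curve.

    Deterministic given the curve and grid settings.  If
    ``linearity_surrogates`` is given, a surrogate linearity p-value is
    attached (see :func:`linearity_significance`).

    Raises
    ------
    InsufficientDataError
        If the curve has no positive weight.
    """
    cp, cd, E = fit_phase_line(
        curve.freqs,
        curve.bps,
        curve.srs,
        cp_step=grid_cp_step,
        cd_step=grid_cd_step,
    )
    fit = CPCDFit(
        cp=cp, cd=cd, residual=np.nan, linearity_p=None,
        n_points=int(curve.freqs.size), objective=E,
    )
    fit.residual = residual_error(curve, fit)
    if linearity_surrogates is not None:
        fit.linearity_p = linearity_significance(
            fit.n_points, fit.residual, n_surrogates=linearity_surrogates,
            seed=seed,
        )
    return fit


# ---------------------------------------------------------------------------
# linearity significance (surrogate test)

def _canonical_freqs(n_points: int) -> np.ndarray:
    # The null distribution of the residual depends essentially only on the
    # number of points; a fixed span stands in for the per-cell frequency set.
    return np.linspace(300.0, 3000.0, n_points)


def null_residual_bank(
    n_points: int,
    n_surrogates: int = 9999,
    seed: int | None = None,
    freqs_hz: np.ndarray | None = None,
) -> np.ndarray:
    """Residuals of circular-linear fits to uniform-BP surrogate curves.

    Each surrogate draws ``n_points`` best phases uniformly on
    ``[-0.5, 0.5)``, fits the wrapped line with uniform weights and records
    the unweighted residual.  The bank can be shared across cells with the
    same number of points, which is what makes large calibration runs
    affordable.
    """
    if n_points < MIN_POINTS:
        raise InsufficientDataError("surrogate curves need at least 5 points")
    rng = np.random.default_rng(seed)
    if freqs_hz is None:
        freqs_hz = _canonical_freqs(n_points)
    f_khz = np.broadcast_to(
        np.asarray(freqs_hz, float)[None, :] / 1000.0, (n_surrogates, n_points)
    )
    bps = rng.uniform(-0.5, 0.5, size=(n_surrogates, n_points))
    w = np.ones_like(bps)
    cp, cd, _ = _fit_batch(f_khz, bps, w)
    pred = cp[:, None] + cd[:, None] * f_khz
    return np.mean(circular_distance(bps, pred), axis=1)


def linearity_significance(
    n_points: int,
    observed_residual: float,
    n_surrogates: int = 9999,
    seed: int | None = None,
    bank: np.ndarray | None = None,
) -> float:
    """Surrogate p-value for the linearity of a phase-frequency curve.

    The null hypothesis is that best phases are uniformly distributed; the
    test statistic is the fit residual.  ``p = (1 + #{r_surr <= r_obs}) /
    (n_surrogates + 1)``, with resolution ``1/(n_surrogates + 1)``.  Pass a
    precomputed ``bank`` (from :func:`null_residual_bank`) to score many
    cells with equal ``n_points`` against shared surrogates.
    """
    if bank is None:
        bank = null_residual_bank(n_points, n_surrogates, seed)
    k = int(np.count_nonzero(bank <= observed_residual))
    return (1 + k) / (bank.size + 1)


# ---------------------------------------------------------------------------
# best ITD

def best_itd_per_freq(
    curve: PhaseFrequencyCurve, cd_hint_ms: float | None = None
) -> np.ndarray:
    """Best ITD (microseconds) at each frequency from the best phase.

    The BP at frequency f maps to the family of delays ``(bp + k)/f`` for
    integer cycle counts k.  By default the candidate of minimal |ITD| is
    reported; with ``cd_hint_ms`` the candidate closest to the cell-level
    characteristic delay is chosen instead.
    """
    target_us = 0.0 if cd_hint_ms is None else cd_hint_ms * 1000.0
    ks = np.arange(-4, 5)
    cand = (curve.bps[:, None] + ks[None, :]) / curve.freqs[:, None] * 1e6
    idx = np.argmin(np.abs(cand - target_us), axis=1)
    return cand[np.arange(curve.freqs.size), idx]


def best_itd_range(
    curve: PhaseFrequencyCurve,
    best_itds_us: np.ndarray,
    threshold_frac: float = 0.8,
) -> float:
    """Spread of best ITD over the well-driven part of the curve.

    Only frequencies whose sync-rate reaches ``threshold_frac`` of the
    maximum contribute; the range is max minus min best ITD (microseconds,
    nonnegative).  The maximum-SR point always passes, so the range is
    always defined.
    """
    best_itds_us = np.asarray(best_itds_us, dtype=float)
    if best_itds_us.size != curve.freqs.size:
        raise ValueError("best_itds must align with curve frequencies")
    keep = curve.srs >= threshold_frac * np.max(curve.srs)
    sel = best_itds_us[keep]
    return float(sel.max() - sel.min())
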