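"""Seeded generators of model cells, model fibers and model IPD sets.

These generators stand in for animal recordings: they produce inputs with
the statistical structure the analysis assumes, under explicit seeds, so
every pipeline stage can be exercised and calibrated.

Model IC cell
    Best phase is linear in frequency, ``BP(f) = wrap(cp + cd * f)``,
    with spikes drawn from a von Mises-modulated Poisson process locked to
    the beat period.  The von Mises concentration is solved numerically so
    the resultant length of the spike phases equals the requested vector
    strength; the discharge rate follows a log-frequency tuning profile
    and phase locking rolls off logistically at high frequency.

Model auditory-nerve fiber
    Spikes are locked to the tone with mean phase given by a
    traveling-wave-like cochlear phase function: the accumulated phase lag
    at frequency f for a fiber of characteristic frequency cf is

        phi(f; cf) = -n_cycles * (f / cf)**gamma      (cycles)

    i.e. the lag reaches ``n_cycles`` at CF and grows super-linearly in f
    (``gamma > 1``), so for a fixed tone the more apical (lower-CF) fiber
    is delayed and phase-lagged — the cochlear disparity that drives the
    pseudobinaural analysis.  Firing rate follows a rounded-exponential
    tuning curve around CF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from itdfreq.circstats import BeatResponse, wrap_phase
from itdfreq.coincidence import FiberResponseSet
from itdfreq.cpcd import PhaseFrequencyCurve

__all__ = [
    "ModelCellSpec",
    "ModelFiberSpec",
    "vs_to_kappa",
    "default_cell_freqs",
    "generate_cell_responses",
    "generate_phase_curve",
    "draw_cell_params",
    "pair_tone_freqs",
    "generate_fiber_responses",
    "generate_ipd_set",
]

MAX_KAPPA = 500.0


def vs_to_kappa(vs: float) -> float:
    """Von Mises concentration whose mean resultant length equals ``vs``.

    Inverts ``A(kappa) = I1(kappa) / I0(kappa)`` numerically; requests of
    vs >= A(500) (~0.999) are capped at kappa = 500.
    """
    if not 0.0 <= vs <= 1.0:
        raise ValueError("vector strength must lie in [0, 1]")
    if vs == 0.0:
        return 0.0
    cap = i1e(MAX_KAPPA) / i0e(MAX_KAPPA)
    if vs >= cap:
        return MAX_KAPPA
    return brentq(lambda k: i1e(k) / i0e(k) - vs, 1e-9, MAX_KAPPA)


def _locked_spikes(rng, rate, duration, freq, mean_phase, vs):
    """One repetition of a periodic von Mises-modulated Poisson train.

    The spike count is Poisson with mean ``rate * duration``; each spike
    phase is von Mises around ``mean_phase`` (cycles) with concentration
    matching ``vs`` and lands in a uniformly chosen stimulus cycle.
    """
    n_cycles = int(np.floor(duration * freq))
    if n_cycles < 1:
        raise ValueError("duration must cover at least one stimulus cycle")
    n = rng.poisson(rate * duration)
    if n == 0:
        return np.empty(0)
    kappa = vs_to_kappa(vs)
    if kappa == 0.0:
        phases = rng.uniform(0.0, 1.0, n)
    else:
        phases = (rng.vonmises(2.0 * np.pi * mean_phase, kappa, n)
                  / (2.0 * np.pi)) % 1.0
    cycles = rng.integers(0, n_cycles, n)
    return np.sort((cycles + phases) / freq)


def default_cell_freqs(n: int = 9) -> np.ndarray:
    """Default tested tone frequencies: log-spaced over 100-3000 Hz.

    Binaural-beat protocols probe the full phase-locked range of a cell;
    the span matches the 300-3000 Hz population CF range with tones
    extending below CF.
    """
    return np.geomspace(100.0, 3000.0, n)


def _default_rate_profile(bf: float) -> Callable[[float], float]:
    # log-frequency Gaussian around best frequency, 1.5-octave SD, 5 sp/s floor
    def rate(f):
        return 5.0 + 55.0 * np.exp(-0.5 * (np.log2(f / bf) / 1.5) ** 2)

    return rate


def _ic_vs_profile(f: float) -> float:
    # logistic phase-locking rolloff of midbrain cells above ~1.8 kHz
    return 0.7 / (1.0 + np.exp((f - 1800.0) / 350.0))


@dataclass
class ModelCellSpec:
    """Generative parameters of one model IC cell."""

    cell_id: str
    cp: float  # cycles
    cd: float  # ms
    cf: float = 1000.0  # Hz
    freqs: np.ndarray = field(default_factory=default_cell_freqs)
    duration: float = 5.0  # s
    n_reps: int = 10
    beat_freq: float = 1.0  # Hz
    level_db: float = 70.0
    rate_profile: Callable[[float], float] | None = None
    vs_profile: Callable[[float], float] = _ic_vs_profile
    seed: int | None = None

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.size < 5:
            raise ValueError("at least 5 tested frequencies required")
        if self.rate_profile is None:
            self.rate_profile = _default_rate_profile(self.cf)


def generate_cell_responses(spec: ModelCellSpec) -> list[BeatResponse]:
    """Binaural-beat responses of a model cell, one per tone frequency.

    At tone frequency f the spikes lock to the beat period with mean
    phase ``wrap(cp + cd * f)`` (cd in ms, f in kHz) and vector strength
    ``vs_profile(f)``; the rate follows ``rate_profile(f)`` within Poisson
    error.  Bit-reproducible given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    for f in spec.freqs:
        mu = wrap_phase(spec.cp + spec.cd * f / 1000.0)
        vs = min(float(spec.vs_profile(f)), 1.0 - 1e-9)
        rate = float(spec.rate_profile(f))
        reps, times = [], []
        for r in range(spec.n_reps):
            t = _locked_spikes(rng, rate, spec.duration, spec.beat_freq, mu, vs)
            times.append(t)
            reps.append(np.full(t.size, r))
        out.append(
            BeatResponse(
                cell_id=spec.cell_id,
                tone_freq=float(f),
                beat_freq=spec.beat_freq,
                beat_sign=1,
                duration=spec.duration,
                n_reps=spec.n_reps,
                spikes=np.concatenate(times),
                reps=np.concatenate(reps),
                level_db=spec.level_db,
            )
        )
    return out


def generate_phase_curve(
    cell_id: str,
    cp: float,
    cd: float,
    freqs=None,
    noise_sigma: float = 0.05,
    seed: int | None = None,
) -> PhaseFrequencyCurve:
    """Phase-frequency curve with wrapped-normal BP noise, unit weights.

    A lightweight curve-level generator (no spikes) for estimator
    calibration: ``bp(f) = wrap(cp + cd * f + N(0, noise_sigma))``.
    """
    rng = np.random.default_rng(seed)
    freqs = default_cell_freqs() if freqs is None else np.asarray(freqs, float)
    bps = wrap_phase(
        cp + cd * freqs / 1000.0 + rng.normal(0.0, noise_sigma, freqs.size)
    )
    return PhaseFrequencyCurve(cell_id, freqs, bps, np.ones(freqs.size))


def draw_cell_params(n: int, seed: int | None = None):
    """Draw (cp, cd) pairs over the observed ranges: cp uniform on
    [-0.5, 0.5) cycles, cd uniform on [-1, 1] ms."""
    rng = np.random.default_rng(seed)
    return rng.uniform(-0.5, 0.5, n), rng.uniform(-1.0, 1.0, n)


# ---------------------------------------------------------------------------
# model auditory-nerve fibers

def _an_vs_profile(f: float) -> float:
    # nerve phase locking extends higher than in midbrain cells
    return 0.8 / (1.0 + np.exp((f - 2800.0) / 500.0))


@dataclass
class ModelFiberSpec:
    """Generative parameters of one model auditory-nerve fiber."""

    fiber_id: str
    cf: float  # Hz
    n_cycles_at_cf: float = 3.0  # accumulated phase lag at CF, cycles
    phase_exponent: float = 2.0  # >1: lag accelerates with frequency
    max_rate: float = 150.0  # sp/s at CF
    spont_rate: float = 10.0  # sp/s
    roex_p: float = 6.0  # excitation-pattern sharpness (suprathreshold)
    vs_profile: Callable[[float], float] = _an_vs_profile
    seed: int | None = None

    def phase(self, f) -> np.ndarray:
        """Cochlear phase (cycles) of this fiber at tone frequency f.

        Monotonic in cf at fixed f: apical (lower-CF) fibers lag.
        """
        return -self.n_cycles_at_cf * (np.asarray(f, float) / self.cf) ** self.phase_exponent

    def tuning(self, f) -> np.ndarray:
        """Rounded-exponential tuning weight in [0, 1]."""
        g = self.roex_p * np.abs(np.asarray(f, float) - self.cf) / self.cf
        return (1.0 + g) * np.exp(-g)

    def rate(self, f) -> np.ndarray:
        return self.spont_rate + (self.max_rate - self.spont_rate) * self.tuning(f)


def pair_tone_freqs(
    cf_a: float, cf_b: float, n: int = 9, span_oct: float = 0.75,
    max_freq: float = 3400.0,
) -> np.ndarray:
    """Tone frequencies probing a fiber pair: log-spaced around the pair's
    geometric-mean CF, ``span_oct`` octaves to each side (clipped above)."""
    cfm = np.sqrt(cf_a * cf_b)
    return np.geomspace(cfm / 2**span_oct, min(cfm * 2**span_oct, max_freq), n)


def generate_fiber_responses(
    spec: ModelFiberSpec,
    tone_freqs,
    duration: float = 5.0,
    n_reps: int = 10,
    seed: int | None = None,
) -> FiberResponseSet:
    """Tone responses of a model fiber at each requested frequency.

    Spikes lock to the tone with mean phase ``spec.phase(f)`` and vector
    strength ``spec.vs_profile(f)``; the rate follows the tuning curve.
    Tones driving less than 1% of the tuning peak yield unlocked
    spontaneous activity only.  Identical (spec, seed) inputs reproduce
    identical trains.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    responses = {}
    for f in np.asarray(tone_freqs, dtype=float):
        driven = spec.tuning(f) >= 0.01
        rate = float(spec.rate(f)) if driven else spec.spont_rate
        vs = float(spec.vs_profile(f)) if driven else 0.0
        mu = float(wrap_phase(spec.phase(f))) if driven else 0.0
        responses[float(f)] = [
            _locked_spikes(rng, rate, duration, f, mu, vs)
            for _ in range(n_reps)
        ]
    return FiberResponseSet(
        fiber_id=spec.fiber_id, cf=spec.cf, duration=duration,
        responses=responses,
    )


# ---------------------------------------------------------------------------
# model IPD sets

def generate_ipd_set(model: str, **params):
    """Model IPD spectra for acoustics tests.

    Parameters
    ----------
    model : str
        ``"affine"`` (``cp`` cycles + ``cd_ms`` slope), ``"pure_delay"``
        (``tau_s``), ``"sphere"`` or ``"sphere+ground"`` (computed from
        the head model; accepts ``azimuths`` in degrees plus optional
        ``head`` :class:`~itdfreq.acoustics.HeadModelConfig` and
        ``ground`` :class:`~itdfreq.acoustics.GroundConfig`).
    params
        ``freqs`` overrides the dense default grid.

    Returns
    -------
    list of IPDSpectrum
    """
    from itdfreq import acoustics as ac

    freqs = params.get("freqs")
    if freqs is None:
        freqs = ac.default_freq_grid()
    freqs = np.asarray(freqs, dtype=float)

    if model == "affine":
        ipd = params["cp"] + params["cd_ms"] * freqs / 1000.0
        return [ac.IPDSpectrum(azimuth=params.get("azimuth", 0.0),
                               freqs=freqs, ipd=ipd)]
    if model == "pure_delay":
        ipd = params["tau_s"] * freqs
        return [ac.IPDSpectrum(azimuth=params.get("azimuth", 0.0),
                               freqs=freqs, ipd=ipd)]
    if model in ("sphere", "sphere+ground"):
        azimuths = np.atleast_1d(params.get("azimuths", [45.0]))
        head = params.get("head", ac.HeadModelConfig())
        ground = params.get("ground", ac.GroundConfig())
        specs = []
        for az in azimuths:
            cfg = ac.HeadModelConfig(
                head_diameter=head.head_diameter,
                ear_azimuth=head.ear_azimuth,
                speed_of_sound=head.speed_of_sound,
                source_distance=head.source_distance,
                source_azimuth=float(az),
                max_order=head.max_order,
            )
            gains = ac.sphere_hrtf(cfg, freqs)
            if model == "sphere+ground":
                gains = ac.add_ground_reflection(gains, cfg, ground, freqs)
            specs.append(ac.ipd_spectrum(gains, freqs, float(az)))
        return specs
    raise ValueError(f"unknown IPD model {model!r}")
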