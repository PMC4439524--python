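"""Circular statistics of phase-locked spike trains.

Spikes recorded under a binaural-beat stimulus sweep the interaural phase
once per beat period.  All phase statistics here are computed on spike
times reduced modulo the beat period and expressed in *cycles* (1 cycle =
2*pi radians).  Best phase (BP) is wrapped to ``[-0.5, 0.5)`` cycles, with
positive BP meaning contralateral-leading; responses recorded with the
opposite beat direction (``beat_sign == -1``) are sign-flipped before
pooling so the convention is uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from itdfreq.exceptions import EmptyResponseError, InsufficientDataError

__all__ = [
    "BeatResponse",
    "PhasePointStats",
    "wrap_phase",
    "circular_distance",
    "period_histogram",
    "phase_point_stats",
    "rayleigh_p",
    "screen_points",
]


def wrap_phase(x):
    """Wrap phase(s) in cycles to the interval ``[-0.5, 0.5)``."""
    return (np.asarray(x) + 0.5) % 1.0 - 0.5


def circular_distance(x, y):
    """Circular distance between phases ``x`` and ``y`` (cycles).

    ``d(x, y) = (1 - cos(2 pi (x - y))) / 2`` ranges from 0 (equal phase,
    mod 1) to 1 (antiphase), is symmetric and 1-periodic in each argument.
    """
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * (np.asarray(x) - np.asarray(y))))


@dataclass
class BeatResponse:
    """Spike response of one cell to one binaural-beat tone.

    Parameters
    ----------
    cell_id : str
        Identifier of the recorded cell.
    tone_freq : float
        Carrier tone frequency, Hz.
    beat_freq : float
        Beat frequency (difference between the two ears' tones), Hz.
    beat_sign : int
        +1 if the contralateral ear carried the higher frequency, -1
        otherwise.
    duration : float
        Stimulus duration, s.
    n_reps : int
        Number of stimulus repetitions pooled in ``spikes``.
    spikes : ndarray
        Spike times in seconds, pooled over repetitions, each in
        ``[0, duration]``.
    reps : ndarray, optional
        Repetition index of each spike (for file round-trips); zeros if
        not provided.
    level_db : float
        Sound level, dB SPL.
    """

    cell_id: str
    tone_freq: float
    beat_freq: float
    beat_sign: int = 1
    duration: float = 5.0
    n_reps: int = 1
    spikes: np.ndarray = field(default_factory=lambda: np.empty(0))
    reps: np.ndarray | None = None
    level_db: float = 70.0

    def __post_init__(self):
        self.spikes = np.asarray(self.spikes, dtype=float)
        if self.tone_freq <= 0 or self.beat_freq <= 0:
            raise ValueError("tone_freq and beat_freq must be positive")
        if self.spikes.size and (
            self.spikes.min() < 0 or self.spikes.max() > self.duration
        ):
            raise ValueError("spike times must lie within [0, duration]")
        if self.reps is None:
            self.reps = np.zeros(self.spikes.size, dtype=int)
        else:
            self.reps = np.asarray(self.reps, dtype=int)

    def beat_phases(self, discard_first_cycle: bool = False) -> np.ndarray:
        """Spike phases relative to the beat period, in ``[0, 1)`` cycles.

        With ``discard_first_cycle`` the response to the entire first beat
        cycle is dropped (used when a strong onset component is present).
        """
        t = self.spikes
        if discard_first_cycle:
            t = t[t >= 1.0 / self.beat_freq]
        return (t * self.beat_freq) % 1.0


@dataclass
class PhasePointStats:
    """Phase-locking statistics of one cell at one tone frequency."""

    tone_freq: float
    vs: float
    bp: float
    rate: float
    sr: float
    rayleigh_p: float
    n_spikes: int


def period_histogram(
    resp: BeatResponse, n_bins: int = 64, discard_first_cycle: bool = False
) -> np.ndarray:
    """Period histogram of spike phases over the beat cycle.

    Returns the spike count in each of ``n_bins`` equal phase bins of the
    beat period.  Counts sum to the number of retained spikes.

    Raises
    ------
    EmptyResponseError
        If no spike remains after the optional first-cycle discard.
    """
    if n_bins < 4:
        raise ValueError("n_bins must be at least 4")
    phases = resp.beat_phases(discard_first_cycle)
    if phases.size == 0:
        raise EmptyResponseError(
            f"cell {resp.cell_id} at {resp.tone_freq} Hz has no retained spikes"
        )
    counts, _ = np.histogram(phases, bins=n_bins, range=(0.0, 1.0))
    return counts


def rayleigh_p(n: int, vs: float) -> float:
    """Rayleigh test p-value for uniformity of ``n`` phases with vector
    strength ``vs``.

    Uses the standard approximation ``p ~ exp(-Z)`` with Zar's finite-n
    correction, ``Z = n vs^2``:

    ``p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n))``, ``R = n vs``.
    """
    n = float(n)
    r = n * vs
    arg = 1.0 + 4.0 * n + 4.0 * (n * n - r * r)
    p = np.exp(np.sqrt(max(arg, 0.0)) - (1.0 + 2.0 * n))
    return float(min(max(p, 0.0), 1.0))


def phase_point_stats(
    resp: BeatResponse, discard_first_cycle: bool = False
) -> PhasePointStats:
    """Vector strength, best phase, rate, sync-rate and Rayleigh p.

    The mean vector of the spike phases has length equal to the vector
    strength (VS) and angle equal to the best phase (BP, cycles, wrapped
    to ``[-0.5, 0.5)``).  The sync-rate SR is the product of discharge
    rate and VS and serves as the regression weight downstream.  BP is
    sign-flipped for negative-beat recordings so that positive BP always
    means contralateral-leading.

    Raises
    ------
    InsufficientDataError
        If fewer than 2 spikes are retained.
    """
    phases = resp.beat_phases(discard_first_cycle)
    n = phases.size
    if n < 2:
        raise InsufficientDataError(
            f"cell {resp.cell_id} at {resp.tone_freq} Hz: {n} spike(s) retained"
        )
    z = np.exp(2j * np.pi * phases).mean()
    vs = float(np.abs(z))
    bp = float(np.angle(z)) / (2.0 * np.pi)
    if resp.beat_sign < 0:
        bp = -bp
    bp = float(wrap_phase(bp))
    total_time = resp.duration * resp.n_reps
    if discard_first_cycle:
        total_time = max(total_time - resp.n_reps / resp.beat_freq, 0.0)
    rate = n / total_time if total_time > 0 else np.nan
    return PhasePointStats(
        tone_freq=resp.tone_freq,
        vs=vs,
        bp=bp,
        rate=rate,
        sr=rate * vs,
        rayleigh_p=rayleigh_p(n, vs),
        n_spikes=int(n),
    )


def screen_points(
    points: list[PhasePointStats], alpha: float = 0.001
) -> list[PhasePointStats]:
    """Keep only points whose Rayleigh test rejects uniformity at ``alpha``.

    Order is preserved; the result may be empty.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return [p for p in points if p.rayleigh_p < alpha]
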