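"""Pseudobinaural coincidence detection between pairs of nerve fibers.

A model binaural neuron is built from two monaural phase-locked fibers by
counting near-coincident spikes while one train is shifted by an internal
delay.  Sweeping the delay produces an ITD tuning curve per tone
frequency; the best phase extracted from each curve feeds the same CP/CD
analysis used for real binaural cells, so that mistuning between the two
fibers' characteristic frequencies (CFs) translates into frequency-
dependent best delays.

Coincidences are defined on continuous spike times: a pair (t_a, t_b)
coincides at delay d if ``|t_a - (t_b + d)| <= bin/2`` (window
coincidence; equals histogram-bin counting in expectation and is
shift-invariant).  Repetitions are paired same-index only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from itdfreq.circstats import wrap_phase
from itdfreq.cpcd import fit_phase_line
from itdfreq.exceptions import InsufficientDataError, UndefinedStatisticError

__all__ = [
    "FiberResponseSet",
    "CoincidenceCurve",
    "PairCPCD",
    "default_delays",
    "count_coincidences",
    "pseudobinaural_curves",
    "bp_from_curve",
    "pair_cpcd",
    "population_analysis",
]

DEFAULT_BIN = 50e-6  # s
DEFAULT_DELAY_SPAN = 2e-3  # s
MISMATCH_LIMIT_OCT = 0.1
CF_LIMIT_HZ = 3300.0


@dataclass
class FiberResponseSet:
    """Spike responses of one auditory-nerve fiber to a set of pure tones.

    ``responses`` maps tone frequency (Hz) to a list of per-repetition
    spike-time arrays (s).
    """

    fiber_id: str
    cf: float
    duration: float
    responses: dict[float, list[np.ndarray]] = field(default_factory=dict)

    @property
    def tone_freqs(self) -> np.ndarray:
        return np.array(sorted(self.responses))


@dataclass
class CoincidenceCurve:
    """Coincidence counts vs internal delay for one pair at one tone."""

    tone_freq: float
    delays: np.ndarray  # s, uniform grid symmetric about 0
    counts: np.ndarray  # nonnegative ints

    def __post_init__(self):
        self.delays = np.asarray(self.delays, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")


@dataclass
class PairCPCD:
    """CP/CD of a pseudobinaural coincidence detector built from a pair."""

    pair_id: str
    cf_a: float
    cf_b: float
    mismatch: float  # octaves, log2(cf_b / cf_a)
    cp: float  # cycles
    cd: float  # ms


def default_delays(
    span: float = DEFAULT_DELAY_SPAN, step: float = DEFAULT_BIN
) -> np.ndarray:
    """Symmetric internal-delay grid, step equal to the bin width."""
    n = int(round(span / step))
    return np.arange(-n, n + 1) * step


def count_coincidences(spikes_a, spikes_b, delay: float, bin: float = DEFAULT_BIN):
    """Number of spike pairs coincident within ``bin`` at internal delay.

    Counts pairs with ``|t_a - (t_b + delay)| <= bin/2`` via a sorted
    sweep; equivalent to the brute-force double loop over all pairs.
    """
    if bin <= 0:
        raise ValueError("bin width must be positive")
    a = np.sort(np.asarray(spikes_a, dtype=float))
    b = np.sort(np.asarray(spikes_b, dtype=float)) + delay
    lo = np.searchsorted(b, a - bin / 2.0, side="left")
    hi = np.searchsorted(b, a + bin / 2.0, side="right")
    return int(np.sum(hi - lo))


def _counts_over_delays(reps_a, reps_b, delays, bin):
    """Coincidence counts at every delay, same-index repetition pairing."""
    delays = np.asarray(delays, dtype=float)
    counts = np.zeros(delays.size, dtype=int)
    for ta, tb in zip(reps_a, reps_b):
        ta = np.sort(np.asarray(ta, dtype=float))
        tb = np.sort(np.asarray(tb, dtype=float))
        if ta.size == 0 or tb.size == 0:
            continue
        edges_lo = (ta[:, None] - delays[None, :] - bin / 2.0).ravel(order="F")
        edges_hi = (ta[:, None] - delays[None, :] + bin / 2.0).ravel(order="F")
        lo = np.searchsorted(tb, edges_lo, side="left")
        hi = np.searchsorted(tb, edges_hi, side="right")
        counts += (hi - lo).reshape(delays.size, ta.size).sum(axis=1)
    return counts


def pseudobinaural_curves(
    fiber_a: FiberResponseSet,
    fiber_b: FiberResponseSet,
    delays=None,
    bin: float = DEFAULT_BIN,
) -> list[CoincidenceCurve]:
    """Coincidence-vs-delay curves for every tone frequency shared by a pair.

    The delay applies to fiber B's spikes (positive delay = B shifted
    later).  For strongly phase-locked inputs each curve is periodic with
    period ~ 1/tone frequency.

    Raises
    ------
    InsufficientDataError
        If the fibers share no tone frequency.
    """
    if delays is None:
        delays = default_delays(step=bin)
    shared = sorted(set(fiber_a.responses) & set(fiber_b.responses))
    if not shared:
        raise InsufficientDataError(
            f"fibers {fiber_a.fiber_id}/{fiber_b.fiber_id} share no tone"
        )
    curves = []
    for f in shared:
        counts = _counts_over_delays(
            fiber_a.responses[f], fiber_b.responses[f], delays, bin
        )
        curves.append(CoincidenceCurve(tone_freq=f, delays=np.asarray(delays),
                                       counts=counts))
    return curves


def bp_from_curve(curve: CoincidenceCurve, mode: str = "circmean") -> float:
    """Best phase (cycles) of a coincidence curve.

    The delay axis is mapped to phase ``delay * tone_freq``; the BP is the
    count-weighted circular mean of those phases (robust at the coarse
    50 us delay grid), or the phase of the peak delay with
    ``mode="argmax"``.  For a unimodal periodic curve both reduce to the
    peak location.  Before the circular mean, the delay window is trimmed
    to a whole number of stimulus periods (centered), removing the bias a
    partial period would add for periodic curves.

    Raises
    ------
    UndefinedStatisticError
        For all-zero counts or a near-zero circular resultant (flat
        curve).
    """
    c = curve.counts.astype(float)
    if not np.any(c > 0):
        raise UndefinedStatisticError("all-zero coincidence counts")
    if mode == "argmax":
        return float(wrap_phase(curve.delays[np.argmax(c)] * curve.tone_freq))
    if mode != "circmean":
        raise ValueError(f"unknown mode {mode!r}")
    d = curve.delays
    step = d[1] - d[0] if d.size > 1 else 0.0
    span = d[-1] - d[0] + step
    n_per = int(np.floor(span * curve.tone_freq))
    if n_per < 1:
        raise UndefinedStatisticError("delay grid shorter than one period")
    if step > 0:
        n_keep = int(round(n_per / (curve.tone_freq * step)))
        lo = (d.size - n_keep) // 2
        d = d[lo : lo + n_keep]
        c = c[lo : lo + n_keep]
    z = np.sum(c * np.exp(2j * np.pi * d * curve.tone_freq))
    if np.abs(z) < 0.02 * c.sum():
        raise UndefinedStatisticError("flat coincidence curve: BP undefined")
    return float(wrap_phase(np.angle(z) / (2.0 * np.pi)))


def curve_modulation_p(curve: CoincidenceCurve) -> float:
    """Rayleigh-style significance of a coincidence curve's modulation.

    Treats the counts as phase samples at ``delay * tone_freq``: with
    resultant ratio ``vs = |sum c e^(2 pi i f d)| / sum c`` and n = total
    count, ``p ~ exp(-n vs^2)``.  Flat (noise-only) curves give p near 1;
    strongly modulated curves give vanishing p.  Used to screen tone
    frequencies before the pair CP/CD fit, mirroring the Rayleigh screen
    applied to cell data points.
    """
    c = curve.counts.astype(float)
    n = c.sum()
    if n <= 0:
        return 1.0
    z = np.sum(c * np.exp(2j * np.pi * curve.delays * curve.tone_freq))
    vs = np.abs(z) / n
    return float(np.exp(-min(n * vs * vs, 700.0)))


def pair_cpcd(
    fiber_a: FiberResponseSet,
    fiber_b: FiberResponseSet,
    delays=None,
    bin: float = DEFAULT_BIN,
    pair_id: str | None = None,
    screen_alpha: float = 0.001,
) -> PairCPCD:
    """CP and CD of the pseudobinaural detector built from two fibers.

    Tone frequencies whose coincidence curve shows no significant
    modulation (see :func:`curve_modulation_p`) are discarded; the
    remaining (tone frequency, BP) points are fit with the cell
    circular-linear regression, weighted by the total coincidence count
    at each frequency.

    Raises
    ------
    InsufficientDataError
        With fewer than 5 usable tone frequencies.
    """
    curves = pseudobinaural_curves(fiber_a, fiber_b, delays, bin)
    freqs, bps, weights = [], [], []
    for cv in curves:
        if curve_modulation_p(cv) >= screen_alpha:
            continue
        try:
            bp = bp_from_curve(cv)
        except UndefinedStatisticError:
            continue
        freqs.append(cv.tone_freq)
        bps.append(bp)
        weights.append(float(cv.counts.sum()))
    if len(freqs) < 5:
        raise InsufficientDataError(
            f"pair {fiber_a.fiber_id}/{fiber_b.fiber_id}: "
            f"{len(freqs)} usable tone frequencies (need 5)"
        )
    cp, cd, _ = fit_phase_line(np.array(freqs), np.array(bps), np.array(weights))
    return PairCPCD(
        pair_id=pair_id or f"{fiber_a.fiber_id}+{fiber_b.fiber_id}",
        cf_a=fiber_a.cf,
        cf_b=fiber_b.cf,
        mismatch=float(np.log2(fiber_b.cf / fiber_a.cf)),
        cp=cp,
        cd=cd,
    )


def population_analysis(
    pairs: list[PairCPCD],
    symmetrize: bool = True,
    max_mismatch_oct: float = MISMATCH_LIMIT_OCT,
    max_cf: float = CF_LIMIT_HZ,
) -> list[PairCPCD]:
    """Filter and optionally symmetrize a population of pair fits.

    Pairs with |CF mismatch| above ``max_mismatch_oct`` octaves or either
    CF at/above ``max_cf`` are excluded.  With ``symmetrize`` each
    retained pair appears twice, as (cp, cd) and (-cp, -cd) — emulating
    random assignment of the mistuned fiber to either ear — interleaved so
    the symmetrized CP and CD means are exactly zero.
    """
    kept = [
        p
        for p in pairs
        if abs(p.mismatch) <= max_mismatch_oct and p.cf_a < max_cf and p.cf_b < max_cf
    ]
    if not symmetrize:
        return kept
    out = []
    for p in kept:
        out.append(p)
        out.append(
            PairCPCD(
                pair_id=p.pair_id + "/mirrored",
                cf_a=p.cf_b,
                cf_b=p.cf_a,
                mismatch=-p.mismatch,
                cp=-p.cp,
                cd=-p.cd,
            )
        )
    return out
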