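"""Analytic spherical-head acoustics and frequency-dependent ITD metrics.

The head is modeled as a rigid sphere of diameter 7.3 cm (measured on a 3D
model of a cat) with point receivers (the ears) on its surface, placed
antipodally at +/-90 degrees on the horizontal great circle.  The pressure
at a receiver for a point source follows the classical partial-wave series
solution of the Helmholtz equation; an optional ground reflection is added
by the image-source method, with a frequency-dependent reflection
coefficient derived from a one-parameter (flow-resistivity) ground
impedance model.

From the two ear pressures the interaural phase difference (IPD, cycles)
is obtained, and from the IPD three frequency-dependent delay metrics:

- phase ITD   ``ITD_p(f) = <IPD(f)> / f``       (unwrapped phase / f),
- group ITD   ``ITD_g(f) = d IPD / d f``         (envelope delay),
- interaural diffraction index
  ``IDI(f) = f (ITD_p(f) - ITD_g(f))``           (cycles),

estimated by circular-linear regression of the IPD over a window of width
``f/4`` centered on each frequency, exactly as best phase is regressed on
frequency in cells.  Band-wise acoustical CP/CD uses the cell bandwidth
``BW(F) = F / Q(F)`` with ``Q(F) = 1.04 + 3.8e-4 * F``.

Sign convention (used everywhere in the package): the source azimuth is
positive on the ipsilateral side; a positive IPD/ITD means the
contralateral ear's signal lags, i.e. the ipsilateral ear leads in time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import eval_legendre, spherical_jn, spherical_yn

from itdfreq.circstats import circular_distance, wrap_phase
from itdfreq.cpcd import fit_phase_line
from itdfreq.exceptions import ConvergenceError, UndefinedStatisticError

__all__ = [
    "HeadModelConfig",
    "GroundConfig",
    "IPDSpectrum",
    "ItdMetrics",
    "AcousticalCPCD",
    "sphere_pressure",
    "sphere_hrtf",
    "ground_reflection_coefficient",
    "image_path_geometry",
    "extra_path_delay",
    "add_ground_reflection",
    "ipd_spectrum",
    "itd_metrics",
    "acoustical_cpcd",
    "q_factor",
    "best_azimuth",
    "default_freq_grid",
]

RHO_AIR = 1.2  # kg/m^3


@dataclass
class HeadModelConfig:
    """Geometry of the rigid-sphere head model.

    ``source_azimuth`` is in degrees, 0 = straight ahead, positive toward
    the ipsilateral ear (located at ``+ear_azimuth`` on the sphere).
    """

    head_diameter: float = 0.073  # m
    ear_azimuth: float = 90.0  # deg; ears at +/- this azimuth
    speed_of_sound: float = 343.0  # m/s (20 C)
    source_distance: float = 1.5  # m, from sphere center
    source_azimuth: float = 0.0  # deg
    max_order: int = 120

    def __post_init__(self):
        if self.head_diameter <= 0:
            raise ValueError("head diameter must be positive")
        if self.source_distance <= self.head_diameter / 2:
            raise ValueError("source must lie outside the sphere")

    @property
    def radius(self) -> float:
        return self.head_diameter / 2.0


@dataclass
class GroundConfig:
    """Image-source geometry and ground impedance.

    ``flow_resistivity`` is in Pa s m^-2 (SI); the default 5e5 lies
    between typical grass (~1e5) and sand (~1e6).
    """

    head_height: float = 0.20  # m
    source_height: float = 0.20  # m
    horizontal_distance: float = 1.5  # m
    flow_resistivity: float = 5e5  # Pa s / m^2; inf = rigid ground

    def __post_init__(self):
        if self.head_height <= 0 or self.source_height <= 0:
            raise ValueError("heights must be positive")
        if self.horizontal_distance <= 0:
            raise ValueError("horizontal distance must be positive")


@dataclass
class IPDSpectrum:
    """Interaural phase difference vs frequency for one source direction.

    ``ipd`` is stored unwrapped (continuous in f, anchored near 0 at the
    low-frequency end), in cycles; positive = contralateral lag.
    """

    azimuth: float
    freqs: np.ndarray
    ipd: np.ndarray

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.ipd = np.asarray(self.ipd, dtype=float)
        if self.freqs.size != self.ipd.size:
            raise ValueError("freqs and ipd must have equal length")


@dataclass
class ItdMetrics:
    """Frequency-dependent delay metrics derived from one IPD spectrum."""

    freqs: np.ndarray
    itd_p: np.ndarray  # s
    itd_g: np.ndarray  # s
    idi: np.ndarray  # cycles
    window_intercepts: np.ndarray  # cycles; regression intercepts, for checks


@dataclass
class AcousticalCPCD:
    """Band-wise acoustical characteristic phase/delay at one direction."""

    azimuth: float
    center_freq: float
    cp: float  # cycles
    cd: float  # ms
    bandwidth: float  # Hz


def default_freq_grid(lo: float = 100.0, hi: float = 4000.0, step: float = 2.0):
    """Dense frequency grid used for IPD spectra (Hz)."""
    return np.arange(lo, hi + 0.5 * step, step)


# ---------------------------------------------------------------------------
# rigid-sphere partial-wave solution

def sphere_pressure(
    freqs,
    source_distance: float,
    cos_theta: float,
    radius: float,
    speed_of_sound: float = 343.0,
    max_order: int = 120,
    rtol: float = 1e-6,
):
    """Complex pressure on a rigid sphere's surface for a point source.

    Partial-wave series for the total (incident + scattered) field at a
    surface point separated by angle ``theta`` from the source direction::

        p ~ (1 / (k a^2)) * sum_m (2m+1) P_m(cos theta) h_m(k r) / h_m'(k a)

    with spherical Hankel functions of the first kind (time convention
    ``exp(-i w t)``, so propagation over an extra path length appears as a
    positive phase, i.e. a lag).  Constant factors common to both ears and
    both propagation paths are dropped; the ``1/r`` spreading loss and the
    travel phase are carried by ``h_m(k r)``, so direct and reflected
    contributions can be summed coherently.

    The series is truncated adaptively; a term three orders running below
    ``rtol`` of the partial sum ends the summation.

    Raises
    ------
    ConvergenceError
        If ``max_order`` terms do not reach the requested tolerance.
    """
    freqs = np.asarray(freqs, dtype=float)
    k = 2.0 * np.pi * freqs / speed_of_sound
    ka = k * radius
    kr = k * source_distance
    total = np.zeros(freqs.shape, dtype=complex)
    small = 0
    for m in range(max_order + 1):
        jm_r, ym_r = spherical_jn(m, kr), spherical_yn(m, kr)
        djm_a = spherical_jn(m, ka, derivative=True)
        dym_a = spherical_yn(m, ka, derivative=True)
        h_r = jm_r + 1j * ym_r
        dh_a = djm_a + 1j * dym_a
        term = (2 * m + 1) * eval_legendre(m, cos_theta) * h_r / dh_a
        total += term
        if np.all(np.abs(term) <= rtol * np.maximum(np.abs(total), 1e-300)):
            small += 1
            if small >= 3:
                break
        else:
            small = 0
    else:
        raise ConvergenceError(
            f"sphere series not converged at order {max_order} "
            f"(max ka = {ka.max():.2f}); increase max_order"
        )
    return total / (ka * radius)


def _ear_pressures(cfg: HeadModelConfig, freqs, azimuth, elevation_deg=0.0,
                   distance=None):
    """Pressures at the ipsilateral (+ear_az) and contralateral (-ear_az)
    ears for a source at (azimuth, elevation)."""
    r = cfg.source_distance if distance is None else distance
    az = np.deg2rad(azimuth)
    el = np.deg2rad(elevation_deg)
    ear = np.deg2rad(cfg.ear_azimuth)
    # unit vectors: source direction and ear positions (horizontal plane)
    cos_ipsi = np.cos(el) * np.cos(az - ear) * 1.0
    cos_contra = np.cos(el) * np.cos(az + ear) * 1.0
    args = dict(
        source_distance=r,
        radius=cfg.radius,
        speed_of_sound=cfg.speed_of_sound,
        max_order=cfg.max_order,
    )
    return (
        sphere_pressure(freqs, cos_theta=cos_ipsi, **args),
        sphere_pressure(freqs, cos_theta=cos_contra, **args),
    )


def sphere_hrtf(cfg: HeadModelConfig, freqs):
    """Complex (ipsilateral, contralateral) ear gains for the bare sphere.

    The source sits in the horizontal plane at ``cfg.source_azimuth``
    (positive toward the ipsilateral ear) and ``cfg.source_distance``.
    """
    return _ear_pressures(cfg, freqs, cfg.source_azimuth)


# ---------------------------------------------------------------------------
# ground reflection

def image_path_geometry(ground: GroundConfig):
    """Direct/reflected path lengths, extra delay factor, and angles.

    Returns a dict with direct and image-source distances, the incidence
    angle cosine at the ground bounce, and the source elevations of the
    direct and reflected rays as seen from the head.
    """
    x = ground.horizontal_distance
    dh, ds = ground.head_height, ground.source_height
    d_direct = np.hypot(x, ds - dh)
    d_image = np.hypot(x, ds + dh)
    return {
        "d_direct": d_direct,
        "d_image": d_image,
        "elev_direct": np.rad2deg(np.arctan2(ds - dh, x)),
        "elev_image": np.rad2deg(np.arctan2(-(ds + dh), x)),
        "cos_incidence": (ds + dh) / d_image,
    }


def extra_path_delay(ground: GroundConfig, speed_of_sound: float = 343.0):
    """Extra travel time of the ground-reflected ray vs the direct ray (s)."""
    g = image_path_geometry(ground)
    return (g["d_image"] - g["d_direct"]) / speed_of_sound


def ground_reflection_coefficient(freqs, ground: GroundConfig):
    """Plane-wave reflection coefficient of the ground at each frequency.

    The ground's normalized specific impedance follows the one-parameter
    Delany–Bazley model, ``zeta = 1 + 0.0571 X^-0.754 + 0.087 i X^-0.732``
    with ``X = rho0 f / sigma`` (sigma = flow resistivity, Pa s m^-2),
    evaluated at the geometric angle of incidence::

        R(f) = (zeta cos(theta_i) - 1) / (zeta cos(theta_i) + 1).

    ``flow_resistivity = inf`` gives the rigid-ground limit R = 1.
    """
    freqs = np.asarray(freqs, dtype=float)
    cos_i = image_path_geometry(ground)["cos_incidence"]
    if np.isinf(ground.flow_resistivity):
        return np.ones(freqs.shape, dtype=complex)
    x = RHO_AIR * freqs / ground.flow_resistivity
    zeta = 1.0 + 0.0571 * x**-0.754 + 0.087j * x**-0.732
    return (zeta * cos_i - 1.0) / (zeta * cos_i + 1.0)


def add_ground_reflection(
    gains,
    cfg: HeadModelConfig,
    ground: GroundConfig,
    freqs,
    diffract_reflection: bool = True,
):
    """Add the ground-reflected ray to a pair of ear gains.

    ``gains`` is the (ipsi, contra) pair for the direct ray; the reflected
    ray is taken from the image source (mirrored below the ground plane),
    attenuated by the reflection coefficient, and — by default — passed
    through the sphere solution at the image source's elevation and
    distance, so head diffraction applies to the reflection as well.  With
    ``diffract_reflection=False`` the reflected ray is added as a free
    field delayed/attenuated copy of the direct gains (cheap mode used for
    comb-filter tests).
    """
    freqs = np.asarray(freqs, dtype=float)
    geom = image_path_geometry(ground)
    refl = ground_reflection_coefficient(freqs, ground)
    g_ipsi, g_contra = gains
    if diffract_reflection:
        r_ipsi, r_contra = _ear_pressures(
            cfg, freqs, cfg.source_azimuth,
            elevation_deg=geom["elev_image"], distance=geom["d_image"],
        )
    else:
        tau = (geom["d_image"] - geom["d_direct"]) / cfg.speed_of_sound
        spread = geom["d_direct"] / geom["d_image"]
        phase = np.exp(2j * np.pi * freqs * tau)  # exp(-iwt): delay = +phase
        r_ipsi, r_contra = g_ipsi * spread * phase, g_contra * spread * phase
    return g_ipsi + refl * r_ipsi, g_contra + refl * r_contra


# ---------------------------------------------------------------------------
# IPD and delay metrics

def ipd_spectrum(gains, freqs, azimuth: float) -> IPDSpectrum:
    """Interaural phase difference spectrum from a pair of ear gains.

    ``ipd = (phase_contra - phase_ipsi) / 2 pi`` cycles, unwrapped along
    frequency; positive means the contralateral signal lags.  Under the
    ``exp(-i w t)`` convention a lag is a positive phase, so no sign flip
    is needed.

    Raises
    ------
    UndefinedStatisticError
        If either gain vanishes at some frequency.
    """
    g_ipsi, g_contra = gains
    if np.any(g_ipsi == 0) or np.any(g_contra == 0):
        raise UndefinedStatisticError("zero gain: interaural phase undefined")
    dphi = np.angle(g_contra) - np.angle(g_ipsi)
    ipd = np.unwrap(dphi) / (2.0 * np.pi)
    # anchor the branch so the low-frequency end is within half a cycle of 0
    ipd = ipd - np.round(ipd[0])
    return IPDSpectrum(azimuth=float(azimuth), freqs=np.asarray(freqs, float),
                       ipd=ipd)


def _window_slice(freqs, lo, hi):
    i0, i1 = np.searchsorted(freqs, [lo, hi])
    return slice(i0, max(i1, i0 + 2))


def _fit_affine_window(freqs_hz, ipd, gtol=1e-12, iters=60):
    """Circular-linear regression of IPD on frequency within one window.

    The window phases are locally smooth, so an ordinary least-squares fit
    of the (already unwrapped) IPD provides the starting point, which
    damped Newton descent then refines on the circular objective.  Returns
    (intercept_cycles, slope_ms); the intercept keeps the branch of the
    unwrapped input.
    """
    f = freqs_hz / 1000.0
    A = np.vstack([np.ones_like(f), f]).T
    (a0, b0), *_ = np.linalg.lstsq(A, ipd, rcond=None)
    a, b = float(a0), float(b0)
    lam = 1e-9
    n = f.size
    for _ in range(iters):
        u = 2.0 * np.pi * (ipd - a - b * f)
        su, cu = np.sin(u), np.cos(u)
        g0 = -np.pi * su.sum() / n
        g1 = -np.pi * (f * su).sum() / n
        if np.hypot(g0, g1) < gtol:
            break
        tp2 = 2.0 * np.pi**2 / n
        h00, h01, h11 = tp2 * cu.sum(), tp2 * (f * cu).sum(), tp2 * (f * f * cu).sum()
        det = h00 * h11 - h01 * h01
        if det <= 0 or h00 <= 0:
            step0, step1 = -g0, -g1
        else:
            step0 = -(h11 * g0 - h01 * g1) / det
            step1 = -(h00 * g1 - h01 * g0) / det
        E = 0.5 * (1 - cu).mean()
        for _ in range(20):
            u2 = 2.0 * np.pi * (ipd - (a + step0) - (b + step1) * f)
            if 0.5 * (1 - np.cos(u2)).mean() <= E + 1e-15:
                break
            step0 *= 0.5
            step1 *= 0.5
        a += step0
        b += step1
        lam *= 1.0  # damping handled by step halving
    return a, b


def itd_metrics(spec: IPDSpectrum, window_frac: float = 0.25) -> ItdMetrics:
    """Phase ITD, group ITD and IDI along the spectrum's frequency grid.

    At each frequency f the IPD is regressed on frequency over a window of
    width ``window_frac * f`` centered on f (circular-linear fit, uniform
    weights).  The slope estimates ``ITD_g(f)``; the phase ITD is the
    unwrapped IPD divided by f; and ``IDI(f) = f (ITD_p - ITD_g)``.  The
    regression intercepts are returned alongside: they equal the IDI up to
    an integer number of cycles and serve as an internal cross-check.

    Windows extending beyond the grid are shrunk to the available range (a
    warning is emitted once).
    """
    f = spec.freqs
    ipd = spec.ipd
    n = f.size
    itd_g = np.empty(n)
    intercepts = np.empty(n)
    clipped = False
    for i, fc in enumerate(f):
        half = 0.5 * window_frac * fc
        lo, hi = fc - half, fc + half
        if lo < f[0] or hi > f[-1]:
            clipped = True
        sl = _window_slice(f, max(lo, f[0]), min(hi, f[-1]))
        a, b = _fit_affine_window(f[sl], ipd[sl])
        intercepts[i] = a
        itd_g[i] = b / 1000.0  # ms -> s
    if clipped:
        warnings.warn(
            "itd_metrics: some regression windows were shrunk at the grid "
            "edges", stacklevel=2,
        )
    itd_p = ipd / f
    idi = f * (itd_p - itd_g)
    return ItdMetrics(freqs=f, itd_p=itd_p, itd_g=itd_g, idi=idi,
                      window_intercepts=intercepts)


def q_factor(center_freq: float) -> float:
    """Filter quality factor Q(F) = 1.04 + 3.8e-4 * F (F in Hz)."""
    return 1.04 + 3.8e-4 * center_freq


def acoustical_cpcd(spec: IPDSpectrum, center_freq: float) -> AcousticalCPCD:
    """Acoustical CP and CD in the band centered on ``center_freq``.

    The analysis window has bandwidth ``BW(F) = F / Q(F)`` (the bandwidth
    of cells at that characteristic frequency); within it the IPD is fit
    with the same grid + descent circular-linear regression used for cell
    best phases, with uniform weights.  For an affine IPD the intercept
    and slope are recovered exactly (up to optimizer tolerance).
    """
    bw = center_freq / q_factor(center_freq)
    lo, hi = center_freq - bw / 2.0, center_freq + bw / 2.0
    if lo < spec.freqs[0] or hi > spec.freqs[-1]:
        raise ValueError(
            f"analysis window [{lo:.0f}, {hi:.0f}] Hz outside the IPD grid"
        )
    sl = _window_slice(spec.freqs, lo, hi)
    cp, cd, _ = fit_phase_line(spec.freqs[sl], wrap_phase(spec.ipd[sl]))
    return AcousticalCPCD(
        azimuth=spec.azimuth, center_freq=float(center_freq),
        cp=cp, cd=cd, bandwidth=float(bw),
    )


def best_azimuth(curve, specs: list[IPDSpectrum]) -> float:
    """Best azimuth of a cell: direction whose IPD best matches its BPs.

    Minimizes ``sum_f d(BP(f), IPD(f; theta))`` over the supplied spectra,
    with IPD taken at the grid frequency closest to each cell frequency.
    Ties break toward the smaller azimuth.
    """
    if len(specs) < 2:
        raise ValueError("need IPD spectra for at least 2 azimuths")
    best = None
    for s in sorted(specs, key=lambda s: s.azimuth):
        idx = np.clip(
            np.searchsorted(s.freqs, curve.freqs), 1, s.freqs.size - 1
        )
        idx = np.where(
            np.abs(s.freqs[idx - 1] - curve.freqs)
            <= np.abs(s.freqs[idx] - curve.freqs),
            idx - 1,
            idx,
        )
        cost = float(np.sum(circular_distance(curve.bps, s.ipd[idx])))
        if best is None or cost < best[0] - 1e-15:
            best = (cost, s.azimuth)
    return best[1]
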