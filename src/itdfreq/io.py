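"""Readers and writers for the package's columnar text formats.

Spike tables are plain CSV with one row per spike:

- cell tables: ``cell_id, tone_freq_hz, beat_freq_hz, beat_sign, rep,
  spike_time_s, duration_s, level_db``
- fiber tables: ``fiber_id, cf_hz, tone_freq_hz, rep, spike_time_s,
  duration_s``

Fit tables have one row per cell (``cell_id, cp_cycles, cd_ms, residual,
linearity_p, n_points, cf_hz``), and IPD tables one row per (azimuth,
frequency) with columns ``azimuth_deg, freq_hz, ipd_cycles``.  Writers can
embed a config hash as a leading ``#`` comment; readers skip comments.
External HRTF sets in SOFA (HDF5) form are read with h5py.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd

from itdfreq.acoustics import IPDSpectrum
from itdfreq.circstats import BeatResponse
from itdfreq.coincidence import FiberResponseSet
from itdfreq.cpcd import CPCDFit

__all__ = [
    "config_hash",
    "write_cell_spikes",
    "read_cell_spikes",
    "write_fiber_spikes",
    "read_fiber_spikes",
    "write_fits",
    "read_fits",
    "write_ipd_table",
    "read_ipd_table",
    "read_sofa_hrir",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path, config: dict | None):
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# itdfreq-config-sha256: {config_hash(config)}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def write_cell_spikes(responses: list[BeatResponse], path, config=None):
    rows = []
    for r in responses:
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": r.cell_id,
                    "tone_freq_hz": r.tone_freq,
                    "beat_freq_hz": r.beat_freq,
                    "beat_sign": r.beat_sign,
                    "rep": r.reps,
                    "spike_time_s": r.spikes,
                    "duration_s": r.duration,
                    "level_db": r.level_db,
                }
            )
        )
    _write_csv(pd.concat(rows, ignore_index=True), path, config)


def read_cell_spikes(path) -> list[BeatResponse]:
    """Read a cell spike table; validates ranges via BeatResponse.

    Round-trips exactly with :func:`write_cell_spikes`.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    out = []
    for (cell, f), grp in df.groupby(["cell_id", "tone_freq_hz"], sort=True):
        out.append(
            BeatResponse(
                cell_id=str(cell),
                tone_freq=float(f),
                beat_freq=float(grp["beat_freq_hz"].iloc[0]),
                beat_sign=int(grp["beat_sign"].iloc[0]),
                duration=float(grp["duration_s"].iloc[0]),
                n_reps=int(grp["rep"].max()) + 1,
                spikes=grp["spike_time_s"].to_numpy(),
                reps=grp["rep"].to_numpy(),
                level_db=float(grp["level_db"].iloc[0]),
            )
        )
    return out


def write_fiber_spikes(fibers: list[FiberResponseSet], path, config=None):
    rows = []
    for fb in fibers:
        for f, reps in sorted(fb.responses.items()):
            for i, t in enumerate(reps):
                t = np.asarray(t)
                rows.append(
                    pd.DataFrame(
                        {
                            "fiber_id": fb.fiber_id,
                            "cf_hz": fb.cf,
                            "tone_freq_hz": f,
                            "rep": i,
                            "spike_time_s": t,
                            "duration_s": fb.duration,
                        }
                    )
                )
    _write_csv(pd.concat(rows, ignore_index=True), path, config)


def read_fiber_spikes(path) -> list[FiberResponseSet]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    out = []
    for fid, grp in df.groupby("fiber_id", sort=True):
        responses = {}
        for f, g in grp.groupby("tone_freq_hz"):
            n_reps = int(g["rep"].max()) + 1
            responses[float(f)] = [
                g.loc[g["rep"] == i, "spike_time_s"].to_numpy()
                for i in range(n_reps)
            ]
        out.append(
            FiberResponseSet(
                fiber_id=str(fid),
                cf=float(grp["cf_hz"].iloc[0]),
                duration=float(grp["duration_s"].iloc[0]),
                responses=responses,
            )
        )
    return out


def write_fits(fits: dict[str, CPCDFit], path, cfs: dict | None = None,
               config=None):
    """Write per-cell CP/CD fits as CSV (one row per cell)."""
    cfs = cfs or {}
    df = pd.DataFrame(
        [
            {
                "cell_id": cid,
                "cp_cycles": f.cp,
                "cd_ms": f.cd,
                "residual": f.residual,
                "linearity_p": f.linearity_p,
                "n_points": f.n_points,
                "cf_hz": cfs.get(cid),
            }
            for cid, f in fits.items()
        ]
    )
    _write_csv(df, path, config)


def read_fits(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_ipd_table(specs: list[IPDSpectrum], path, config=None):
    rows = [
        pd.DataFrame(
            {"azimuth_deg": s.azimuth, "freq_hz": s.freqs, "ipd_cycles": s.ipd}
        )
        for s in specs
    ]
    _write_csv(pd.concat(rows, ignore_index=True), path, config)


def read_ipd_table(path) -> list[IPDSpectrum]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return [
        IPDSpectrum(
            azimuth=float(az),
            freqs=grp["freq_hz"].to_numpy(),
            ipd=grp["ipd_cycles"].to_numpy(),
        )
        for az, grp in df.groupby("azimuth_deg", sort=True)
    ]


def read_sofa_hrir(path):
    """Read a SimpleFreeFieldHRIR SOFA file (HDF5) into IPD spectra.

    Returns a list of :class:`~itdfreq.acoustics.IPDSpectrum`, one per
    measurement position, restricted to positions on (or nearest to) the
    horizontal plane.  The left/right impulse responses are Fourier
    transformed; the interaural phase is unwrapped along frequency.
    Receiver 0 is taken as the left ear (the SOFA convention), and
    positive SOFA azimuths point left, so a source at positive azimuth
    yields positive IPD (contralateral/right ear lagging).
    """
    import h5py  # deferred: optional dependency

    with h5py.File(path, "r") as f:
        ir = np.asarray(f["Data.IR"])  # (M, R, N)
        fs = float(np.asarray(f["Data.SamplingRate"]).ravel()[0])
        pos = np.asarray(f["SourcePosition"])  # (M, 3): az, el, dist
    if ir.ndim != 3 or ir.shape[1] < 2:
        raise ValueError("expected SimpleFreeFieldHRIR layout (M, 2, N)")
    n = ir.shape[2]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    specs = []
    for m in range(ir.shape[0]):
        az = float(pos[m, 0])
        left = np.fft.rfft(ir[m, 0])
        right = np.fft.rfft(ir[m, 1])
        valid = freqs > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            dphi = np.angle(left[valid]) - np.angle(right[valid])
        ipd = np.unwrap(dphi) / (2.0 * np.pi)
        ipd = ipd - np.round(ipd[0])
        specs.append(IPDSpectrum(azimuth=az, freqs=freqs[valid], ipd=ipd))
    return specs
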