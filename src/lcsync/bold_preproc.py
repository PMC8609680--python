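"""Temporal conditioning of parcellated BOLD time series.

Implements the post-spatial-preprocessing chain applied to node x time
matrices before phase-synchronization analysis, in this fixed order:

1. drop the first k volumes (scanner stabilization / adaptation; default 10),
2. remove a per-node linear trend,
3. regress out nuisance confounds (e.g. WM/CSF signals and the Friston-24
   motion expansion),
4. ideal band-pass in 0.04-0.07 Hz, the band where resting-state
   synchronization is evaluated,

plus the head-motion exclusion rule: subjects whose mean Jenkinson framewise
displacement (FD) exceeds 0.2 mm are excluded.  Spatial steps (slice timing,
realignment, normalization, smoothing) are assumed done upstream; inputs here
are already parcellated.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping

import numpy as np

from .datatypes import TimeSeriesMatrix

__all__ = [
    "drop_initial_volumes",
    "detrend",
    "regress_confounds",
    "bandpass",
    "friston24",
    "jenkinson_fd",
    "exclude_by_fd",
    "preprocess",
]


def drop_initial_volumes(ts: TimeSeriesMatrix, k: int = 10) -> TimeSeriesMatrix:
    """Remove the first ``k`` volumes (columns). 205 -> 195 at the defaults."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= ts.n_timepoints:
        raise ValueError(f"cannot drop {k} of {ts.n_timepoints} volumes")
    return ts.replace_values(ts.values[:, k:])


def detrend(ts: TimeSeriesMatrix) -> TimeSeriesMatrix:
    """Remove the per-node least-squares linear trend (intercept + slope).

    Output rows have zero mean and are orthogonal to the time index.
    """
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 time points to detrend")
    t = np.arange(ts.n_timepoints, dtype=float)
    basis = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(basis, ts.values.T, rcond=None)
    return ts.replace_values(ts.values - (basis @ coef).T)


def regress_confounds(ts: TimeSeriesMatrix, confounds: np.ndarray) -> TimeSeriesMatrix:
    """Project out the confound column space (plus an intercept) per node.

    Residuals are orthogonal to every confound column.  Linearly dependent
    confound columns are dropped with a warning.
    """
    conf = np.asarray(confounds, dtype=float)
    if conf.ndim == 1:
        conf = conf[:, None]
    if conf.shape[0] != ts.n_timepoints:
        raise ValueError("confound rows must match the number of time points")
    if conf.shape[1] >= ts.n_timepoints:
        raise ValueError("more confounds than time points")

    design = np.column_stack([np.ones(ts.n_timepoints), conf])
    q, r, piv = _qr_drop_dependent(design)
    if q.shape[1] < design.shape[1]:
        warnings.warn(
            f"dropped {design.shape[1] - q.shape[1]} linearly dependent confound column(s)",
            stacklevel=2,
        )
    fitted = q @ (q.T @ ts.values.T)
    return ts.replace_values(ts.values - fitted.T)


def _qr_drop_dependent(design: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal basis of the design's column space via pivoted rank check."""
    q, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    tol = max(design.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    keep = diag > tol
    return q[:, keep], r[keep][:, keep], np.nonzero(keep)[0]


def bandpass(ts: TimeSeriesMatrix, low: float = 0.04, high: float = 0.07) -> TimeSeriesMatrix:
    """Ideal (rectangular) zero-phase band-pass via a DFT mask.

    Discrete-Fourier components with frequency magnitude in [low, high]
    (inclusive) are retained; everything else, including the zero-frequency
    term, is zeroed.  Idempotent by construction.
    """
    nyquist = 0.5 / ts.sampling_interval
    if not 0 <= low < high:
        raise ValueError("need 0 <= low < high")
    if high > nyquist:
        raise ValueError(f"high cutoff {high} Hz exceeds Nyquist {nyquist} Hz")
    n = ts.n_timepoints
    freqs = np.fft.rfftfreq(n, d=ts.sampling_interval)
    spectrum = np.fft.rfft(ts.values, axis=1)
    spectrum[:, (freqs < low) | (freqs > high)] = 0.0
    return ts.replace_values(np.fft.irfft(spectrum, n=n, axis=1))


def friston24(motion: np.ndarray) -> np.ndarray:
    """Friston 24-parameter motion expansion from a 6-parameter trace.

    Columns are [p(t), p(t-1), p(t)^2, p(t-1)^2] for the six rigid-body
    parameters, with the lagged terms zero at the first volume.
    """
    m = _check_motion(motion)
    lagged = np.vstack([np.zeros((1, 6)), m[:-1]])
    return np.column_stack([m, lagged, m**2, lagged**2])


def _check_motion(motion: np.ndarray) -> np.ndarray:
    m = np.asarray(motion, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError("motion trace must be an n_volumes x 6 array")
    if not np.all(np.isfinite(m)):
        raise ValueError("motion trace contains non-finite values")
    return m


def _rigid_affine(params: np.ndarray) -> np.ndarray:
    """4x4 affine from (tx, ty, tz, rx, ry, rz); rotations in radians,
    composed as Rx @ Ry @ Rz."""
    tx, ty, tz, rx, ry, rz = params
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    rot_x = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    rot_y = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rot_z = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    affine = np.eye(4)
    affine[:3, :3] = rot_x @ rot_y @ rot_z
    affine[:3, 3] = (tx, ty, tz)
    return affine


def jenkinson_fd(motion: np.ndarray, radius: float = 80.0) -> np.ndarray:
    """Jenkinson framewise displacement trace in mm.

    For each consecutive volume pair the relative rigid-body transform
    T_rel = T_i T_{i-1}^{-1} is decomposed into its matrix residual
    A = M - I and translation b, and the RMS displacement of a point
    uniformly distributed in a sphere of the given radius is

        FD = sqrt( (1/5) radius^2 trace(A^T A) + b^T b ).

    The first volume is assigned 0.  ``radius`` = 80 mm is the conventional
    head-size value.
    """
    m = _check_motion(motion)
    if m.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    fd = np.zeros(m.shape[0])
    prev = _rigid_affine(m[0])
    for i in range(1, m.shape[0]):
        cur = _rigid_affine(m[i])
        rel = cur @ np.linalg.inv(prev)
        a = rel[:3, :3] - np.eye(3)
        b = rel[:3, 3]
        fd[i] = np.sqrt(0.2 * radius**2 * np.trace(a.T @ a) + b @ b)
        prev = cur
    return fd


def exclude_by_fd(
    subject_fd: Mapping[str, float], threshold: float = 0.2
) -> tuple[list[str], list[str]]:
    """Partition subjects into (kept, excluded) by mean FD.

    Exclusion is strict: a subject is excluded iff mean FD > threshold, so a
    boundary value exactly equal to the threshold is kept.
    """
    for sid, fd in subject_fd.items():
        if not np.isfinite(fd):
            raise ValueError(f"non-finite FD for subject {sid}")
    kept = [sid for sid, fd in subject_fd.items() if fd <= threshold]
    excluded = [sid for sid, fd in subject_fd.items() if fd > threshold]
    return kept, excluded


def preprocess(
    ts: TimeSeriesMatrix,
    *,
    drop: int = 10,
    confounds: np.ndarray | None = None,
    low: float = 0.04,
    high: float = 0.07,
) -> TimeSeriesMatrix:
    """Run the fixed conditioning chain: drop -> detrend -> regress -> bandpass.

    ``confounds`` rows must match the post-drop length; pass ``None`` to skip
    the nuisance regression (e.g. for simulated data with no confounds).
    """
    out = drop_initial_volumes(ts, drop)
    out = detrend(out)
    if confounds is not None:
        out = regress_confounds(out, confounds)
    return bandpass(out, low=low, high=high)
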