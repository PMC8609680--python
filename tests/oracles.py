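"""Independent brute-force oracles used to validate pipeline computations.

Everything here is deliberately written from scratch against the defining
formulas — explicit DFT manipulation, pixel-by-pixel loops, explicit ANOVA
sums — so that agreement with the package is a genuine two-route check, not a
re-run of the same code path.
"""

from __future__ import annotations

import numpy as np


def analytic_signal_dft(x: np.ndarray) -> np.ndarray:
    """Analytic signal via the one-sided spectrum, built from np.fft directly:
    zero negative frequencies, double positive ones, half-weight on DC and
    (for even length) the Nyquist bin."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    spec = np.fft.fft(x, axis=-1)
    h = np.zeros(n)
    h[0] = 1.0
    if n % 2 == 0:
        h[n // 2] = 1.0
        h[1 : n // 2] = 2.0
    else:
        h[1 : (n + 1) // 2] = 2.0
    return np.fft.ifft(spec * h, axis=-1)


def phase_sync_pipeline(values: np.ndarray, trim: int = 10) -> tuple[np.ndarray, float]:
    """Direct phase-synchronization pipeline: DFT analytic signal, border
    trim, explicit complex sums for the order parameter."""
    phases = np.angle(analytic_signal_dft(values))
    if trim:
        phases = phases[:, trim:-trim]
    n = phases.shape[0]
    r_trace = np.empty(phases.shape[1])
    for t in range(phases.shape[1]):
        total = 0.0 + 0.0j
        for j in range(n):
            total += complex(np.cos(phases[j, t]), np.sin(phases[j, t]))
        r_trace[t] = abs(total) / n
    return r_trace, float(r_trace.mean())


def roi_mean_sd_bruteforce(
    plane: np.ndarray,
    center: tuple[float, float],
    radius_mm: float,
    pixel_size: tuple[float, float],
) -> tuple[float, float, int]:
    """Mean/SD over a disc by looping over every pixel of the slice and
    testing the strict center-in-disc inequality."""
    values = []
    pr, pc = pixel_size
    for r in range(plane.shape[0]):
        for c in range(plane.shape[1]):
            if ((r - center[0]) * pr) ** 2 + ((c - center[1]) * pc) ** 2 < radius_mm**2:
                values.append(plane[r, c])
    values = np.asarray(values)
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()), sd, int(values.size)


def icc_absolute_agreement(table: np.ndarray) -> float:
    """ICC(A,1) from the two-way ANOVA decomposition, with every sum written
    out explicitly."""
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    grand = table.sum() / (n * k)
    ss_rows = sum(k * (table[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (table[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((table[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def fd_sphere_oracle(
    affine_prev: np.ndarray, affine_cur: np.ndarray, radius: float = 80.0,
    n_points: int = 200_000, seed: int = 0,
) -> float:
    """RMS displacement between two rigid transforms over a uniformly sampled
    solid sphere (Monte-Carlo integration)."""
    rng = np.random.default_rng(seed)
    directions = rng.normal(size=(n_points, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    pts = directions * radius * rng.uniform(0.0, 1.0, size=(n_points, 1)) ** (1.0 / 3.0)
    rel = affine_cur @ np.linalg.inv(affine_prev)
    disp = pts @ (rel[:3, :3] - np.eye(3)).T + rel[:3, 3]
    return float(np.sqrt((disp**2).sum(axis=1).mean()))


def kuramoto_reference(
    freqs: np.ndarray,
    init_phases: np.ndarray,
    coupling: float,
    n_timepoints: int,
    sampling_interval: float,
    substeps: int = 20,
) -> np.ndarray:
    """Straightforward pairwise-sum integration of the phase-oscillator
    system (no mean-field shortcut); returns phases at sample times."""
    theta = np.array(init_phases, dtype=float)
    n = theta.size
    omega = 2 * np.pi * np.asarray(freqs, dtype=float)
    dt = sampling_interval / substeps
    out = np.empty((n, n_timepoints))
    out[:, 0] = theta
    for t in range(1, n_timepoints):
        for _ in range(substeps):
            coupling_term = np.array(
                [np.sin(theta - theta[j]).sum() for j in range(n)]
            )
            theta = theta + dt * (omega + coupling / n * coupling_term)
        out[:, t] = theta
    return out
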