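"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators stand in for the study's non-deposited patient data:

* ``gen_nm_phantom`` — neuromelanin-MRI-like phantom volumes with planted
  bright LC/SN discs, reference-tissue discs (pontine tegmentum, cerebral
  peduncle) and additive Gaussian noise, so CNR estimation and LC
  localization can be validated against planted contrast.
* ``gen_oscillator_bold`` — node x time BOLD-like matrices from the
  mean-field coupled phase-oscillator system
  ``dtheta_j/dt = omega_j + (K/n) sum_k sin(theta_k - theta_j)`` observed as
  ``sin(theta_j) + noise``.  The Kuramoto order parameter the pipeline
  measures is exactly this model's synchrony, and the sine observation forces
  the pipeline's own Hilbert step to recover the phases.
* ``gen_cohort`` — per-subject tables (CNR, UPDRS-III OFF/ON, synchrony
  OFF/ON, age, medication duration, LEDD) with a planted partial correlation
  between CNR_LC and the UPDRS-III response rate after covariate removal.

All randomness flows from an explicit per-call seed; no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ImageVolume, RoiSpec, TimeSeriesMatrix
from .nm_quant import disc_pixel_offsets

__all__ = [
    "PhantomTruth",
    "default_phantom_truth",
    "gen_nm_phantom",
    "OscillatorParams",
    "gen_oscillator_bold",
    "CohortParams",
    "gen_cohort",
]

# in-plane resolution of a 220 mm FOV / 512 matrix acquisition
DEFAULT_PIXEL_MM = 220.0 / 512.0
DEFAULT_VOXEL_SIZE = (3.0, DEFAULT_PIXEL_MM, DEFAULT_PIXEL_MM)
DEFAULT_SHAPE = (3, 96, 96)


@dataclass
class PhantomTruth:
    """Planted geometry and intensities of an NM-MRI phantom.

    Centers are (row, col) pixel coordinates.  LC discs appear on each of
    ``lc_slices`` (3 contiguous pons slices) on both sides, with the pontine
    reference (PT) on the same slices; SN subregion discs and the
    cerebral-peduncle references (CP) sit on the single midbrain slice
    ``sn_slice``.  ``si_map`` plants the mean intensity per region label and
    for the background; ``true_cnr`` is the planted contrast
    (SI_region - SI_reference) / noise_sd.
    """

    lc_centers: dict[tuple[int, str], tuple[int, int]]  # (slice, side) -> center
    pt_center: tuple[int, int]
    sn_centers: dict[tuple[str, str], tuple[int, int]]  # (side, subregion) -> center
    cp_centers: dict[str, tuple[int, int]]  # side -> center
    sn_slice: int
    si_map: dict[str, float]
    noise_sd: float

    @property
    def lc_slices(self) -> list[int]:
        return sorted({s for s, _ in self.lc_centers})

    @property
    def true_cnr(self) -> dict[str, float]:
        if self.noise_sd <= 0:
            raise ValueError("true_cnr undefined at zero noise")
        return {
            "LC": (self.si_map["LC"] - self.si_map["PT"]) / self.noise_sd,
            "SN": (self.si_map["SN"] - self.si_map["CP"]) / self.noise_sd,
        }


def default_phantom_truth(
    si_lc: float = 120.0,
    si_pt: float = 100.0,
    si_sn: float = 115.0,
    si_cp: float = 95.0,
    background: float = 80.0,
    noise_sd: float = 10.0,
) -> PhantomTruth:
    """Reference phantom geometry for the default 3 x 96 x 96 grid."""
    lc_centers = {(s, "left"): (40, 40) for s in range(3)}
    lc_centers.update({(s, "right"): (40, 56) for s in range(3)})
    return PhantomTruth(
        lc_centers=lc_centers,
        pt_center=(60, 48),
        sn_centers={
            ("left", "lateral"): (16, 28),
            ("left", "central"): (22, 24),
            ("left", "medial"): (28, 20),
            ("right", "lateral"): (16, 68),
            ("right", "central"): (22, 72),
            ("right", "medial"): (28, 76),
        },
        cp_centers={"left": (36, 32), "right": (36, 64)},
        sn_slice=1,
        si_map={"LC": si_lc, "PT": si_pt, "SN": si_sn, "CP": si_cp, "background": background},
        noise_sd=noise_sd,
    )


def _paint_disc(plane: np.ndarray, center: tuple[int, int], area_mm2: float,
                pixel_size: tuple[float, float], value: float) -> tuple[np.ndarray, np.ndarray]:
    radius = float(np.sqrt(area_mm2 / np.pi))
    dr, dc = disc_pixel_offsets(radius, pixel_size)
    rows, cols = center[0] + dr, center[1] + dc
    if rows.min() < 0 or cols.min() < 0 or rows.max() >= plane.shape[0] or cols.max() >= plane.shape[1]:
        raise ValueError(f"region disc at {center} does not fit within the slice grid")
    plane[rows, cols] = value
    return rows, cols


def gen_nm_phantom(
    truth: PhantomTruth,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    seed: int = 0,
) -> tuple[ImageVolume, list[RoiSpec]]:
    """Render a phantom volume and the ROI specifications matching its truth.

    Each planted region is a disc of the protocol ROI area (2 mm^2 LC,
    20 mm^2 PT, 10 mm^2 SN subregion, 30 mm^2 CP) at the planted mean
    intensity, over a uniform background, with i.i.d. Gaussian noise of SD
    ``truth.noise_sd`` added everywhere.  As noise_sd -> 0 the extracted ROI
    means equal the planted intensities exactly.

    Raises
    ------
    ValueError
        If an LC disc overlaps the PT disc on the same slice, or a disc does
        not fit inside the grid.
    """
    rng = np.random.default_rng(seed)
    px = (voxel_size[1], voxel_size[2])
    vol = np.full(shape, truth.si_map["background"], dtype=float)
    rois: list[RoiSpec] = []

    for s in truth.lc_slices:
        if not 0 <= s < shape[0]:
            raise ValueError(f"LC slice {s} outside volume of {shape[0]} slices")
    if not 0 <= truth.sn_slice < shape[0]:
        raise ValueError("SN slice outside volume")

    for s in truth.lc_slices:
        pt_px = _paint_disc(vol[s], truth.pt_center, 20.0, px, truth.si_map["PT"])
        pt_set = set(zip(*pt_px))
        rois.append(RoiSpec("PT", s, truth.pt_center, 20.0))
        for side in ("left", "right"):
            lc_px = _paint_disc(vol[s], truth.lc_centers[(s, side)], 2.0, px, truth.si_map["LC"])
            if set(zip(*lc_px)) & pt_set:
                raise ValueError(f"LC disc overlaps PT disc on slice {s}")
            rois.append(RoiSpec(f"LC_{side}", s, truth.lc_centers[(s, side)], 2.0))

    for side in ("left", "right"):
        _paint_disc(vol[truth.sn_slice], truth.cp_centers[side], 30.0, px, truth.si_map["CP"])
        rois.append(RoiSpec(f"CP_{side}", truth.sn_slice, truth.cp_centers[side], 30.0))
        for sub in ("lateral", "central", "medial"):
            _paint_disc(vol[truth.sn_slice], truth.sn_centers[(side, sub)], 10.0, px,
                        truth.si_map["SN"])
            rois.append(RoiSpec(f"SN_{sub}_{side}", truth.sn_slice, truth.sn_centers[(side, sub)], 10.0))

    if truth.noise_sd > 0:
        vol += rng.normal(0.0, truth.noise_sd, size=shape)
    return ImageVolume(vol, voxel_size), rois


@dataclass
class OscillatorParams:
    """Parameters of the coupled phase-oscillator BOLD simulator.

    ``coupling`` is the dimensionless mean-field coupling K >= 0.
    ``natural_freqs`` (Hz) default to a uniform draw in the 0.04-0.07 Hz
    band, so the synchronization band-pass is transparent to the signal.
    ``init_phases`` default to a uniform draw on (-pi, pi]; pass explicit
    equal phases and frequencies with zero noise for the fully synchronized
    limit.  Integration is forward Euler at ``sampling_interval / 20``.
    """

    n_nodes: int = 33
    coupling: float = 0.0
    natural_freqs: np.ndarray | None = None
    n_timepoints: int = 205
    sampling_interval: float = 2.0
    obs_noise_sd: float = 0.05
    init_phases: np.ndarray | None = None
    freq_band: tuple[float, float] = (0.04, 0.07)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.coupling < 0:
            raise ValueError("coupling must be >= 0")
        if self.natural_freqs is not None and len(self.natural_freqs) != self.n_nodes:
            raise ValueError("natural_freqs length must equal n_nodes")
        if self.init_phases is not None and len(self.init_phases) != self.n_nodes:
            raise ValueError("init_phases length must equal n_nodes")


def gen_oscillator_bold(params: OscillatorParams) -> TimeSeriesMatrix:
    """Simulate coupled phase oscillators and observe s_j(t) = sin(theta_j) + noise.

    The mean-field identity (K/n) sum_k sin(theta_k - theta_j)
    = K R sin(psi - theta_j), with R e^{i psi} the instantaneous mean phasor,
    keeps each Euler step O(n).  With coupling 0 and spread frequencies the
    downstream mean order parameter is low; with large coupling it
    approaches 1.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_nodes
    freqs = (
        np.asarray(params.natural_freqs, dtype=float)
        if params.natural_freqs is not None
        else rng.uniform(*params.freq_band, size=n)
    )
    theta = (
        np.asarray(params.init_phases, dtype=float).copy()
        if params.init_phases is not None
        else rng.uniform(-np.pi, np.pi, size=n)
    )
    omega = 2.0 * np.pi * freqs
    substeps = 20
    dt = params.sampling_interval / substeps

    samples = np.empty((n, params.n_timepoints))
    samples[:, 0] = theta
    for t in range(1, params.n_timepoints):
        for _ in range(substeps):
            mean_phasor = np.exp(1j * theta).mean()
            r, psi = np.abs(mean_phasor), np.angle(mean_phasor)
            theta = theta + dt * (omega + params.coupling * r * np.sin(psi - theta))
        samples[:, t] = theta

    values = np.sin(samples)
    if params.obs_noise_sd > 0:
        values = values + rng.normal(0.0, params.obs_noise_sd, size=values.shape)
    labels = [f"node_{j:02d}" for j in range(n)]
    return TimeSeriesMatrix(values, labels, params.sampling_interval)


@dataclass
class CohortParams:
    """Parameters of the synthetic patient-cohort generator.

    ``target_r`` is the planted partial correlation between CNR_LC and the
    UPDRS-III rate of change after removing the age / medication-duration /
    LEDD covariate effects; ``target_r_sync`` likewise links CNR_LC to the
    synchronization rate of change (negative: higher LC integrity, larger ON
    increase in synchrony).  ``covariate_effects[var]`` gives the linear
    coefficients of the three standardized covariates on ``var``;
    ``noise_sds[var]`` the residual SD.  Defaults put the cohort at the
    reference study scale: 57 subjects, target_r 0.42.
    """

    n_subjects: int = 57
    target_r: float = 0.42
    target_r_sync: float = -0.32
    covariate_effects: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "cnr_lc": (-0.10, -0.05, 0.00),
            "cnr_sn": (-0.15, -0.08, 0.00),
            "rate_updrs": (-0.03, -0.02, 0.02),
            "rate_sync": (0.01, 0.01, -0.01),
        }
    )
    noise_sds: dict[str, float] = field(
        default_factory=lambda: {
            "cnr_lc": 0.45,
            "cnr_sn": 0.60,
            "rate_updrs": 0.15,
            "rate_sync": 0.10,
        }
    )
    means: dict[str, float] = field(
        default_factory=lambda: {
            "cnr_lc": 1.5,
            "cnr_sn": 2.0,
            "rate_updrs": 0.40,
            "rate_sync": -0.08,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.target_r) < 1 or not abs(self.target_r_sync) < 1:
            raise ValueError("planted correlations must satisfy |r| < 1")
        if self.n_subjects < 4 + 3:
            raise ValueError("n_subjects must be >= 4 + number of covariates")
        if self.means["rate_updrs"] > 1:
            raise ValueError("planted mean UPDRS rate > 1 is infeasible (ON score would be negative)")


def gen_cohort(params: CohortParams) -> pd.DataFrame:
    """Generate a per-subject cohort table with planted partial correlations.

    Construction: covariates (age, medication duration, LEDD) are drawn and
    standardized; residual innovations e1, e2, e3 are jointly Gaussian with
    corr(e1, e2) = target_r and corr(e1, e3) = target_r_sync; each outcome is
    mean + covariate effects + residual.  Regressing the covariates out of
    CNR_LC and the response rate therefore leaves residuals whose population
    correlation is exactly target_r.  UPDRS-III ON is derived as
    OFF * (1 - rate), so (OFF - ON) / OFF reproduces the planted rate
    exactly and all scores stay non-negative (rates are truncated to 0.95 in
    the far upper tail to keep ON >= 0).
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.n_subjects

    age = rng.normal(61.0, 8.0, n)
    duration = np.abs(rng.normal(4.0, 2.5, n)) + 0.25
    ledd = np.clip(rng.normal(450.0, 180.0, n), 50.0, None)
    sex = rng.integers(0, 2, n)

    z = np.column_stack(
        [(v - v.mean()) / v.std(ddof=0) for v in (age, duration, ledd)]
    )

    e1 = rng.standard_normal(n)
    e2 = p.target_r * e1 + np.sqrt(1 - p.target_r**2) * rng.standard_normal(n)
    e3 = p.target_r_sync * e1 + np.sqrt(1 - p.target_r_sync**2) * rng.standard_normal(n)
    e_sn = rng.standard_normal(n)

    def outcome(name: str, e: np.ndarray) -> np.ndarray:
        return p.means[name] + z @ np.asarray(p.covariate_effects[name]) + p.noise_sds[name] * e

    cnr_lc = outcome("cnr_lc", e1)
    cnr_sn = outcome("cnr_sn", e_sn)
    rate_updrs = np.minimum(outcome("rate_updrs", e2), 0.95)
    rate_sync = outcome("rate_sync", e3)

    updrs_off = np.clip(rng.normal(25.0, 8.0, n), 5.0, None)
    updrs_on = updrs_off * (1.0 - rate_updrs)

    sync_off = np.clip(rng.normal(0.55, 0.06, n), 0.05, 0.95)
    # keep sync_on inside [0, 1]
    rate_sync = np.clip(rate_sync, 1.0 - 1.0 / sync_off, 1.0)
    sync_on = sync_off * (1.0 - rate_sync)

    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "duration_med": duration,
            "ledd": ledd,
            "cnr_lc": cnr_lc,
            "cnr_sn": cnr_sn,
            "updrs3_off": updrs_off,
            "updrs3_on": updrs_on,
            "sync_off": sync_off,
            "sync_on": sync_on,
        }
    )
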