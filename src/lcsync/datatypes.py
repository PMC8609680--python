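"""Shared domain containers for the NM-MRI / phase-synchronization pipeline.

All containers are plain dataclasses over numpy arrays.  Geometric
conventions: an :class:`ImageVolume` is indexed ``(slice, row, col)`` with the
slice axis first; in-plane ROI centers are ``(row, col)`` pixel coordinates on
a named slice.  Time-series matrices are node x time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Valid ROI labels. LC and its pontine reference (PT) live on pons slices;
#: SN subregions and the cerebral-peduncle reference (CP) on midbrain slices.
ROI_LABELS = frozenset(
    {
        "LC_left",
        "LC_right",
        "PT",
        "SN_lateral_left",
        "SN_central_left",
        "SN_medial_left",
        "SN_lateral_right",
        "SN_central_right",
        "SN_medial_right",
        "CP_left",
        "CP_right",
    }
)

#: ROI areas in mm^2: 2 for LC, 20 for the pontine reference, 10 for each SN
#: subregion, 30 for the cerebral peduncle reference.
ROI_AREA_MM2 = {
    "LC": 2.0,
    "PT": 20.0,
    "SN": 10.0,
    "CP": 30.0,
}


@dataclass
class ImageVolume:
    """A 3D scalar intensity grid with physical voxel dimensions.

    Parameters
    ----------
    intensities : ndarray, shape (n_slices, n_rows, n_cols)
        Signal intensities in arbitrary MR units.
    voxel_size : tuple of float
        Physical size per axis in mm, ordered (slice, row, col).
    slice_axis : int
        Axis indexing slices; the canonical layout puts it first.
    """

    intensities: np.ndarray
    voxel_size: tuple[float, float, float]
    slice_axis: int = 0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if min(self.intensities.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three strictly positive values")
        if self.slice_axis != 0:
            # normalize to slice-first layout once, at construction
            self.intensities = np.moveaxis(self.intensities, self.slice_axis, 0)
            vs = list(self.voxel_size)
            vs.insert(0, vs.pop(self.slice_axis))
            self.voxel_size = tuple(vs)
            self.slice_axis = 0

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[0]

    @property
    def in_plane_voxel_size(self) -> tuple[float, float]:
        """(row, col) pixel size in mm."""
        return self.voxel_size[1], self.voxel_size[2]


@dataclass(frozen=True)
class RoiSpec:
    """A circular region of interest on one slice.

    ``center`` is the (row, col) pixel coordinate of the disc center; the disc
    radius in mm is ``sqrt(area_mm2 / pi)``.
    """

    label: str
    slice_index: int
    center: tuple[float, float]
    area_mm2: float

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0:
            raise ValueError("area_mm2 must be positive")

    @property
    def radius_mm(self) -> float:
        return float(np.sqrt(self.area_mm2 / np.pi))


@dataclass(frozen=True)
class RoiStats:
    """Mean and standard deviation of signal intensity over an ROI."""

    mean_si: float
    sd_si: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")
        if self.sd_si < 0:
            raise ValueError("sd_si must be non-negative")


@dataclass
class CnrResult:
    """Per-measurement contrast-to-noise ratios and their mean.

    ``per_measurement`` rows are ``(session, side_or_subregion, slice, cnr)``;
    ``aggregate`` is their arithmetic mean (the protocol's averaged CNR).
    """

    per_measurement: list[tuple]
    aggregate: float


@dataclass
class TimeSeriesMatrix:
    """Parcellated BOLD matrix s_j(t): one row per node, one column per volume."""

    values: np.ndarray
    node_labels: list[str]
    sampling_interval: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a node x time 2D array")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 time points")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain missing or non-finite entries")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if len(self.node_labels) != self.values.shape[0]:
            raise ValueError("node_labels length must match number of rows")
        if len(set(self.node_labels)) != len(self.node_labels):
            raise ValueError("node labels must be unique")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def replace_values(self, values: np.ndarray) -> "TimeSeriesMatrix":
        return TimeSeriesMatrix(values, list(self.node_labels), self.sampling_interval)


@dataclass
class PhaseMatrix:
    """Instantaneous phases theta_j(t) in radians, wrapped to (-pi, pi]."""

    phases: np.ndarray

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.ndim != 2:
            raise ValueError("phases must be a node x time 2D array")
        if not np.all(np.isfinite(self.phases)):
            raise ValueError("phases must be finite")
        # map the closed lower end -pi onto pi so the range is (-pi, pi]
        self.phases = np.where(self.phases <= -np.pi, self.phases + 2 * np.pi, self.phases)

    @property
    def n_nodes(self) -> int:
        return self.phases.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.phases.shape[1]


@dataclass
class SyncResult:
    """Kuramoto order-parameter trace and its temporal mean.

    ``r_trace[t]`` is the modulus of the mean unit phasor across nodes at time
    t; ``mean_sync`` is its arithmetic mean over the ``n_timepoints_used``
    retained time points (L).
    """

    r_trace: np.ndarray
    mean_sync: float
    n_nodes: int
    n_timepoints_used: int

    def __post_init__(self) -> None:
        self.r_trace = np.asarray(self.r_trace, dtype=float)
        if self.r_trace.ndim != 1:
            raise ValueError("r_trace must be 1D")
        if len(self.r_trace) != self.n_timepoints_used:
            raise ValueError("n_timepoints_used must equal len(r_trace)")


@dataclass
class PartialCorrResult:
    """Partial correlation of two variables after covariate residualization."""

    r: float
    p: float
    df: int
    covariates: list[str] = field(default_factory=list)


@dataclass
class StepwiseResult:
    """Outcome of forward-selection / backward-elimination regression.

    ``selected`` is the retained predictors in entry order; ``betas`` and
    ``p_values`` come from the final fit on standardized variables; ``steps``
    is an audit log of ("enter"|"remove", name, p) events.
    """

    selected: list[str]
    betas: dict[str, float]
    p_values: dict[str, float]
    steps: list[tuple[str, str, float]]
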