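"""File interfaces: NIfTI volumes, ROI tables, TSV matrices, cohort CSV.

Conventions
-----------
* Volumes are stored as NIfTI with the voxel size on the affine diagonal,
  slice axis first.
* ROI specifications travel as CSV with columns
  ``label, slice_index, center_row, center_col, area_mm2``.
* Time-series matrices are TSV with one row per node (first column the node
  label) and one column per volume; motion traces are 6-column TSV
  (tx, ty, tz in mm, rx, ry, rz in radians).
* Cohort tables are CSV with the documented per-subject header.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import ImageVolume, RoiSpec, SyncResult, TimeSeriesMatrix

__all__ = [
    "save_volume",
    "load_volume",
    "save_rois",
    "load_rois",
    "save_timeseries",
    "load_timeseries",
    "save_motion",
    "load_motion",
    "save_cohort",
    "load_cohort",
    "save_sync_result",
]


def save_volume(volume: ImageVolume, path: str | Path) -> None:
    affine = np.diag(list(volume.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(volume.intensities, affine), str(path))


def load_volume(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return ImageVolume(np.asarray(img.dataobj, dtype=float), tuple(float(z) for z in zooms))


def save_rois(rois: list[RoiSpec], path: str | Path) -> None:
    pd.DataFrame(
        {
            "label": [r.label for r in rois],
            "slice_index": [r.slice_index for r in rois],
            "center_row": [r.center[0] for r in rois],
            "center_col": [r.center[1] for r in rois],
            "area_mm2": [r.area_mm2 for r in rois],
        }
    ).to_csv(path, index=False)


def load_rois(path: str | Path) -> list[RoiSpec]:
    df = pd.read_csv(path)
    return [
        RoiSpec(
            label=row["label"],
            slice_index=int(row["slice_index"]),
            center=(float(row["center_row"]), float(row["center_col"])),
            area_mm2=float(row["area_mm2"]),
        )
        for _, row in df.iterrows()
    ]


def save_timeseries(ts: TimeSeriesMatrix, path: str | Path) -> None:
    df = pd.DataFrame(ts.values, index=ts.node_labels)
    df.index.name = "node"
    df.to_csv(path, sep="\t")


def load_timeseries(path: str | Path, sampling_interval: float) -> TimeSeriesMatrix:
    df = pd.read_csv(path, sep="\t", index_col="node")
    return TimeSeriesMatrix(df.to_numpy(dtype=float), [str(i) for i in df.index], sampling_interval)


def save_motion(motion: np.ndarray, path: str | Path) -> None:
    cols = ["tx_mm", "ty_mm", "tz_mm", "rx_rad", "ry_rad", "rz_rad"]
    pd.DataFrame(np.asarray(motion, dtype=float), columns=cols).to_csv(path, sep="\t", index=False)


def load_motion(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


def save_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def load_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_sync_result(result: SyncResult, path: str | Path, r_trace_path: str | Path | None = None) -> None:
    """JSON summary {mean_sync, n_nodes, L}; optional per-time r(t) CSV."""
    payload = {
        "mean_sync": result.mean_sync,
        "n_nodes": result.n_nodes,
        "L": result.n_timepoints_used,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
    if r_trace_path is not None:
        pd.DataFrame({"t": np.arange(len(result.r_trace)), "r": result.r_trace}).to_csv(
            r_trace_path, index=False
        )
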