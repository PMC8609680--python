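"""Neuromelanin-MRI contrast quantification.

Quantifies locus coeruleus (LC) and substantia nigra (SN) integrity from
neuromelanin-sensitive volumes as contrast-to-noise ratios (CNR) against
nearby reference tissue:

    CNR_LC = (SI_LC - SI_PT) / SD_PT        (pontine tegmentum reference)
    CNR_SN = (SI_SN - SI_CP) / SD_CP        (cerebral peduncle reference)

where SI is the mean and SD the standard deviation of the signal intensity
over a circular ROI.  LC ROIs (2 mm^2) are placed at the in-plane position of
highest mean signal within a per-side search region, on three contiguous
slices; the averaged CNR over slices, sides and repeated assessments is the
subject-level measure.  Intra-rater reliability of repeated assessments is
summarized by an absolute-agreement intraclass correlation coefficient.
"""

from __future__ import annotations

import itertools
from collections.abc import Mapping, Sequence

import numpy as np

from .datatypes import CnrResult, ImageVolume, RoiSpec, RoiStats

__all__ = [
    "disc_pixel_offsets",
    "roi_stats",
    "locate_lc",
    "cnr",
    "aggregate_cnr_lc",
    "aggregate_cnr_sn",
    "icc_intra_rater",
]


def disc_pixel_offsets(
    radius_mm: float, pixel_size: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """(row, col) integer offsets of pixels whose centers lie strictly inside
    a disc of ``radius_mm`` centered on a pixel center.

    Membership uses the pixel-center-in-disc rule with a strict inequality,
    so the pixel set is deterministic and matches brute-force enumeration.
    """
    pr, pc = pixel_size
    max_r = int(np.floor(radius_mm / pr)) + 1
    max_c = int(np.floor(radius_mm / pc)) + 1
    dr, dc = np.meshgrid(
        np.arange(-max_r, max_r + 1), np.arange(-max_c, max_c + 1), indexing="ij"
    )
    inside = (dr * pr) ** 2 + (dc * pc) ** 2 < radius_mm**2
    return dr[inside], dc[inside]


def _roi_pixel_indices(volume: ImageVolume, roi: RoiSpec) -> tuple[np.ndarray, np.ndarray]:
    """Member pixel (row, col) indices; error if a member lies off the slice."""
    pr, pc = volume.in_plane_voxel_size
    n_rows, n_cols = volume.intensities.shape[1:]
    cr, cc = roi.center
    rad = roi.radius_mm
    rows = np.arange(int(np.ceil(cr - rad / pr)), int(np.floor(cr + rad / pr)) + 1)
    cols = np.arange(int(np.ceil(cc - rad / pc)), int(np.floor(cc + rad / pc)) + 1)
    dr2 = ((rows - cr) * pr) ** 2
    dc2 = ((cols - cc) * pc) ** 2
    mask = dr2[:, None] + dc2[None, :] < rad**2
    r_idx, c_idx = np.nonzero(mask)
    r_mem, c_mem = rows[r_idx], cols[c_idx]
    if r_mem.size and (
        r_mem.min() < 0 or r_mem.max() >= n_rows or c_mem.min() < 0 or c_mem.max() >= n_cols
    ):
        raise ValueError("ROI disc extends beyond the slice")
    return r_mem, c_mem


def roi_stats(volume: ImageVolume, roi: RoiSpec) -> RoiStats:
    """Mean and SD of signal intensity over a circular ROI.

    A pixel belongs to the ROI iff its center falls strictly within the disc
    of radius sqrt(area/pi) around the ROI center, on the ROI's slice.  SD
    uses the n-1 denominator.

    Raises
    ------
    ValueError
        If the ROI slice is out of range, the disc extends beyond the slice,
        or no pixel center falls inside the disc.
    """
    if not 0 <= roi.slice_index < volume.n_slices:
        raise ValueError(f"slice_index {roi.slice_index} outside volume")
    rows, cols = _roi_pixel_indices(volume, roi)
    if rows.size == 0:
        raise ValueError(
            "ROI contains no pixel centers (disc smaller than one pixel at this resolution)"
        )
    values = volume.intensities[roi.slice_index, rows, cols]
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return RoiStats(mean_si=float(np.mean(values)), sd_si=sd, n_pixels=int(values.size))


def locate_lc(
    volume: ImageVolume,
    search_region: Mapping[str, tuple[int, int, int, int]],
    slice_range: Sequence[int],
    area_mm2: float = 2.0,
) -> list[RoiSpec]:
    """Place the LC ROI at the highest-mean-signal position per side and slice.

    For each of three contiguous slices and each side, an exhaustive grid
    search over pixel-center placements inside that side's search region finds
    the disc of ``area_mm2`` maximizing mean intensity.  Ties are broken by
    the lexicographically smallest (row, col) center.

    Parameters
    ----------
    search_region : mapping
        ``{"left": (row_min, row_max, col_min, col_max), "right": ...}`` with
        inclusive pixel bounds; the whole disc must fit inside the box.
    slice_range : sequence of int
        Exactly 3 contiguous slice indices.

    Returns
    -------
    list of RoiSpec
        One ``LC_left`` and one ``LC_right`` ROI per slice (6 total).
    """
    slice_range = list(slice_range)
    if len(slice_range) != 3 or sorted(slice_range) != list(
        range(min(slice_range), min(slice_range) + 3)
    ):
        raise ValueError("slice_range must be exactly 3 contiguous slice indices")
    if any(not 0 <= s < volume.n_slices for s in slice_range):
        raise ValueError("slice_range outside volume")

    radius_mm = float(np.sqrt(area_mm2 / np.pi))
    dr, dc = disc_pixel_offsets(radius_mm, volume.in_plane_voxel_size)

    rois: list[RoiSpec] = []
    for s in slice_range:
        plane = volume.intensities[s]
        for side in ("left", "right"):
            rmin, rmax, cmin, cmax = search_region[side]
            # candidate centers whose full disc lies inside the box
            r_lo, r_hi = rmin - dr.min(), rmax - dr.max()
            c_lo, c_hi = cmin - dc.min(), cmax - dc.max()
            if r_hi < r_lo or c_hi < c_lo:
                raise ValueError(f"search region on side '{side}' smaller than the ROI disc")
            cand_r = np.arange(r_lo, r_hi + 1)
            cand_c = np.arange(c_lo, c_hi + 1)
            rr, cc = np.meshgrid(cand_r, cand_c, indexing="ij")
            rr, cc = rr.ravel(), cc.ravel()
            means = plane[rr[:, None] + dr, cc[:, None] + dc].mean(axis=1)
            # lexicographic tie-break: candidates are already ordered by (row, col)
            best = int(np.argmax(means))
            rois.append(
                RoiSpec(
                    label=f"LC_{side}",
                    slice_index=s,
                    center=(int(rr[best]), int(cc[best])),
                    area_mm2=area_mm2,
                )
            )
    return rois


def cnr(si_target: float, si_ref: float, sd_ref: float) -> float:
    """Contrast-to-noise ratio (SI_target - SI_ref) / SD_ref.

    Invariant under common affine intensity rescaling a*SI + b with a > 0.
    """
    if sd_ref <= 0:
        raise ValueError("sd_ref must be positive (degenerate reference region)")
    return (si_target - si_ref) / sd_ref


def aggregate_cnr_lc(
    lc_stats: Mapping[tuple[int, str, int], RoiStats],
    pt_stats: Mapping[tuple[int, int], RoiStats],
) -> CnrResult:
    """Averaged CNR_LC over 3 slices x 2 sides x S sessions.

    Parameters
    ----------
    lc_stats : mapping
        ``(session, side, slice) -> RoiStats`` for LC; every session must
        cover both sides on the same 3 slices.
    pt_stats : mapping
        ``(session, slice) -> RoiStats`` for the pontine reference; one per
        session and slice (duplicated values are accepted).
    """
    sessions = sorted({k[0] for k in lc_stats})
    slices = sorted({k[2] for k in lc_stats})
    sides = ("left", "right")
    if len(slices) != 3:
        raise ValueError(f"expected 3 slices, got {slices}")
    missing = [
        (sess, side, sl)
        for sess, side, sl in itertools.product(sessions, sides, slices)
        if (sess, side, sl) not in lc_stats
    ]
    missing_pt = [
        (sess, sl) for sess, sl in itertools.product(sessions, slices) if (sess, sl) not in pt_stats
    ]
    if missing or missing_pt:
        raise ValueError(f"missing LC cells {missing}; missing PT cells {missing_pt}")

    per = [
        (
            sess,
            side,
            sl,
            cnr(
                lc_stats[(sess, side, sl)].mean_si,
                pt_stats[(sess, sl)].mean_si,
                pt_stats[(sess, sl)].sd_si,
            ),
        )
        for sess, side, sl in itertools.product(sessions, sides, slices)
    ]
    return CnrResult(per_measurement=per, aggregate=float(np.mean([m[-1] for m in per])))


def aggregate_cnr_sn(
    sn_stats: Mapping[tuple[int, str, str], RoiStats],
    cp_stats: Mapping[tuple[int, str], RoiStats],
) -> CnrResult:
    """Averaged CNR_SN over 3 subregions x 2 sides x S sessions.

    ``sn_stats`` maps ``(session, side, subregion)`` with subregions
    {lateral, central, medial}; ``cp_stats`` maps ``(session, side)`` for the
    cerebral-peduncle reference.  Bilateral averaging is unconditional.
    """
    sessions = sorted({k[0] for k in sn_stats})
    sides = ("left", "right")
    subregions = ("lateral", "central", "medial")
    missing = [
        (sess, side, sub)
        for sess, side, sub in itertools.product(sessions, sides, subregions)
        if (sess, side, sub) not in sn_stats
    ]
    missing_cp = [
        (sess, side) for sess, side in itertools.product(sessions, sides) if (sess, side) not in cp_stats
    ]
    if missing or missing_cp:
        raise ValueError(f"missing SN cells {missing}; missing CP cells {missing_cp}")

    per = [
        (
            sess,
            f"{sub}_{side}",
            None,
            cnr(
                sn_stats[(sess, side, sub)].mean_si,
                cp_stats[(sess, side)].mean_si,
                cp_stats[(sess, side)].sd_si,
            ),
        )
        for sess, side, sub in itertools.product(sessions, sides, subregions)
    ]
    return CnrResult(per_measurement=per, aggregate=float(np.mean([m[-1] for m in per])))


def icc_intra_rater(session1: Sequence[float], session2: Sequence[float]) -> float:
    """Absolute-agreement, single-measure intraclass correlation, ICC(A,1).

    Computed from the two-way ANOVA mean squares of an n-subject x 2-session
    table:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with k = 2 sessions, MSR the between-subject, MSC the between-session and
    MSE the residual mean square.  This is the standard intra-rater
    reliability statistic for repeated assessments by the same rater.
    """
    a = np.asarray(session1, dtype=float)
    b = np.asarray(session2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("sessions must be equal-length 1D sequences")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 subjects")
    table = np.column_stack([a, b])
    k = 2
    grand = table.mean()
    subj_means = table.mean(axis=1)
    sess_means = table.mean(axis=0)
    ss_rows = k * np.sum((subj_means - grand) ** 2)
    ss_cols = n * np.sum((sess_means - grand) ** 2)
    ss_total = np.sum((table - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr <= 0:
        raise ValueError("zero between-subject variance; ICC undefined")
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))
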