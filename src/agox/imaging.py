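"""Quantification of nucleolar enrichment and foci from confocal z-stacks.

The z-stack procedure works in three steps: (1) a nuclei projection mask is
built from the per-pixel maximum of the DAPI stack and segmented; per-slice
nucleus masks are restricted to it; (2) the nucleolin channel is masked by
the nuclei projection mask and segmented the same way, and each nucleolus
is assigned to the nucleus whose projected footprint it overlaps most;
(3) signal-channel intensities are collected over nucleolar and
nucleoplasm voxels per cell, and their ratio summarized with a paired
t-test.  A separate routine max-projects a foci channel, detects
non-overlapping local maxima, and bins per-cell counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage import feature, filters, measure, morphology, segmentation

from .errors import InputError


@dataclass
class SegParams:
    """Segmentation knobs; defaults match the synthetic default resolution."""

    threshold: float | None = None  # None -> Otsu on the projection
    opening_radius: int = 2
    min_nucleus_px: int = 500  # projected-footprint area filter
    min_nucleolus_px: int = 20
    exclude_border: bool = True


@dataclass
class SegmentationResult:
    nuclei_projection_mask: np.ndarray  # 2D int labels
    nucleus_labels: np.ndarray | None = None  # 3D, per-slice, nucleus id
    nucleoli_projection_mask: np.ndarray | None = None  # 2D int labels
    nucleolus_labels: np.ndarray | None = None  # 3D, nucleolus id
    assignment: dict[int, int] = field(default_factory=dict)  # nucleolus -> nucleus

    @property
    def nucleus_ids(self) -> list[int]:
        return [int(v) for v in np.unique(self.nuclei_projection_mask) if v != 0]


@dataclass
class CellQuant:
    cell_id: int
    nucleolar_mean: float
    nucleoplasm_mean: float
    n_nucleolar_voxels: int
    n_nucleoplasm_voxels: int

    @property
    def ratio(self) -> float:
        return self.nucleolar_mean / self.nucleoplasm_mean


BIN_LABELS = ("<1", "1-5", ">5")


def focus_bin(count: int) -> str:
    """Abundance bin of a per-cell focus count: 0, 1-5, or more than 5."""
    if count < 0:
        raise InputError("negative focus count")
    if count == 0:
        return "<1"
    if count <= 5:
        return "1-5"
    return ">5"


@dataclass
class FociCount:
    cell_id: int
    count: int

    @property
    def bin(self) -> str:
        return focus_bin(self.count)


def _segment_projection(
    image2d: np.ndarray,
    params: SegParams,
    min_size: int,
    within: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Threshold + open + label a 2D image, with size and border filters."""
    if within is not None:
        values = image2d[within]
        if values.size == 0 or np.ptp(values) == 0:
            return np.zeros(image2d.shape, dtype=int), 0.0
        thr = params.threshold if params.threshold is not None else float(
            filters.threshold_otsu(values)
        )
        mask = (image2d > thr) & within
    else:
        if np.ptp(image2d) == 0:
            return np.zeros(image2d.shape, dtype=int), 0.0
        thr = params.threshold if params.threshold is not None else float(
            filters.threshold_otsu(image2d)
        )
        mask = image2d > thr
    mask = morphology.opening(mask, morphology.disk(params.opening_radius))
    if params.exclude_border and within is None:
        mask = segmentation.clear_border(mask)
    labels = measure.label(mask)
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < min_size)
    labels[np.isin(labels, small)] = 0
    labels, _, _ = segmentation.relabel_sequential(labels)
    return labels.astype(int), thr


def nuclei_mask(dapi: np.ndarray, params: SegParams | None = None) -> SegmentationResult:
    """Step 1: nuclei projection mask and per-slice nucleus labels.

    The DAPI stack is max-projected over z, thresholded (Otsu unless a
    manual threshold is given), opened, labeled, size-filtered, and
    border-touching nuclei removed.  Per slice, above-threshold pixels
    inside the projection mask inherit the projected nucleus label.
    An all-background stack yields zero labels (not an error).
    """
    dapi = np.asarray(dapi)
    if dapi.ndim != 3 or dapi.size == 0:
        raise InputError("DAPI stack must be a nonempty 3D (z, y, x) array")
    proj = dapi.max(axis=0)
    labels2d, thr = _segment_projection(proj, params or SegParams(),
                                        (params or SegParams()).min_nucleus_px)
    nucleus_labels = np.zeros(dapi.shape, dtype=int)
    for z in range(dapi.shape[0]):
        slice_mask = (dapi[z] > thr) & (labels2d > 0)
        nucleus_labels[z][slice_mask] = labels2d[slice_mask]
    return SegmentationResult(
        nuclei_projection_mask=labels2d, nucleus_labels=nucleus_labels
    )


def nucleoli_labels(
    nucleolin: np.ndarray,
    seg: SegmentationResult,
    params: SegParams | None = None,
) -> SegmentationResult:
    """Step 2: segment nucleoli inside the nuclei projection mask.

    The nucleolin channel is masked by the nuclei projection mask (noise
    outside nuclei removed), max-projected, and segmented with the same
    procedure as the nuclei but a nucleolus-scale size filter.  Each
    nucleolus is assigned to the nucleus whose projection footprint it
    overlaps most (ties: larger overlap, then lower nucleus label);
    nucleoli overlapping no nucleus are dropped.
    """
    params = params or SegParams()
    nucleolin = np.asarray(nucleolin)
    if nucleolin.ndim != 3:
        raise InputError("nucleolin stack must be 3D (z, y, x)")
    within = seg.nuclei_projection_mask > 0
    masked = nucleolin * within[None, :, :]
    proj = masked.max(axis=0)
    small_params = SegParams(
        threshold=params.threshold,
        opening_radius=max(1, params.opening_radius - 1),
        exclude_border=False,
    )
    labels2d, thr = _segment_projection(
        proj, small_params, params.min_nucleolus_px, within=within
    )
    assignment: dict[int, int] = {}
    keep = np.zeros_like(labels2d)
    for lab in np.unique(labels2d):
        if lab == 0:
            continue
        footprint = labels2d == lab
        overlap_labels = seg.nuclei_projection_mask[footprint]
        overlap_labels = overlap_labels[overlap_labels > 0]
        if overlap_labels.size == 0:
            continue
        ids, counts = np.unique(overlap_labels, return_counts=True)
        order = np.lexsort((ids, -counts))  # max overlap, then lowest id
        assignment[int(lab)] = int(ids[order[0]])
        keep[footprint] = lab
    nucleolus_labels = np.zeros(nucleolin.shape, dtype=int)
    for z in range(nucleolin.shape[0]):
        slice_mask = (masked[z] > thr) & (keep > 0)
        nucleolus_labels[z][slice_mask] = keep[slice_mask]
    seg.nucleoli_projection_mask = keep
    seg.nucleolus_labels = nucleolus_labels
    seg.assignment = assignment
    return seg


def cell_intensity(signal: np.ndarray, seg: SegmentationResult) -> list[CellQuant]:
    """Step 3: per-cell mean signal over nucleolar and nucleoplasm voxels.

    Nucleoplasm voxels are the cell's nucleus voxels not claimed by any
    nucleolus.  Cells without a detected nucleolus, or with an empty
    nucleoplasm, are skipped with a warning.
    """
    if seg.nucleus_labels is None or seg.nucleolus_labels is None:
        raise InputError("both segmentations are required")
    signal = np.asarray(signal, dtype=float)
    quants: list[CellQuant] = []
    nucleolus_any = seg.nucleolus_labels > 0
    for cell in seg.nucleus_ids:
        nucleolus_ids = [nl for nl, nuc in seg.assignment.items() if nuc == cell]
        if not nucleolus_ids:
            warnings.warn(f"cell {cell}: no nucleolus detected; skipped")
            continue
        nucleus_vox = seg.nucleus_labels == cell
        nucleolar_vox = np.isin(seg.nucleolus_labels, nucleolus_ids) & nucleus_vox
        nucleoplasm_vox = nucleus_vox & ~nucleolus_any
        if not nucleoplasm_vox.any() or not nucleolar_vox.any():
            warnings.warn(f"cell {cell}: empty compartment; skipped")
            continue
        quants.append(
            CellQuant(
                cell_id=cell,
                nucleolar_mean=float(signal[nucleolar_vox].mean()),
                nucleoplasm_mean=float(signal[nucleoplasm_vox].mean()),
                n_nucleolar_voxels=int(nucleolar_vox.sum()),
                n_nucleoplasm_voxels=int(nucleoplasm_vox.sum()),
            )
        )
    return quants


def ratio_stats(quants: list[CellQuant]) -> dict:
    """Compartment means +/- SD, mean per-cell ratio, paired t-test.

    With zero variance of the paired differences but a nonzero mean
    difference the t statistic diverges; the p-value is reported as 0.0
    with ``degenerate=True``.
    """
    if len(quants) < 2:
        raise InputError("need >=2 cells for ratio statistics")
    nucleolar = np.array([q.nucleolar_mean for q in quants])
    nucleoplasm = np.array([q.nucleoplasm_mean for q in quants])
    ratios = nucleolar / nucleoplasm
    diffs = nucleolar - nucleoplasm
    degenerate = bool(np.std(diffs, ddof=1) == 0)
    if degenerate:
        p = 0.0 if diffs.mean() != 0 else 1.0
    else:
        p = float(stats.ttest_rel(nucleolar, nucleoplasm).pvalue)
    return {
        "n_cells": len(quants),
        "nucleolar_mean": float(nucleolar.mean()),
        "nucleolar_sd": float(nucleolar.std(ddof=1)),
        "nucleoplasm_mean": float(nucleoplasm.mean()),
        "nucleoplasm_sd": float(nucleoplasm.std(ddof=1)),
        "mean_ratio": float(ratios.mean()),
        "sd_ratio": float(ratios.std(ddof=1)),
        "p_value": p,
        "degenerate": degenerate,
    }


@dataclass
class FociParams:
    tophat_radius: int = 5
    min_separation: int = 3  # "non-overlapping" foci: minimum peak distance
    threshold_abs: float | None = None  # None -> mean + 5 SD of the top-hat


def count_and_bin_foci(
    foci: np.ndarray,
    footprints: np.ndarray,
    params: FociParams | None = None,
) -> tuple[list[FociCount], dict[str, int]]:
    """Max-project a foci channel and count non-overlapping foci per cell.

    ``footprints`` is a 2D label image of cell footprints (e.g. the nuclei
    projection mask).  The projection is background-subtracted with a white
    top-hat, local maxima above a threshold and separated by at least
    ``min_separation`` pixels are detected, and maxima falling inside a
    footprint are counted for that cell.  Counts are binned 0 / 1-5 / >5.
    """
    params = params or FociParams()
    foci = np.asarray(foci, dtype=float)
    proj = foci.max(axis=0) if foci.ndim == 3 else foci
    if proj.shape != footprints.shape:
        raise InputError("foci projection and footprints differ in shape")
    tophat = morphology.white_tophat(proj, morphology.disk(params.tophat_radius))
    if params.threshold_abs is not None:
        thr = params.threshold_abs
    elif np.ptp(tophat) == 0:
        thr = np.inf  # flat image: no foci
    else:
        thr = float(tophat.mean() + 5.0 * tophat.std())
    peaks = feature.peak_local_max(
        tophat, min_distance=params.min_separation, threshold_abs=thr
    )
    counts: dict[int, int] = {
        int(c): 0 for c in np.unique(footprints) if c != 0
    }
    for (y, x) in peaks:
        cell = int(footprints[y, x])
        if cell != 0:
            counts[cell] += 1
    results = [FociCount(cell, n) for cell, n in sorted(counts.items())]
    hist = {label: 0 for label in BIN_LABELS}
    for fc in results:
        hist[fc.bin] += 1
    return results, hist
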