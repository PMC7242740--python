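"""Per-cell endpoint extraction, control normalization, and the OMI index.

The OMI index combines the three single-cell optical endpoints — optical
redox ratio, NAD(P)H tau_m, and FAD tau_m — with coefficients (1, 1, -1),
after centering each endpoint around the mean of control cells measured in
the same patient at the same timepoint.  Centering divides by the stratum
control mean and subtracts 1, so each addend is a unitless fractional
deviation and the unitless ratio can be combined with nanosecond lifetimes.
A decrease in OMI index relative to control indicates drug response.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import watershed

from .flim import LifetimeImage

log = logging.getLogger(__name__)

#: columns identifying a cell record
KEY_COLUMNS = ["patient_id", "organoid_id", "cell_id", "treatment", "timepoint_h"]
STRATUM = ["patient_id", "timepoint_h"]
OMI_ENDPOINTS = ["redox_ratio_raw", "nadph_tau_m", "fad_tau_m"]


class SegmentationOptions:
    """Hyperparameters of the simplified cytoplasm segmentation."""

    def __init__(
        self,
        smoothing_sigma: float = 2.0,
        min_area: int = 50,
        min_marker_distance: int = 5,
        interior_floor_frac: float = 0.0,
    ):
        self.smoothing_sigma = smoothing_sigma
        self.min_area = min_area
        self.min_marker_distance = min_marker_distance
        # labeled pixels darker than this fraction of the Otsu threshold are
        # treated as nuclear/lumen interior and excluded from the label
        self.interior_floor_frac = interior_floor_frac


def segment_cytoplasms(
    nadph_intensity: np.ndarray, options: SegmentationOptions | None = None
) -> np.ndarray:
    """Label individual cell cytoplasms from an NAD(P)H intensity image.

    Gaussian smoothing, global Otsu threshold, removal of small objects, and
    marker-based watershed splitting of touching cells.  Interior pixels that
    fall below the intensity threshold (hollow lumens, dark nuclei) are never
    part of the foreground and therefore excluded from every label.
    """
    opts = options or SegmentationOptions()
    img = np.asarray(nadph_intensity, dtype=float)
    if img.ndim != 2 or img.min() < 0:
        raise ValueError("expected a 2-D non-negative intensity image")
    if img.max() == 0:
        warnings.warn("blank intensity image: returning empty mask", stacklevel=2)
        return np.zeros(img.shape, dtype=np.uint16)
    smoothed = gaussian(img, sigma=opts.smoothing_sigma, preserve_range=True)
    try:
        thr = threshold_otsu(smoothed)
    except ValueError:  # constant image
        warnings.warn("constant intensity image: returning empty mask", stacklevel=2)
        return np.zeros(img.shape, dtype=np.uint16)
    fg = smoothed > thr
    components, n_comp = ndi.label(fg)
    sizes = np.bincount(components.ravel())
    fg &= sizes[components] >= opts.min_area
    if not fg.any():
        warnings.warn("no foreground above threshold: returning empty mask", stacklevel=2)
        return np.zeros(img.shape, dtype=np.uint16)
    distance = ndi.distance_transform_edt(fg)
    peaks = peak_local_max(
        distance, min_distance=opts.min_marker_distance, labels=fg, exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        markers, _ = ndi.label(fg)
    labels = watershed(-distance, markers, mask=fg)
    if opts.interior_floor_frac > 0:
        labels[smoothed < opts.interior_floor_frac * thr] = 0
    # drop labels reduced below min_area and renumber contiguously
    out = np.zeros(img.shape, dtype=np.uint16)
    next_label = 1
    for lab in np.unique(labels):
        if lab == 0:
            continue
        sel = labels == lab
        if sel.sum() >= opts.min_area:
            out[sel] = next_label
            next_label += 1
    return out


def extract_cell_endpoints(
    mask: np.ndarray,
    nadph: LifetimeImage,
    fad: LifetimeImage,
    metadata: dict | None = None,
    min_valid_pixels: int = 20,
) -> tuple[pd.DataFrame, dict]:
    """Average per-pixel endpoints over each labeled cell.

    Every endpoint is the mean over the label's valid (successfully fitted)
    pixels.  The per-cell redox ratio is the ratio of the cell's mean NAD(P)H
    intensity to its mean FAD intensity (ratio of means, not mean of pixel
    ratios).  Labels with fewer than ``min_valid_pixels`` valid pixels are
    dropped and counted in the returned report.
    """
    mask = np.asarray(mask)
    if mask.shape != nadph.valid.shape or mask.shape != fad.valid.shape:
        raise ValueError("mask and lifetime images must share a shape")
    metadata = metadata or {}
    rows = []
    dropped = 0
    for label in np.unique(mask):
        if label == 0:
            continue
        sel = mask == label
        valid = sel & nadph.valid & fad.valid
        if valid.sum() < min_valid_pixels:
            dropped += 1
            continue
        fad_int = fad.intensity[valid].mean()
        row = dict(metadata)
        row.update(
            cell_id=int(label),
            n_pixels=int(valid.sum()),
            redox_ratio_raw=nadph.intensity[valid].mean() / fad_int if fad_int > 0 else np.nan,
            nadph_tau_m=nadph.tau_m[valid].mean(),
            nadph_tau1=nadph.tau1[valid].mean(),
            nadph_tau2=nadph.tau2[valid].mean(),
            nadph_alpha1_frac=nadph.alpha1_frac[valid].mean(),
            fad_tau_m=fad.tau_m[valid].mean(),
            fad_tau1=fad.tau1[valid].mean(),
            fad_tau2=fad.tau2[valid].mean(),
            fad_alpha1_frac=fad.alpha1_frac[valid].mean(),
        )
        rows.append(row)
    if dropped:
        log.info("dropped %d cells below %d valid pixels", dropped, min_valid_pixels)
    report = {"n_cells": len(rows), "n_dropped": dropped, "min_valid_pixels": min_valid_pixels}
    return pd.DataFrame(rows), report


def _control_means(group: pd.DataFrame, columns: list[str]) -> pd.Series | None:
    controls = group[group["treatment"] == "control"]
    if controls.empty:
        return None
    return controls[columns].mean()


def normalize_to_control(cells: pd.DataFrame) -> pd.DataFrame:
    """Normalize redox ratios to the control mean of each patient/timepoint.

    Adds ``redox_ratio_norm`` (control mean = 1) and a boolean
    ``control_normalized`` flag.  Strata without control cells are flagged and
    left unnormalized (NaN); a table with no control cells anywhere is an error.
    """
    if (cells["treatment"] == "control").sum() == 0:
        raise ValueError("no control cells in the table: cannot normalize")
    out = cells.copy()
    out["redox_ratio_norm"] = np.nan
    out["control_normalized"] = False
    for key, idx in out.groupby(STRATUM).groups.items():
        group = out.loc[idx]
        means = _control_means(group, ["redox_ratio_raw"])
        if means is None:
            warnings.warn(f"stratum {key} has no control cells; left unnormalized",
                          stacklevel=2)
            continue
        out.loc[idx, "redox_ratio_norm"] = group["redox_ratio_raw"] / means["redox_ratio_raw"]
        out.loc[idx, "control_normalized"] = True
    return out


def omi_index(cells: pd.DataFrame) -> pd.DataFrame:
    """Compute the per-cell OMI index with coefficients (1, 1, -1).

    Within each (patient, timepoint) stratum each of redox ratio, NAD(P)H
    tau_m, and FAD tau_m is divided by its control mean and then has 1
    subtracted; the OMI index is ``(+1) redox + (+1) NAD(P)H tau_m
    + (-1) FAD tau_m`` of these centered values.  Control cells average to an
    OMI index of exactly 0 within every stratum.
    """
    if (cells["treatment"] == "control").sum() == 0:
        raise ValueError("no control cells in the table: cannot center")
    out = cells.copy()
    out["omi_index"] = np.nan
    for key, idx in out.groupby(STRATUM).groups.items():
        group = out.loc[idx]
        means = _control_means(group, OMI_ENDPOINTS)
        if means is None:
            warnings.warn(f"stratum {key} has no control cells; OMI index undefined",
                          stacklevel=2)
            continue
        centered = group[OMI_ENDPOINTS] / means - 1.0
        out.loc[idx, "omi_index"] = (
            centered["redox_ratio_raw"] + centered["nadph_tau_m"] - centered["fad_tau_m"]
        )
    return out
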