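"""Apparent tissue sodium content (aTSC) quantification.

Converts (partial-volume-corrected) signal images into concentration maps:
coil-sensitivity correction, relaxation correction, linear calibration
against reference phantoms of known concentration, region-wise map scaling
for the region-level corrections, and ROI statistics.

The correction order is fixed: partial volume correction first, then
sensitivity correction, then calibration — partial volume effects act on
the measurable (sensitivity-weighted) signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import binary_erosion

from .core import RelaxationTimes
from .phantom import relaxation_weight

__all__ = [
    "CalibrationFit",
    "RoiReport",
    "sensitivity_correct",
    "relaxation_correct",
    "calibrate",
    "to_atsc",
    "regionwise_map",
    "roi_statistics",
    "reference_means",
]


@dataclass(frozen=True)
class CalibrationFit:
    """Ordinary least squares fit ``signal = slope·concentration + intercept``."""

    slope: float
    intercept: float
    concentrations: Tuple[float, ...]
    residual_norm: float

    def __post_init__(self) -> None:
        if len(self.concentrations) >= 2 and not all(
            b > a for a, b in zip(self.concentrations, self.concentrations[1:])
        ):
            raise ValueError("reference concentrations must be strictly increasing")


@dataclass
class RoiReport:
    """Per-ROI aTSC mean ± SD (mM) plus the combined whole-tendon value."""

    sections: Dict[str, Tuple[float, float, int]]  # name -> (mean, sd, n)
    combined: Optional[Tuple[float, float]] = None  # (value, sd across ROI)

    def to_frame(self):
        import pandas as pd

        rows = {
            name: {"mean_mM": m, "sd_mM": s, "n_voxels": n}
            for name, (m, s, n) in self.sections.items()
        }
        if self.combined is not None:
            rows["combined"] = {
                "mean_mM": self.combined[0],
                "sd_mM": self.combined[1],
                "n_voxels": sum(n for *_, n in self.sections.values()),
            }
        return pd.DataFrame(rows).T


def sensitivity_correct(
    image: np.ndarray,
    sensitivity: np.ndarray,
    floor: float = 0.05,
) -> Tuple[np.ndarray, np.ndarray]:
    """Divide by the normalised coil sensitivity.

    Returns the corrected image and a validity mask; voxels with
    sensitivity below ``floor`` (deep, poorly measurable tissue) are left
    unscaled and flagged invalid.
    """

    image = np.asarray(image, dtype=float)
    sens = np.asarray(sensitivity, dtype=float)
    if sens.shape != image.shape:
        raise ValueError("sensitivity grid does not match the image")
    m = sens.max()
    if m <= 0:
        raise ValueError("sensitivity must contain positive values")
    if m > 1.0:  # maps with max <= 1 are taken as already normalised
        sens = sens / m
    valid = sens >= floor
    if not valid.any():
        raise ValueError("all voxels fall below the sensitivity floor")
    out = image.copy()
    out[valid] = image[valid] / sens[valid]
    return out, valid


def relaxation_correct(signal, relax: RelaxationTimes, tr: float, te: float):
    """Divide out the relaxation weighting of a tissue (scalar or array)."""
    w = relaxation_weight(relax, tr, te)
    if w <= 0:
        raise ValueError("relaxation weight must be positive")
    return np.asarray(signal, dtype=float) / w if np.ndim(signal) else float(signal) / w


def calibrate(
    reference_signals: Sequence[float],
    reference_concentrations: Sequence[float],
) -> CalibrationFit:
    """Fit reference-phantom signals linearly to their known concentrations."""

    sig = np.asarray(reference_signals, dtype=float)
    conc = np.asarray(reference_concentrations, dtype=float)
    if sig.size != conc.size or sig.size < 2:
        raise ValueError("at least two matched reference measurements are required")
    if np.unique(conc).size < 2:
        raise ValueError("reference concentrations must not be identical")
    design = np.stack([conc, np.ones_like(conc)], axis=1)
    (slope, intercept), res, *_ = np.linalg.lstsq(design, sig, rcond=None)
    residual = float(np.sqrt(res[0])) if res.size else 0.0
    return CalibrationFit(
        float(slope), float(intercept), tuple(np.sort(conc)), residual
    )


def to_atsc(signal, fit: CalibrationFit):
    """Invert the calibration: ``aTSC = (signal - intercept) / slope`` (mM).

    Negative concentrations are reported with a warning, never clamped.
    """

    if fit.slope <= 0:
        raise ValueError("calibration slope must be positive")
    out = (np.asarray(signal, dtype=float) - fit.intercept) / fit.slope
    if np.any(out < 0):
        warnings.warn("negative aTSC values produced", stacklevel=2)
    return out if np.ndim(signal) else float(out)


def regionwise_map(
    image: np.ndarray,
    roi_mask: np.ndarray,
    corrected_mean: float,
    uncorrected_mean: float,
) -> np.ndarray:
    """Turn a region-level correction into a map: scale every ROI voxel by
    ``corrected_mean / uncorrected_mean``, preserving the within-ROI
    relative pattern."""

    if uncorrected_mean == 0:
        raise ValueError("uncorrected mean must be non-zero")
    roi = np.asarray(roi_mask, dtype=bool)
    out = np.asarray(image, dtype=float).copy()
    out[roi] *= corrected_mean / uncorrected_mean
    return out


def reference_means(
    image: np.ndarray,
    reference_masks: Mapping[float, np.ndarray],
    erosion: int = 0,
) -> Tuple[list, list]:
    """Mean signal of each reference phantom over its mask.

    The full segmentation mask is used by default, so an uncorrected
    reference carries its own partial volume deficit — the mechanism that
    inflates uncorrected concentration estimates.  Optional erosion
    (falling back to the full mask when erosion would empty it) measures a
    less contaminated interior instead.  Returns (concentrations, means)
    sorted by concentration.
    """

    concs = sorted(reference_masks)
    means = []
    for c in concs:
        mask = np.asarray(reference_masks[c], dtype=bool)
        if erosion > 0:
            er = binary_erosion(mask, iterations=erosion)
            if er.any():
                mask = er
        if not mask.any():
            raise ValueError(f"reference mask for {c} mM is empty")
        means.append(float(np.asarray(image, dtype=float)[mask].mean()))
    return list(concs), means


def roi_statistics(
    atsc_map: np.ndarray,
    section_masks: Mapping[str, np.ndarray],
    combined: Optional[Tuple[float, float]] = None,
) -> RoiReport:
    """Mean ± SD of the aTSC map over each tendon section.

    The combined whole-tendon value is *not* the average of the section
    means: it is computed upstream from the average signal and average
    relaxation times of the entire tendon and passed in via ``combined``.
    """

    sections: Dict[str, Tuple[float, float, int]] = {}
    atsc_map = np.asarray(atsc_map, dtype=float)
    for name, mask in section_masks.items():
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError(f"section {name!r} is empty")
        vals = atsc_map[mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"section {name!r} has no valid aTSC voxels")
        sections[name] = (float(vals.mean()), float(vals.std()), int(vals.size))
    return RoiReport(sections=sections, combined=combined)
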