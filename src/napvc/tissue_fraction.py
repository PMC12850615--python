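"""Tissue-fraction partial volume corrections: PSSR and 3D-mLTS.

Two corrections for intravoxel signal averaging on coarse grids:

* **PSSR** (proton-to-sodium segmentation ratio) corrects a region mean
  using the volume ratio between a high-resolution segmentation and its
  downsized version, subtracting the signal contribution of the immediate
  surroundings: ``C = S_m - S_sur (1 - v_PS)/v_PS``.
* **3D-mLTS** recovers per-tissue intensities voxel-by-voxel by least
  trimmed squares regression of the measured signal on per-tissue volume
  fraction maps inside a 3×3×3 kernel, iteratively discarding the 40% of
  kernel samples with the largest residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import binary_dilation

from .core import LabelMap, VolumeGrid
from .phantom import block_downsample

__all__ = [
    "RegionMeasurement",
    "FractionMaps",
    "MLTSResult",
    "volume_ratio",
    "surrounding_mean",
    "pssr_correct",
    "fraction_maps",
    "mlts_correct",
]


@dataclass(frozen=True)
class RegionMeasurement:
    """Inputs of the PSSR correction for one region of interest."""

    s_m: float
    s_sur: float
    v_ps: float

    def __post_init__(self) -> None:
        if self.s_m < 0:
            raise ValueError("measured ROI signal must be non-negative")
        if self.v_ps <= 0:
            raise ValueError("volume ratio v_PS must be positive")


def volume_ratio(
    highres_mask: np.ndarray,
    lowres_mask: np.ndarray,
    highres_voxel: float,
    lowres_voxel: float,
) -> float:
    """Physical volume ratio of a high-resolution mask to its low-resolution
    counterpart (``v_PS``); warns when the ratio exceeds 1."""

    hr = np.asarray(highres_mask, dtype=bool)
    lr = np.asarray(lowres_mask, dtype=bool)
    if not hr.any() or not lr.any():
        raise ValueError("both masks must be non-empty")
    v = (hr.sum() * highres_voxel**3) / (lr.sum() * lowres_voxel**3)
    if v > 1.0:
        warnings.warn(
            "v_PS exceeds 1: the low-resolution mask is smaller than the "
            "high-resolution content",
            stacklevel=2,
        )
    return float(v)


def surrounding_mean(image: np.ndarray, roi_mask: np.ndarray) -> float:
    """Mean signal of the one-voxel 26-connected shell around an ROI."""

    roi = np.asarray(roi_mask, dtype=bool)
    if not roi.any():
        raise ValueError("ROI mask must be non-empty")
    shell = binary_dilation(roi, structure=np.ones((3, 3, 3), dtype=bool)) & ~roi
    if not shell.any():
        raise ValueError("surrounding shell is empty")
    return float(np.asarray(image, dtype=float)[shell].mean())


def pssr_correct(meas: RegionMeasurement) -> float:
    """PSSR-corrected region mean ``C = S_m - S_sur (1 - v_PS)/v_PS``.

    With ``v_PS = 1`` (no extra volume) this returns ``S_m``; with zero
    surrounding signal it reduces to the original single-compartment form.
    Negative results are reported with a warning, never clamped.
    """

    c = meas.s_m - meas.s_sur * (1.0 - meas.v_ps) / meas.v_ps
    if c < 0:
        warnings.warn("PSSR produced a negative corrected signal", stacklevel=2)
    return float(c)


# ---------------------------------------------------------------------------
# Fraction maps and 3D-mLTS
# ---------------------------------------------------------------------------


@dataclass
class FractionMaps:
    """Per-tissue volume fractions on the low-resolution grid.

    Fractions form a partition of unity at every voxel (the background
    label 0 is included as its own class).
    """

    fractions: Dict[int, np.ndarray]
    factor: int
    voxel_size: float

    @property
    def labels(self) -> Sequence[int]:
        return sorted(self.fractions)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return next(iter(self.fractions.values())).shape

    def stacked(self, labels: Optional[Sequence[int]] = None) -> np.ndarray:
        labels = list(labels if labels is not None else self.labels)
        return np.stack([self.fractions[lab] for lab in labels], axis=-1)

    def dominant_label(self) -> np.ndarray:
        labs = self.labels
        stack = self.stacked(labs)
        return np.asarray(labs)[np.argmax(stack, axis=-1)]


def fraction_maps(label_map: LabelMap, factor: int) -> FractionMaps:
    """Share of each tissue class inside every low-resolution voxel."""

    factor = int(factor)
    labs = [0] + label_map.labels_present()
    fractions: Dict[int, np.ndarray] = {}
    for lab in labs:
        mask = (label_map.labels == lab).astype(float)
        fractions[lab] = block_downsample(
            VolumeGrid(mask, label_map.voxel_size), factor
        ).values
    return FractionMaps(fractions, factor, label_map.voxel_size * factor)


@dataclass
class MLTSResult:
    """Fitted per-tissue intensities of the 3D-mLTS regression."""

    intensities: Dict[int, np.ndarray]  # NaN where the tissue is absent
    corrected: np.ndarray  # dominant-tissue intensity per voxel
    valid: np.ndarray  # False where the design was rank deficient
    rank_fallback: np.ndarray  # untrimmed-fit fallback flags
    converged: np.ndarray
    mask: np.ndarray
    labels: Sequence[int] = field(default_factory=list)


def _neighbourhood(arr: np.ndarray, offsets: np.ndarray, pad: int) -> np.ndarray:
    """Stacked kernel samples: output[..., j] = arr shifted by offsets[j]."""
    padded = np.pad(arr, pad, mode="constant", constant_values=np.nan)
    views = [
        padded[
            pad + dx : pad + dx + arr.shape[0],
            pad + dy : pad + dy + arr.shape[1],
            pad + dz : pad + dz + arr.shape[2],
        ]
        for dx, dy, dz in offsets
    ]
    return np.stack(views, axis=-1)


def mlts_correct(
    image: np.ndarray | VolumeGrid,
    fractions: FractionMaps,
    trimming: float = 0.4,
    kernel: int = 3,
    max_iter: int = 25,
    mask: Optional[np.ndarray] = None,
) -> MLTSResult:
    """3D modified least-trimmed-squares tissue-fraction correction.

    At every voxel the ``kernel³`` neighbourhood samples ``y_j`` are modelled
    as ``y_j = Σ_i f_i(j) T_i`` with locally constant tissue intensities
    ``T_i``.  Starting from the full-kernel least-squares fit, the
    ``h = round((1-trimming)·n)`` samples with the smallest residuals are
    retained and the fit repeated until the retained subset is stable.
    Kernels are clipped at the grid boundary (``n`` shrinks); ties in the
    residual ranking are broken by kernel sample order, which makes the
    iteration deterministic.

    Rank-deficient trimmed designs fall back to the untrimmed fit (flagged);
    voxels that remain deficient are marked invalid.  Negative fitted
    intensities are kept, mirroring the PSSR behaviour.

    ``mask`` restricts the computation to a subset of voxels (e.g. the
    voxels containing tendon); other voxels carry NaN intensities.
    """

    values = image.values if isinstance(image, VolumeGrid) else np.asarray(image)
    values = values.astype(float)
    if values.shape != fractions.shape:
        raise ValueError("image grid does not match the fraction maps")
    if not 0.0 <= trimming < 1.0:
        raise ValueError("trimming must lie in [0, 1)")
    if kernel % 2 != 1 or kernel < 1:
        raise ValueError("kernel must be an odd positive integer")

    labels = list(fractions.labels)
    pad = kernel // 2
    offs = np.array(
        [
            (dx, dy, dz)
            for dx in range(-pad, pad + 1)
            for dy in range(-pad, pad + 1)
            for dz in range(-pad, pad + 1)
        ]
    )
    n_samples = len(offs)

    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != values.shape:
            raise ValueError("mask grid does not match the image")

    y_all = _neighbourhood(values, offs, pad)[mask]  # (M, n)
    f_all = np.stack(
        [_neighbourhood(fractions.fractions[lab], offs, pad)[mask] for lab in labels],
        axis=-1,
    )  # (M, n, T)
    in_grid = np.isfinite(y_all)
    y_all = np.nan_to_num(y_all)
    f_all = np.nan_to_num(f_all)

    M = y_all.shape[0]
    n_valid = in_grid.sum(axis=1)
    present = f_all.sum(axis=1) > 1e-12  # (M, T) tissue appears in kernel
    n_present = present.sum(axis=1)
    h = np.round((1.0 - trimming) * n_valid).astype(int)
    h = np.maximum(h, np.maximum(n_present, 1))
    h = np.minimum(h, n_valid)

    def _fit(weights: np.ndarray):
        # weighted normal equations, solved by pseudo-inverse (absent
        # tissues contribute zero rows/columns -> min-norm coefficient 0)
        a = np.einsum("mnt,mn,mnu->mtu", f_all, weights, f_all)
        b = np.einsum("mnt,mn,mn->mt", f_all, weights, y_all)
        coef = np.einsum("mtu,mu->mt", np.linalg.pinv(a, rcond=1e-10), b)
        return a, coef

    w = in_grid.astype(float)
    _, coef = _fit(w)
    converged = np.zeros(M, dtype=bool)
    for _ in range(max_iter):
        resid = np.where(in_grid, (y_all - np.einsum("mnt,mt->mn", f_all, coef)) ** 2, np.inf)
        order = np.argsort(resid, axis=1, kind="stable")
        ranks = np.empty_like(order)
        np.put_along_axis(ranks, order, np.arange(n_samples)[None, :], axis=1)
        w_new = (ranks < h[:, None]).astype(float) * in_grid
        stable = np.all(w_new == w, axis=1)
        converged |= stable
        if stable.all():
            break
        w = w_new
        _, coef = _fit(w)

    # rank diagnostics on the final (trimmed) design: the fit is deficient
    # only if it cannot resolve the tissues actually represented in the
    # retained subset (tissues trimmed out entirely are fine — the
    # pseudo-inverse returns their minimum-norm zero coefficient)
    a_final, _ = _fit(w)
    present_trim = np.einsum("mnt,mn->mt", f_all, w) > 1e-12
    n_present_trim = present_trim.sum(axis=1)
    svals = np.linalg.svd(a_final, compute_uv=False)
    rank = (svals > svals[:, :1] * 1e-8).sum(axis=1)
    deficient = rank < n_present_trim
    rank_fallback = deficient.copy()
    valid_rows = np.ones(M, dtype=bool)
    if deficient.any():
        # grow the retained subset in residual order until the design can
        # resolve its tissues; outliers (largest residuals) re-enter last
        resid_fin = np.where(
            in_grid, (y_all - np.einsum("mnt,mt->mn", f_all, coef)) ** 2, np.inf
        )
        for m in np.nonzero(deficient)[0]:
            order_m = np.argsort(resid_fin[m], kind="stable")
            solved = False
            for hh in range(int(h[m]) + 1, int(n_valid[m]) + 1):
                keep = order_m[:hh]
                x = f_all[m][keep]
                pres = x.sum(axis=0) > 1e-12
                a = x.T @ x
                s = np.linalg.svd(a, compute_uv=False)
                if (s > s[0] * 1e-8).sum() >= pres.sum():
                    coef[m] = np.linalg.pinv(a, rcond=1e-10) @ (
                        x.T @ y_all[m][keep]
                    )
                    present_trim[m] = pres
                    solved = True
                    break
            if not solved:
                valid_rows[m] = False

    # scatter the per-voxel results back onto the grid; a tissue without
    # samples in the subset that produced the fit has no estimate (NaN)
    present_eff = np.where(deficient[:, None], present, present_trim)
    intensities = {}
    for t, lab in enumerate(labels):
        vol = np.full(values.shape, np.nan)
        col = coef[:, t].copy()
        col[~present_eff[:, t]] = np.nan
        vol[mask] = col
        intensities[lab] = vol

    frac_here = fractions.stacked(labels)[mask]  # (M, T)
    dominant = np.argmax(frac_here, axis=1)
    rows = np.arange(M)
    corrected = values.copy()
    corrected[mask] = coef[rows, dominant]
    # the reported value is meaningless if the dominant tissue is absent
    # from the samples that produced the fit
    dom_ok = np.where(
        deficient, present[rows, dominant], present_trim[rows, dominant]
    )
    valid_rows = valid_rows & dom_ok

    def scatter(flags: np.ndarray, fill: bool) -> np.ndarray:
        out = np.full(values.shape, fill, dtype=bool)
        out[mask] = flags
        return out

    return MLTSResult(
        intensities=intensities,
        corrected=corrected,
        valid=scatter(valid_rows, True),
        rank_fallback=scatter(rank_fallback, False),
        converged=scatter(converged, True),
        mask=mask,
        labels=labels,
    )
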