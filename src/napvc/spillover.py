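"""Spill-over partial volume corrections: GTM, STC and eSTC.

All three methods are built on region spread functions (RSF): the
convolution of a compartment mask with that compartment's PSF, which
quantifies where the compartment's signal lands in the image.

* **GTM** (geometric transfer matrix) accumulates the inter-region spill
  fractions into a matrix ``W_ij = mean over mask i of RSF_j`` and recovers
  region mean intensities by solving ``W T = m``.
* **STC** (single target correction) corrects voxel-wise between one target
  and its surroundings: the cross-spilled signal (estimate convolved with
  the other compartment's PSF) is subtracted and the result divided by the
  recovery factor ``R = Σ_i m_i·(m_i * PSF_i)``, iterating to convergence.
  Negative voxels are replaced by their nearest positive neighbour each
  iteration.  A period-2 steady state is detected and reported as an
  oscillation with both states.
* **eSTC** (estimated single target correction) replaces the iteration by a
  single sweep: compartment signals are first *estimated* by dividing the
  masked image by the compartment RSF and repairing the overestimated edge
  voxels with an erode-and-refill operator, then each compartment is
  corrected once by subtracting all estimated spill-in contributions and
  dividing by its RSF, updating estimates from large to small compartments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.fft import irfftn, next_fast_len, rfftn
from scipy.ndimage import binary_erosion, distance_transform_edt, generate_binary_structure

from .core import SequenceParams, TissueSpec
from .psf import PSFKernel, mixed_voxel_relaxation, simulate_psf

__all__ = [
    "CompartmentSet",
    "CorrectionResult",
    "build_rsf",
    "gtm_correct",
    "stc_correct",
    "erode_and_fill",
    "estc_correct",
    "surround_psf",
]


class _Convolver:
    """FFT convolution with a cached kernel transform ('same', zero-padded)."""

    def __init__(self, kernel: np.ndarray, shape: Tuple[int, ...]):
        self.kernel_shape = kernel.shape
        self.shape = shape
        self.fshape = [next_fast_len(s + k - 1) for s, k in zip(shape, kernel.shape)]
        self.kf = rfftn(kernel, self.fshape)

    def __call__(self, volume: np.ndarray) -> np.ndarray:
        full = irfftn(rfftn(volume, self.fshape) * self.kf, self.fshape)
        starts = [(k - 1) // 2 for k in self.kernel_shape]
        slices = tuple(
            slice(st, st + s) for st, s in zip(starts, self.shape)
        )
        return full[slices].copy()


def build_rsf(mask: np.ndarray, psf: PSFKernel, masked: bool = False) -> np.ndarray:
    """Region spread function of a compartment.

    Full-field by default (``mask * PSF`` everywhere); with ``masked=True``
    restricted to the compartment (``m·(m * PSF)``) as used by the recovery
    factor.  The PSF must have unit DC gain.
    """

    mask = np.asarray(mask, dtype=bool)
    if abs(psf.values.sum() - 1.0) > 1e-6:
        raise ValueError("PSF must be normalised to unit sum")
    conv = _Convolver(psf.values, mask.shape)
    rsf = conv(mask.astype(float))
    if masked:
        rsf = np.where(mask, rsf, 0.0)
    return rsf


@dataclass
class CompartmentSet:
    """Ordered disjoint compartments with their PSFs and derived RSFs.

    ``surround_index`` designates the compartment treated as "surroundings"
    by STC/eSTC.  RSFs and the recovery factor ``R`` are computed on
    construction; convolvers with cached kernel FFTs are reused by all
    corrections.
    """

    masks: List[np.ndarray]
    psfs: List[PSFKernel]
    names: Optional[Sequence[str]] = None
    surround_index: Optional[int] = None
    rsf_floor: float = 0.05
    rsfs_full: List[np.ndarray] = field(init=False)
    rsfs_masked: List[np.ndarray] = field(init=False)
    recovery: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if len(self.masks) < 2:
            raise ValueError("at least two compartments are required")
        if len(self.masks) != len(self.psfs):
            raise ValueError("one PSF per compartment is required")
        self.masks = [np.asarray(m, dtype=bool) for m in self.masks]
        shape = self.masks[0].shape
        overlap = np.zeros(shape, dtype=np.int16)
        for m in self.masks:
            if m.shape != shape:
                raise ValueError("compartment masks must share one grid")
            if not m.any():
                raise ValueError("compartment masks must be non-empty")
            overlap += m
        if (overlap > 1).any():
            raise ValueError("compartment masks must be pairwise disjoint")
        if self.names is None:
            self.names = [f"compartment_{i}" for i in range(len(self.masks))]
        self._convolvers = [
            _Convolver(psf.values, shape) for psf in self.psfs
        ]
        self.rsfs_full = [
            conv(m.astype(float)) for conv, m in zip(self._convolvers, self.masks)
        ]
        self.rsfs_masked = [
            np.where(m, r, 0.0) for m, r in zip(self.masks, self.rsfs_full)
        ]
        self.recovery = np.sum(self.rsfs_masked, axis=0)

    @property
    def n(self) -> int:
        return len(self.masks)

    @property
    def union(self) -> np.ndarray:
        return np.any(self.masks, axis=0)

    def convolve(self, i: int, volume: np.ndarray) -> np.ndarray:
        """Convolve a volume with compartment ``i``'s PSF."""
        return self._convolvers[i](volume)


@dataclass
class CorrectionResult:
    """Corrected image (or region means) plus convergence diagnostics."""

    image: Optional[np.ndarray]
    method: str
    iterations: int = 0
    converged: bool = True
    oscillating: bool = False
    states: Optional[Tuple[np.ndarray, np.ndarray]] = None
    region_means: Optional[Dict[str, float]] = None
    flags: Dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# GTM
# ---------------------------------------------------------------------------


def gtm_correct(
    image: np.ndarray,
    compartments: CompartmentSet,
    cond_threshold: float = 1e8,
) -> CorrectionResult:
    """Region-wise geometric transfer matrix correction.

    Exact for piecewise-constant images blurred with the compartments' own
    PSFs.  A severely ill-conditioned transfer matrix (near-duplicate
    compartments) raises an error suggesting compartment merging.
    """

    image = np.asarray(image, dtype=float)
    n = compartments.n
    w = np.empty((n, n))
    m = np.empty(n)
    for i, mask in enumerate(compartments.masks):
        m[i] = image[mask].mean()
        for j in range(n):
            w[i, j] = compartments.rsfs_full[j][mask].mean()
    cond = np.linalg.cond(w)
    if not np.isfinite(cond) or cond > cond_threshold:
        raise np.linalg.LinAlgError(
            f"geometric transfer matrix is ill-conditioned (cond={cond:.3g}); "
            "consider merging near-duplicate compartments"
        )
    t = np.linalg.solve(w, m)
    means = {name: float(v) for name, v in zip(compartments.names, t)}
    res = CorrectionResult(image=None, method="gtm", region_means=means)
    res.flags["transfer_matrix"] = w
    return res


# ---------------------------------------------------------------------------
# Nearest-neighbour replacement helpers
# ---------------------------------------------------------------------------


def _fill_from_source(
    values: np.ndarray, targets: np.ndarray, source: np.ndarray
) -> np.ndarray:
    """Replace ``targets`` voxels by the value of the nearest ``source``
    voxel (Euclidean distance; equidistant ties resolved by the distance
    transform's deterministic scan order)."""

    if not source.any() or not targets.any():
        return values
    idx = distance_transform_edt(~source, return_distances=False, return_indices=True)
    out = values.copy()
    out[targets] = values[tuple(axis_idx[targets] for axis_idx in idx)]
    return out


def _replace_negatives(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Non-negativity step: negative voxels inside ``mask`` take the value
    of their nearest positive neighbour inside the mask."""

    neg = mask & (values < 0)
    if not neg.any():
        return values
    pos = mask & (values > 0)
    if not pos.any():
        return np.where(neg, 0.0, values)
    return _fill_from_source(values, neg, pos)


# ---------------------------------------------------------------------------
# STC
# ---------------------------------------------------------------------------


def stc_correct(
    image: np.ndarray,
    compartments: CompartmentSet,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> CorrectionResult:
    """Iterative voxel-wise single target correction (two compartments).

    Each iteration subtracts the cross-spilled signal between target and
    surroundings (current estimate convolved with the spilling
    compartment's PSF, masked to the receiving compartment), divides by the
    recovery factor ``R`` and enforces non-negativity.  Convergence is
    declared when the maximum relative voxel change falls below ``tol``; a
    state matching the state two iterations back (but not the previous one)
    flags a period-2 oscillation and both states are returned.
    """

    if compartments.n != 2:
        raise ValueError("STC is defined for exactly two compartments")
    image = np.asarray(image, dtype=float)
    union = compartments.union
    r = compartments.recovery
    low_r = union & (r < compartments.rsf_floor)
    if low_r.all():
        raise ValueError("recovery factor is zero across the compartments")
    safe_r = np.where(union & ~low_r, r, 1.0)

    m0, m1 = compartments.masks
    est = image.copy()
    prev: Optional[np.ndarray] = None
    it = 0
    converged = False
    oscillating = False
    states: Optional[Tuple[np.ndarray, np.ndarray]] = None
    # numerical-scale guard so near-zero voxels do not dominate the
    # relative-change criterion
    eps = 1e-6 * float(np.abs(image[union]).mean()) + 1e-12

    def rel_diff(a: np.ndarray, b: np.ndarray) -> float:
        d = np.abs(a - b) / (np.abs(b) + eps)
        return float(d[union & ~low_r].max())

    for it in range(1, max_iter + 1):
        spill_0 = compartments.convolve(0, np.where(m0, est, 0.0))
        spill_1 = compartments.convolve(1, np.where(m1, est, 0.0))
        new = image - np.where(m1, spill_0, 0.0) - np.where(m0, spill_1, 0.0)
        new = np.where(union, new / safe_r, image)
        new = _replace_negatives(new, union)
        if rel_diff(new, est) < tol:
            est = new
            converged = True
            break
        if prev is not None and rel_diff(new, prev) < tol:
            oscillating = True
            states = (est.copy(), new.copy())
            est = 0.5 * (est + new)  # labelled convenience mean of both states
            break
        prev = est
        est = new

    result = CorrectionResult(
        image=est,
        method="stc",
        iterations=it,
        converged=converged,
        oscillating=oscillating,
        states=states,
    )
    result.flags["low_recovery"] = low_r
    return result


# ---------------------------------------------------------------------------
# eSTC
# ---------------------------------------------------------------------------


def erode_and_fill(
    volume: np.ndarray, mask: np.ndarray, depth: int = 1
) -> Tuple[np.ndarray, bool]:
    """Edge-repair operator ``r``: erode the mask and refill the lost edge
    voxels with the value of their nearest surviving voxel.

    Used by eSTC to discard the edge voxels that RSF division
    overestimates.  If erosion empties the mask the values are returned
    unchanged with a fallback flag (small compartments keep their uneroded
    values at reduced accuracy).  Voxels outside the mask are untouched.
    """

    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask must be non-empty")
    structure = generate_binary_structure(3, 1)  # 6-connectivity
    eroded = binary_erosion(mask, structure=structure, iterations=depth)
    if not eroded.any():
        return volume.copy(), True
    ring = mask & ~eroded
    return _fill_from_source(volume, ring, eroded), False


def estc_correct(
    image: np.ndarray,
    compartments: CompartmentSet,
    erosion_depth: int = 1,
) -> CorrectionResult:
    """Single-pass estimated single target correction.

    1. Estimate the surrounding signal ``E_sur = r(m_sur·S / RSF_sur)``.
    2. Estimate every target ``E_i = r((S_i - m_i·(E_sur*PSF_sur)) / RSF_i)``.
    3. Sweep all compartments from largest to smallest:
       ``C_i = (S_i - Σ_{j≠i} m_i·(E_j*PSF_j)) / RSF_i``, replace negative
       voxels by their nearest non-negative neighbour and update
       ``E_i = r(C_i)`` before correcting the next compartment.

    Divisions use the mask-restricted RSF; voxels with RSF below the floor
    are flagged and later repaired by the edge refill.  No iteration is
    required.
    """

    if compartments.surround_index is None:
        raise ValueError("a surround compartment must be designated for eSTC")
    image = np.asarray(image, dtype=float)
    s_idx = compartments.surround_index
    n = compartments.n
    floor = compartments.rsf_floor
    low_flags = np.zeros(image.shape, dtype=bool)
    fallback_flags: Dict[str, bool] = {}

    def rsf_divide(num: np.ndarray, i: int) -> np.ndarray:
        rsf = compartments.rsfs_masked[i]
        mask = compartments.masks[i]
        ok = mask & (rsf >= floor)
        low = mask & ~ok
        if low.all():
            raise ValueError(
                f"RSF of {compartments.names[i]!r} is below the floor everywhere"
            )
        low_flags[low] = True
        out = np.zeros_like(num)
        out[ok] = num[ok] / rsf[ok]
        if low.any():  # repair edge voxels from the valid interior
            out = _fill_from_source(out, low, ok)
        return out

    def repair(vals: np.ndarray, i: int) -> np.ndarray:
        repaired, fb = erode_and_fill(vals, compartments.masks[i], depth=erosion_depth)
        fallback_flags[str(compartments.names[i])] = fb
        return repaired

    # step 1: surround estimate
    estimates: List[Optional[np.ndarray]] = [None] * n
    masked_image = [np.where(m, image, 0.0) for m in compartments.masks]
    estimates[s_idx] = repair(rsf_divide(masked_image[s_idx], s_idx), s_idx)

    # step 2: initial target estimates from surround spill-in
    sur_spill = compartments.convolve(s_idx, estimates[s_idx])
    for i in range(n):
        if i == s_idx:
            continue
        num = masked_image[i] - np.where(compartments.masks[i], sur_spill, 0.0)
        estimates[i] = repair(rsf_divide(num, i), i)

    # step 3: single sweep from the largest to the smallest compartment
    sizes = [int(m.sum()) for m in compartments.masks]
    order = sorted(range(n), key=lambda i: (-sizes[i], i))
    spills = [compartments.convolve(j, estimates[j]) for j in range(n)]
    corrected = image.copy()
    for i in order:
        mask = compartments.masks[i]
        spill_in = np.zeros_like(image)
        for j in range(n):
            if j != i:
                spill_in += spills[j]
        num = masked_image[i] - np.where(mask, spill_in, 0.0)
        c_i = rsf_divide(num, i)
        c_i = _replace_negatives_nonneg(c_i, mask)
        corrected[mask] = c_i[mask]
        estimates[i] = repair(c_i, i)
        spills[i] = compartments.convolve(i, estimates[i])

    result = CorrectionResult(image=corrected, method="estc", iterations=1)
    result.flags["low_rsf"] = low_flags
    result.flags["erosion_fallback"] = fallback_flags  # type: ignore[assignment]
    return result


def _replace_negatives_nonneg(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """eSTC negativity rule: nearest non-negative neighbour inside the mask."""
    neg = mask & (values < 0)
    if not neg.any():
        return values
    nonneg = mask & (values >= 0)
    if not nonneg.any():
        return np.where(neg, 0.0, values)
    return _fill_from_source(values, neg, nonneg)


def surround_psf(
    tissue_specs: Sequence[TissueSpec],
    params: SequenceParams,
    **psf_kwargs,
) -> PSFKernel:
    """Averaged PSF of the surroundings: the PSF simulated at the
    arithmetic-mean relaxation times of all surrounding tissues."""

    relax = mixed_voxel_relaxation(list(tissue_specs))
    return simulate_psf(relax, params, **psf_kwargs)
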