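"""Point spread function simulation for density-adapted 3D radial sodium MRI.

The image-space PSF of a radial ultrashort-echo-time acquisition is governed
by the transverse relaxation during readout: each k-space shell ``k`` is
sampled at readout time ``t(k)`` and therefore weighted by the biexponential
T2* decay evaluated at ``TE + t(k)``, optionally multiplied by the
reconstruction apodization window.  Because the trajectory is isotropic only
the radial weighting matters, so the PSF is computed as the inverse Fourier
transform of a radially weighted k-space ball on a Cartesian grid.

The trajectory model is a linear-gradient ramp for ``k <= k0``
(``k0 = ramp_fraction``, hence ``k ∝ t²`` on the ramp) followed by the
density-adapted regime with constant sampling density (``k ∝ t^(1/3)``).
The junction time is chosen so that ``t(k)`` is C1-continuous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence, Union

import numpy as np

from .core import RelaxationTimes, SequenceParams, TissueSpec

__all__ = [
    "PSFKernel",
    "kspace_time_map",
    "kspace_weighting",
    "simulate_psf",
    "impulse_kernel",
    "mixed_voxel_relaxation",
    "fwhm",
]


@dataclass
class PSFKernel:
    """Discrete PSF on an odd-sized cube; normalised to unit sum (DC gain 1)."""

    values: np.ndarray
    voxel_size: float
    mass_coverage: float = 1.0
    low_coverage: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or any(s % 2 == 0 for s in self.values.shape):
            raise ValueError("PSF kernel must be a 3D array with odd edges")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def halfwidth(self) -> int:
        return self.values.shape[0] // 2

    @property
    def center(self) -> tuple:
        return tuple(s // 2 for s in self.values.shape)


def kspace_time_map(params: SequenceParams) -> Callable[[np.ndarray], np.ndarray]:
    """Map normalised k-space radius ``k`` in [0, 1] to readout time (ms).

    On the gradient ramp the radius grows quadratically with time; in the
    density-adapted regime ``k³`` grows linearly with time.  The ramp
    duration ``t0 = 6 k0³ T / (1 + 5 k0³)`` makes ``dk/dt`` continuous at the
    junction, with ``T`` the total readout duration.
    """

    k0 = params.ramp_fraction
    total = params.readout_duration
    t0 = 6.0 * k0**3 * total / (1.0 + 5.0 * k0**3)

    def t_of_k(k):
        k = np.asarray(k, dtype=float)
        if np.any(k < 0) or np.any(k > 1):
            raise ValueError("normalised k-space radius must lie in [0, 1]")
        ramp = t0 * np.sqrt(np.clip(k, 0.0, k0) / k0)
        da = t0 + (total - t0) * (np.clip(k, k0, 1.0) ** 3 - k0**3) / (1.0 - k0**3)
        return np.where(k <= k0, ramp, da)

    return t_of_k


def kspace_weighting(
    relax: RelaxationTimes,
    params: SequenceParams,
    apodization: str = "hanning",
) -> Callable[[np.ndarray], np.ndarray]:
    """Radial k-space weighting ``w(k)``: T2* decay at ``TE + t(k)`` times
    the apodization window (``none`` or ``hanning``)."""

    if apodization not in ("none", "hanning"):
        raise ValueError("apodization must be 'none' or 'hanning'")
    t_of_k = kspace_time_map(params)

    def w(k):
        k = np.asarray(k, dtype=float)
        decay = relax.transverse_decay(params.te + t_of_k(k))
        if apodization == "hanning":
            decay = decay * 0.5 * (1.0 + np.cos(np.pi * k))
        return decay

    return w


def simulate_psf(
    relax: RelaxationTimes,
    params: SequenceParams,
    apodization: str = "hanning",
    kernel_halfwidth: int = 10,
    voxel_size: float | None = None,
    fft_size: int = 96,
    mass_threshold: float = 0.99,
) -> PSFKernel:
    """Simulate the image-space PSF for one set of relaxation times.

    A Cartesian k-space cube of ``fft_size³`` voxels is filled with
    ``w(|k|)`` inside the sampled ball ``|k| <= k_max = 1/(2·nominal
    resolution)`` and zero outside, inverse transformed, cropped to
    ``(2·kernel_halfwidth+1)³`` and normalised to unit sum.  Voxels cut by
    the ball surface are weighted by a linear sub-voxel coverage taper to
    suppress surface discretisation noise.

    ``voxel_size`` is the sampling grid of the returned kernel and defaults
    to the nominal resolution; a finer ``voxel_size`` yields an oversampled
    kernel (e.g. for use on zerofilled images).
    """

    if kernel_halfwidth < 3:
        raise ValueError("kernel_halfwidth must be at least 3")
    v = params.nominal_resolution if voxel_size is None else float(voxel_size)
    if v <= 0:
        raise ValueError("voxel_size must be positive")
    n = int(fft_size)
    if 2 * kernel_halfwidth + 1 > n:
        raise ValueError("fft_size too small for the requested kernel window")

    # Index radius of the sampled ball: k_max / dk with dk = 1/(n*v).
    ball_radius = n * v / (2.0 * params.nominal_resolution)
    if ball_radius > n / 2:
        raise ValueError(
            "voxel_size too coarse: k-space ball exceeds the Cartesian grid"
        )

    w = kspace_weighting(relax, params, apodization)
    idx = np.arange(n) - n // 2
    r = np.sqrt(
        idx[:, None, None] ** 2 + idx[None, :, None] ** 2 + idx[None, None, :] ** 2
    )
    coverage = np.clip(ball_radius + 0.5 - r, 0.0, 1.0)
    k_norm = np.minimum(r / ball_radius, 1.0)
    weights = w(k_norm) * coverage

    psf_full = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(weights))).real
    c = n // 2
    h = kernel_halfwidth
    crop = psf_full[c - h : c + h + 1, c - h : c + h + 1, c - h : c + h + 1].copy()

    total_mass = np.abs(psf_full).sum()
    coverage_frac = float(np.abs(crop).sum() / total_mass) if total_mass > 0 else 0.0
    s = crop.sum()
    if s <= 0:
        raise ValueError("degenerate PSF: non-positive DC gain")
    crop /= s
    return PSFKernel(
        crop,
        voxel_size=v,
        mass_coverage=coverage_frac,
        low_coverage=coverage_frac < mass_threshold,
    )


def impulse_kernel(halfwidth: int = 1, voxel_size: float = 1.0) -> PSFKernel:
    """Unit impulse kernel (identity under convolution)."""
    size = 2 * halfwidth + 1
    values = np.zeros((size, size, size))
    values[halfwidth, halfwidth, halfwidth] = 1.0
    return PSFKernel(values, voxel_size=voxel_size)


def mixed_voxel_relaxation(
    specs: Sequence[Union[TissueSpec, RelaxationTimes]],
) -> RelaxationTimes:
    """Arithmetic-mean relaxation times of a tissue combination.

    Used for voxels containing several tissues: T1, T2l* and T2s* are
    averaged over the supplied tissues.  Monoexponential tissues contribute
    their T2l* to the short-component mean.  The short-component amplitude
    fraction is shared by all tissues and passed through.
    """

    if len(specs) == 0:
        raise ValueError("mixed_voxel_relaxation requires a non-empty tissue list")
    relaxes = [s.relax if isinstance(s, TissueSpec) else s for s in specs]
    fs = relaxes[0].short_fraction
    t1 = float(np.mean([r.t1 for r in relaxes]))
    t2l = float(np.mean([r.t2l_star for r in relaxes]))
    t2s = float(np.mean([r.t2s_effective for r in relaxes]))
    return RelaxationTimes(t1, t2l, min(t2s, t2l), short_fraction=fs)


def fwhm(kernel: PSFKernel) -> float:
    """Full width at half maximum of the central axis profile, in mm.

    Half-maximum crossings are located by linear interpolation on the
    profile through the kernel centre along the first axis.
    """

    c = kernel.center
    profile = kernel.values[:, c[1], c[2]].astype(float)
    peak = profile[c[0]]
    if peak <= 0:
        raise ValueError("kernel peak must be positive")
    half = peak / 2.0

    def crossing(direction: int) -> float:
        # walk outwards from the centre until the profile drops below half
        i = c[0]
        while True:
            j = i + direction
            if j < 0 or j >= profile.size:
                raise ValueError("half maximum not reached inside kernel window")
            if profile[j] < half:
                # linear interpolation between i and j
                frac = (profile[i] - half) / (profile[i] - profile[j])
                return abs(i - c[0]) + frac
            i = j

    return (crossing(+1) + crossing(-1)) * kernel.voxel_size
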