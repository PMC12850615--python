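"""Synthetic Achilles-tendon phantom and the forward acquisition model.

The digital phantom is a parametric stand-in for a manually segmented ankle:
the tendon is a gently curved elliptical tube split into three 3-cm sections
(insertion INS, middle MID, myotendinous junction MTJ), inserting onto an
ellipsoidal calcaneus, covered posteriorly by a thin skin shell, embedded in
fat, with the triceps surae muscle anteriorly, a small fluid-filled
retrocalcaneal bursa, two blood vessels, intra-tendinous concentration spots
and four agarose reference cylinders behind the coil plane.

The forward model corrupts the ground-truth concentration map in the order a
real acquisition would: relaxation weighting, block-mean downsampling
(tissue-fraction effect), surface-coil sensitivity, per-tissue PSF
convolution (spill-over), Rician noise, and zerofilling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Mapping, Optional, Tuple

import numpy as np
from scipy.signal import fftconvolve

from .core import (
    LabelMap,
    RelaxationTimes,
    SequenceParams,
    TissueSpec,
    VolumeGrid,
    achilles_tissue_table,
)
from .psf import PSFKernel, impulse_kernel, mixed_voxel_relaxation, simulate_psf

__all__ = [
    "GeometryConfig",
    "GeometryError",
    "PhantomBundle",
    "AcquisitionResult",
    "generate_phantom",
    "relaxation_weight",
    "relaxation_weight_map",
    "block_downsample",
    "make_sensitivity",
    "apply_sensitivity",
    "build_psf_bank",
    "spillover_forward",
    "add_rician_noise",
    "zerofill",
    "simulate_acquisition",
]


class GeometryError(ValueError):
    """Raised when a phantom region is empty, overlaps or exits the grid."""


@dataclass(frozen=True)
class GeometryConfig:
    """Shape parameters of the synthetic ankle, in mm (= voxels at 1 mm).

    The default layout fits a 96³ grid; ``preset`` recentres it on larger
    grids.  All coordinates are (x, y, z) with z the tendon long axis and
    the surface coil plane at ``coil_plane_y``.
    """

    grid_shape: Tuple[int, int, int] = (96, 96, 96)
    voxel_size: float = 1.0
    # leg cross section (elliptical cylinder along z) and skin thickness
    leg_center: Tuple[float, float] = (48.0, 44.0)
    leg_semi: Tuple[float, float] = (34.0, 29.0)
    skin_thickness: float = 3.0
    leg_z: Tuple[float, float] = (2.0, 94.0)
    # tendon tube (subcutaneous: in contact with the posterior skin layer)
    tendon_x: float = 48.0
    tendon_y0: float = 20.5
    tendon_y_drift: float = 0.0
    tendon_semi: Tuple[float, float] = (7.0, 3.0)
    tendon_z0: float = 4.0
    section_length: float = 30.0
    tip_length: float = 6.0
    spot_radius: float = 3.0
    # calcaneus, bursa, muscle, vessels
    calcaneus_center: Tuple[float, float, float] = (48.0, 40.0, 10.0)
    calcaneus_semi: Tuple[float, float, float] = (18.0, 16.0, 10.0)
    bursa_center: Tuple[float, float, float] = (48.0, 27.0, 16.0)
    bursa_semi: Tuple[float, float, float] = (4.0, 2.5, 3.5)
    muscle_center: Tuple[float, float] = (48.0, 45.0)
    muscle_semi: Tuple[float, float] = (25.0, 18.0)
    muscle_z: Tuple[float, float] = (26.0, 94.0)
    vessel_xy: Tuple[Tuple[float, float], ...] = ((34.0, 36.0), (60.0, 36.0))
    vessel_radius: float = 1.5
    vessel_z: Tuple[float, float] = (24.0, 92.0)
    # reference cylinders (10 mm diameter, 35 mm height) behind the coil
    reference_x: Tuple[float, ...] = (18.0, 38.0, 58.0, 78.0)
    reference_y: float = 6.0
    reference_radius: float = 5.0
    reference_z: Tuple[float, float] = (30.0, 65.0)
    # surface coil model
    coil_plane_y: float = 12.0
    sensitivity_scale: float = 60.0

    @classmethod
    def preset(cls, name: str = "default") -> "GeometryConfig":
        """Named geometries: ``default`` (96³) and ``large`` (160³)."""
        if name == "default":
            return cls()
        if name == "large":
            return cls._shifted(160, 32.0)
        raise ValueError(f"unknown geometry preset: {name!r}")

    @classmethod
    def _shifted(cls, n: int, d: float) -> "GeometryConfig":
        base = cls()

        def s2(p):
            return (p[0] + d, p[1] + d)

        def s3(p):
            return (p[0] + d, p[1] + d, p[2] + d)

        return cls(
            grid_shape=(n, n, n),
            leg_center=s2(base.leg_center),
            leg_z=(base.leg_z[0] + d, base.leg_z[1] + d),
            tendon_x=base.tendon_x + d,
            tendon_y0=base.tendon_y0 + d,
            tendon_z0=base.tendon_z0 + d,
            calcaneus_center=s3(base.calcaneus_center),
            bursa_center=s3(base.bursa_center),
            muscle_center=s2(base.muscle_center),
            muscle_z=(base.muscle_z[0] + d, base.muscle_z[1] + d),
            vessel_xy=tuple(s2(v) for v in base.vessel_xy),
            vessel_z=(base.vessel_z[0] + d, base.vessel_z[1] + d),
            reference_x=tuple(x + d for x in base.reference_x),
            reference_y=base.reference_y + d,
            reference_z=(base.reference_z[0] + d, base.reference_z[1] + d),
            coil_plane_y=base.coil_plane_y + d,
        )

    def tendon_center_y(self, z):
        """Posterior-to-anterior drift of the tendon axis along z."""
        span = 3.0 * self.section_length
        u = (np.asarray(z, dtype=float) - self.tendon_z0) / span
        return self.tendon_y0 + self.tendon_y_drift * u**2


@dataclass
class PhantomBundle:
    """Ground truth, segmentation and coil sensitivity of one phantom."""

    ground_truth: VolumeGrid
    label_map: LabelMap
    sensitivity: VolumeGrid
    seed: int = 0


@dataclass
class AcquisitionResult:
    """Output of the forward corruption chain."""

    lowres: VolumeGrid
    zerofilled: Optional[VolumeGrid]
    noise_sigma: Optional[float]
    seed: Optional[int]
    resolution_factor: int


# ---------------------------------------------------------------------------
# Geometry painting
# ---------------------------------------------------------------------------


def _coords(shape):
    x = np.arange(shape[0], dtype=float)
    y = np.arange(shape[1], dtype=float)
    z = np.arange(shape[2], dtype=float)
    return np.meshgrid(x, y, z, indexing="ij")


def _check_region(name: str, mask: np.ndarray, require_nonempty: bool = True) -> None:
    if require_nonempty and not mask.any():
        raise GeometryError(f"region {name!r} is empty on this grid")


def generate_phantom(
    geometry: GeometryConfig | str | None = None,
    tissue_table: Mapping[int, TissueSpec] | None = None,
    seed: int = 0,
) -> PhantomBundle:
    """Generate the labelled ground-truth phantom.

    Regions are painted in anatomical priority order (later regions win at
    their mutual interfaces: skin < calcaneus < muscle < vessels < bursa <
    tendon < intra-tendinous sub-regions), which keeps all labels disjoint
    by construction.  Reference cylinders must not intersect the leg; an
    overlapping or empty region raises :class:`GeometryError` naming it.
    """

    if geometry is None:
        geometry = GeometryConfig.preset("default")
    elif isinstance(geometry, str):
        geometry = GeometryConfig.preset(geometry)
    g = geometry
    table = dict(tissue_table or achilles_tissue_table())
    by_name = {spec.name: spec for spec in table.values()}

    shape = g.grid_shape
    X, Y, Z = _coords(shape)
    labels = np.zeros(shape, dtype=np.int16)

    def paint(name: str, mask: np.ndarray) -> np.ndarray:
        _check_region(name, mask)
        labels[mask] = by_name[name].label
        return mask

    # leg: fat fills the interior, skin is the outer shell
    lx, ly = g.leg_center
    ax, ay = g.leg_semi
    rho_out = ((X - lx) / ax) ** 2 + ((Y - ly) / ay) ** 2
    rho_in = ((X - lx) / (ax - g.skin_thickness)) ** 2 + (
        (Y - ly) / (ay - g.skin_thickness)
    ) ** 2
    in_z = (Z >= g.leg_z[0]) & (Z < g.leg_z[1])
    leg = (rho_out <= 1.0) & in_z
    paint("fat", leg)
    paint("skin", leg & (rho_in > 1.0))

    # calcaneus
    cc, cs = g.calcaneus_center, g.calcaneus_semi
    calc = (
        ((X - cc[0]) / cs[0]) ** 2
        + ((Y - cc[1]) / cs[1]) ** 2
        + ((Z - cc[2]) / cs[2]) ** 2
    ) <= 1.0
    paint("calcaneus", calc & leg)

    # muscle (soleus/gastrocnemius) anterior to the tendon
    mc, ms = g.muscle_center, g.muscle_semi
    muscle = (
        (((X - mc[0]) / ms[0]) ** 2 + ((Y - mc[1]) / ms[1]) ** 2 <= 1.0)
        & (Z >= g.muscle_z[0])
        & (Z < g.muscle_z[1])
    )
    paint("muscle", muscle & leg & ~calc)

    # blood vessels through the deep compartment
    vessels = np.zeros(shape, dtype=bool)
    for vx, vy in g.vessel_xy:
        vessels |= (
            ((X - vx) ** 2 + (Y - vy) ** 2 <= g.vessel_radius**2)
            & (Z >= g.vessel_z[0])
            & (Z < g.vessel_z[1])
        )
    paint("blood", vessels & leg & ~calc)

    # retrocalcaneal bursa
    bc, bs = g.bursa_center, g.bursa_semi
    bursa = (
        ((X - bc[0]) / bs[0]) ** 2
        + ((Y - bc[1]) / bs[1]) ** 2
        + ((Z - bc[2]) / bs[2]) ** 2
    ) <= 1.0
    paint("bursa", bursa & leg)

    # tendon tube and its three sections
    yc = g.tendon_center_y(Z)
    tendon = (
        ((X - g.tendon_x) / g.tendon_semi[0]) ** 2
        + ((Y - yc) / g.tendon_semi[1]) ** 2
    ) <= 1.0
    z0, L = g.tendon_z0, g.section_length
    if z0 + 3 * L > shape[2]:
        raise GeometryError("region 'tendon' exits the grid along z")
    sections = {
        "ins": tendon & (Z >= z0) & (Z < z0 + L),
        "mid": tendon & (Z >= z0 + L) & (Z < z0 + 2 * L),
        "mtj": tendon & (Z >= z0 + 2 * L) & (Z < z0 + 3 * L),
    }
    for name, mask in sections.items():
        paint(name, mask)

    # intra-tendinous sub-regions
    paint("ins_tip", sections["ins"] & (Z < z0 + g.tip_length))
    for name, zc in (("mid_spot", z0 + 1.5 * L), ("mtj_spot", z0 + 2.5 * L)):
        sx, sy = g.tendon_x, float(g.tendon_center_y(zc))
        spot = ((X - sx) ** 2 + (Y - sy) ** 2 + (Z - zc) ** 2) <= g.spot_radius**2
        spot &= tendon
        paint(name, spot)

    # reference cylinders behind the coil plane
    zlo, zhi = g.reference_z
    ref_names = sorted(
        (n for n in by_name if n.startswith("ref_")), key=lambda n: by_name[n].label
    )
    if len(ref_names) != len(g.reference_x):
        raise GeometryError("number of reference cylinders must match tissue table")
    for rx, name in zip(g.reference_x, ref_names):
        cyl = (
            ((X - rx) ** 2 + (Y - g.reference_y) ** 2 <= g.reference_radius**2)
            & (Z >= zlo)
            & (Z < zhi)
        )
        _check_region(name, cyl)
        if (
            rx - g.reference_radius < 0
            or rx + g.reference_radius >= shape[0]
            or g.reference_y - g.reference_radius < 0
        ):
            raise GeometryError(f"region {name!r} exits the grid")
        if (labels[cyl] != 0).any():
            raise GeometryError(f"region {name!r} overlaps existing tissue")
        labels[cyl] = by_name[name].label

    legend = {spec.label: spec for spec in table.values()}
    label_map = LabelMap(labels, voxel_size=g.voxel_size, legend=legend)
    ground_truth = VolumeGrid(label_map.concentration_map(), g.voxel_size)
    sensitivity = make_sensitivity(g)
    return PhantomBundle(ground_truth, label_map, sensitivity, seed=seed)


# ---------------------------------------------------------------------------
# Forward corruption chain
# ---------------------------------------------------------------------------


def relaxation_weight(relax: RelaxationTimes, tr: float, te: float) -> float:
    """Steady-state relaxation weighting for a 90° excitation.

    ``(1 - exp(-TR/T1)) * (f_s exp(-TE/T2s*) + (1-f_s) exp(-TE/T2l*))``.
    """

    if tr <= 0 or te < 0:
        raise ValueError("TR must be positive and TE non-negative")
    return float((1.0 - np.exp(-tr / relax.t1)) * relax.transverse_decay(te))


def relaxation_weight_map(label_map: LabelMap, tr: float, te: float) -> np.ndarray:
    """Per-voxel relaxation weighting from the segmentation legend."""
    out = np.ones(label_map.shape, dtype=float)
    for lab, spec in label_map.legend.items():
        out[label_map.labels == lab] = relaxation_weight(spec.relax, tr, te)
    return out


def block_downsample(volume: VolumeGrid, factor: int) -> VolumeGrid:
    """Downsample by the block mean over ``factor³`` voxels.

    Models the tissue-fraction effect of a coarse acquisition grid; the
    global mean is preserved exactly.  Grid edges must be divisible by
    ``factor`` — no implicit padding.
    """

    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return volume.with_values(volume.values.copy())
    v = volume.values
    if any(s % factor for s in v.shape):
        raise ValueError(
            f"grid shape {v.shape} is not divisible by factor {factor}"
        )
    nx, ny, nz = (s // factor for s in v.shape)
    blocks = v.reshape(nx, factor, ny, factor, nz, factor)
    out = blocks.mean(axis=(1, 3, 5))
    return VolumeGrid(out, volume.voxel_size * factor, volume.origin)


def make_sensitivity(geometry: GeometryConfig) -> VolumeGrid:
    """Analytic surface-coil sensitivity: ``exp(-d/d0)`` with ``d`` the
    distance from the coil plane and ``d0 = sensitivity_scale`` (mm)."""

    shape = geometry.grid_shape
    y = np.arange(shape[1], dtype=float) * geometry.voxel_size
    d = np.abs(y - geometry.coil_plane_y)
    sens = np.exp(-d / geometry.sensitivity_scale)
    values = np.broadcast_to(sens[None, :, None], shape).copy()
    return VolumeGrid(values, geometry.voxel_size)


def apply_sensitivity(volume: VolumeGrid, sensitivity: VolumeGrid) -> VolumeGrid:
    """Voxel-wise product with a sensitivity map normalised to max 1."""
    if volume.shape != sensitivity.shape:
        raise ValueError("volume and sensitivity grids do not match")
    sens = sensitivity.values
    m = sens.max()
    if m <= 0:
        raise ValueError("sensitivity map must contain positive values")
    return volume.with_values(volume.values * (sens / m))


# ---------------------------------------------------------------------------
# Spill-over (per-tissue PSF convolution)
# ---------------------------------------------------------------------------


@dataclass
class PSFBank:
    """Per-voxel tissue-combination map plus one PSF per combination."""

    combo_ids: np.ndarray  # int array on the low-resolution grid
    psfs: Dict[int, PSFKernel]
    members: Dict[int, FrozenSet[int]]


def build_psf_bank(
    label_map: LabelMap,
    factor: int,
    params: SequenceParams,
    apodization: str = "hanning",
    kernel_halfwidth: int = 10,
    fft_size: int = 96,
    impulse: bool = False,
) -> PSFBank:
    """Assign each low-resolution voxel its tissue combination and PSF.

    Voxels containing several tissues after block downsampling use the
    arithmetic-mean relaxation times of the combination.  PSFs are cached
    over identical mean relaxation times.  With ``impulse=True`` every
    combination maps to a unit impulse (spill-over disabled).
    """

    labs = label_map.labels
    factor = int(factor)
    if any(s % factor for s in labs.shape):
        raise ValueError("label grid not divisible by the downsampling factor")
    nx, ny, nz = (s // factor for s in labs.shape)
    blocks = labs.reshape(nx, factor, ny, factor, nz, factor).transpose(
        0, 2, 4, 1, 3, 5
    ).reshape(nx, ny, nz, factor**3)

    present = sorted(int(v) for v in np.unique(labs))
    bit = {lab: i for i, lab in enumerate(present)}
    codes = np.zeros((nx, ny, nz), dtype=np.int64)
    for lab in present:
        codes |= np.any(blocks == lab, axis=-1).astype(np.int64) << bit[lab]

    unique_codes = [int(c) for c in np.unique(codes)]
    combo_ids = np.searchsorted(unique_codes, codes).astype(np.int32)

    psfs: Dict[int, PSFKernel] = {}
    members: Dict[int, FrozenSet[int]] = {}
    cache: Dict[tuple, PSFKernel] = {}
    voxel = label_map.voxel_size * factor
    for cid, code in enumerate(unique_codes):
        labs_in = frozenset(lab for lab in present if code >> bit[lab] & 1)
        members[cid] = labs_in
        tissue_labs = sorted(labs_in - {0})
        if impulse or not tissue_labs:
            psfs[cid] = impulse_kernel(halfwidth=1, voxel_size=voxel)
            continue
        relax = mixed_voxel_relaxation(
            [label_map.legend[lab] for lab in tissue_labs]
        )
        key = (
            round(relax.t1, 4),
            round(relax.t2l_star, 4),
            round(relax.t2s_effective, 4),
        )
        if key not in cache:
            cache[key] = simulate_psf(
                relax,
                params,
                apodization=apodization,
                kernel_halfwidth=kernel_halfwidth,
                voxel_size=voxel,
                fft_size=fft_size,
            )
        psfs[cid] = cache[key]
    return PSFBank(combo_ids, psfs, members)


def spillover_forward(volume: VolumeGrid, psf_bank: PSFBank) -> VolumeGrid:
    """Apply the spill-over effect: each tissue-combination group is
    convolved with its own PSF and the results are summed.

    Linear in the input; boundaries are zero-padded (object in air).
    """

    if psf_bank.combo_ids.shape != volume.shape:
        raise ValueError("psf_bank grid does not match the volume")
    out = np.zeros(volume.shape, dtype=float)
    for cid, psf in psf_bank.psfs.items():
        group = psf_bank.combo_ids == cid
        if not group.any():
            raise KeyError(
                f"PSF bank combination {sorted(psf_bank.members[cid])} "
                "has no voxels on this grid"
            )
        masked = np.where(group, volume.values, 0.0)
        if psf.values.shape == (3, 3, 3) and psf.values[1, 1, 1] == 1.0:
            out += masked  # impulse shortcut
        else:
            out += fftconvolve(masked, psf.values, mode="same")
    return volume.with_values(out)


def add_rician_noise(
    volume: VolumeGrid,
    target_snr: float,
    snr_roi: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> Tuple[VolumeGrid, float]:
    """Add magnitude (Rician) noise calibrated to an SNR in a reference ROI.

    ``sigma = mean(volume over snr_roi) / target_snr``; the output voxel is
    ``sqrt((v + n1)² + n2²)`` with independent Gaussian channels of standard
    deviation ``sigma``.  Zero-signal regions become Rayleigh distributed
    with mean ``sigma·sqrt(pi/2)``.
    """

    if target_snr <= 0:
        raise ValueError("target_snr must be positive")
    snr_roi = np.asarray(snr_roi, dtype=bool)
    if snr_roi.shape != volume.shape or not snr_roi.any():
        raise ValueError("snr_roi must be a non-empty mask on the volume grid")
    mean_signal = float(volume.values[snr_roi].mean())
    if mean_signal <= 0:
        raise ValueError("mean signal in snr_roi must be positive")
    sigma = mean_signal / target_snr
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n1 = rng.normal(0.0, sigma, volume.shape)
    n2 = rng.normal(0.0, sigma, volume.shape)
    noisy = np.sqrt((volume.values + n1) ** 2 + n2**2)
    return volume.with_values(noisy), sigma


def zerofill(volume: VolumeGrid, target_voxel_size: float) -> VolumeGrid:
    """Fourier-domain zero-padding interpolation to a finer grid.

    The voxel size must shrink by an integer factor.  The DC component
    (global mean) is preserved; band-limited content is interpolated
    exactly.
    """

    ratio = volume.voxel_size / target_voxel_size
    factor = int(round(ratio))
    if factor < 1 or abs(ratio - factor) > 1e-9:
        raise ValueError(
            "target voxel size must divide the source voxel size by an "
            f"integer factor (got ratio {ratio})"
        )
    if factor == 1:
        return volume.with_values(volume.values.copy())
    v = volume.values
    spec = np.fft.fftshift(np.fft.fftn(v))
    pads = []
    for s in v.shape:
        total = s * factor - s
        pads.append((total - total // 2, total // 2))
    spec = np.pad(spec, pads)
    out = np.fft.ifftn(np.fft.ifftshift(spec)).real * factor**3
    return VolumeGrid(out, target_voxel_size, volume.origin)


def simulate_acquisition(
    bundle: PhantomBundle,
    params: SequenceParams,
    resolution_factor: int = 2,
    target_snr: Optional[float] = 10.0,
    seed: int = 0,
    apodization: str = "hanning",
    kernel_halfwidth: int = 10,
    psf_bank: Optional[PSFBank] = None,
    snr_roi: Optional[np.ndarray] = None,
    zerofill_back: bool = True,
) -> AcquisitionResult:
    """Run the full forward corruption chain on a phantom.

    Stage order (fixed): relaxation weighting → block-mean downsampling →
    coil sensitivity → per-tissue PSF convolution → Rician noise →
    zerofilling back to the ground-truth grid.  ``target_snr=None`` disables
    noise; pass a precomputed ``psf_bank`` to amortise PSF simulation over
    Monte Carlo iterations.
    """

    factor = int(resolution_factor)
    weights = relaxation_weight_map(bundle.label_map, params.tr, params.te)
    signal = bundle.ground_truth.with_values(bundle.ground_truth.values * weights)

    lowres = block_downsample(signal, factor)
    sens_lr = block_downsample(bundle.sensitivity, factor)
    lowres = apply_sensitivity(lowres, sens_lr)

    if psf_bank is None:
        psf_bank = build_psf_bank(
            bundle.label_map,
            factor,
            params,
            apodization=apodization,
            kernel_halfwidth=kernel_halfwidth,
        )
    lowres = spillover_forward(lowres, psf_bank)

    sigma: Optional[float] = None
    used_seed: Optional[int] = None
    if target_snr is not None and np.isfinite(target_snr):
        if snr_roi is None:
            snr_roi = _default_snr_roi(bundle.label_map, factor)
        lowres, sigma = add_rician_noise(lowres, target_snr, snr_roi, seed)
        used_seed = int(seed)

    zf = (
        zerofill(lowres, bundle.ground_truth.voxel_size) if zerofill_back else None
    )
    return AcquisitionResult(lowres, zf, sigma, used_seed, factor)


def _default_snr_roi(label_map: LabelMap, factor: int) -> np.ndarray:
    """Low-resolution voxels dominated by the MID tendon section."""
    from .core import TENDON_SECTIONS

    mid = label_map.mask(TENDON_SECTIONS["mid"]).astype(float)
    frac = block_downsample(VolumeGrid(mid, label_map.voxel_size), factor).values
    roi = frac >= 0.5
    if not roi.any():
        roi = frac > 0.0
    return roi
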