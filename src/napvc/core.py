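"""Core containers: volumes, label maps, tissue parameters, sequence parameters.

Conventions used throughout the package:

* volumes are 3D ``numpy`` arrays with an isotropic voxel size in mm;
* voxel coordinates are 0-based array indices, physical positions are
  ``index * voxel_size + origin``;
* concentrations are in mM, times in ms, signals in arbitrary units.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "RelaxationTimes",
    "SequenceParams",
    "TissueSpec",
    "VolumeGrid",
    "LabelMap",
    "achilles_tissue_table",
    "TENDON_SECTIONS",
    "AT_LABELS",
    "SURROUND_LABELS",
    "REFERENCE_LABELS",
]


@dataclass(frozen=True)
class RelaxationTimes:
    """Longitudinal and biexponential transverse relaxation times of a tissue.

    Sodium nuclei in ordered tissue relax biexponentially: a short component
    ``t2s_star`` with amplitude fraction ``short_fraction`` and a long
    component ``t2l_star``.  Fluids relax monoexponentially, which is
    expressed by ``t2s_star=None`` (the short component collapses onto the
    long one).

    Parameters are in ms; ``short_fraction`` is dimensionless in [0, 1] and
    defaults to the canonical 60/40 amplitude split of the spin-3/2 sodium
    signal.
    """

    t1: float
    t2l_star: float
    t2s_star: Optional[float] = None
    short_fraction: float = 0.6

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2l_star <= 0:
            raise ValueError("relaxation times must be positive")
        if self.t2s_star is not None:
            if self.t2s_star <= 0:
                raise ValueError("relaxation times must be positive")
            if self.t2s_star > self.t2l_star:
                raise ValueError("t2s_star must not exceed t2l_star")
        if not 0.0 <= self.short_fraction <= 1.0:
            raise ValueError("short_fraction must lie in [0, 1]")

    @property
    def t2s_effective(self) -> float:
        """Short T2* used in formulas; equals ``t2l_star`` for fluids."""
        return self.t2l_star if self.t2s_star is None else self.t2s_star

    def transverse_decay(self, t):
        """Biexponential transverse decay factor at echo/readout time ``t`` (ms).

        Vectorised over ``t``.
        """
        t = np.asarray(t, dtype=float)
        fs = self.short_fraction
        return fs * np.exp(-t / self.t2s_effective) + (1.0 - fs) * np.exp(
            -t / self.t2l_star
        )


@dataclass(frozen=True)
class SequenceParams:
    """Acquisition parameters of a density-adapted 3D radial (DA-3D-RAD) scan.

    ``ramp_fraction`` is the normalised k-space radius reached on the linear
    gradient ramp before the density-adapted regime takes over.
    """

    tr: float = 15.0
    te: float = 0.1
    readout_duration: float = 5.0
    ramp_fraction: float = 0.2
    nominal_resolution: float = 2.0
    matrix_size: int = 48
    flip_angle: float = 90.0

    def __post_init__(self) -> None:
        if not self.te < self.tr:
            raise ValueError("TE must be smaller than TR")
        if self.readout_duration <= 0:
            raise ValueError("readout_duration must be positive")
        if not 0.0 < self.ramp_fraction < 1.0:
            raise ValueError("ramp_fraction must lie in (0, 1)")
        if self.nominal_resolution <= 0:
            raise ValueError("nominal_resolution must be positive")
        if self.matrix_size < 8:
            raise ValueError("matrix_size must be at least 8")


@dataclass(frozen=True)
class TissueSpec:
    """Physical description of one tissue class in the phantom."""

    name: str
    label: int
    concentration: float
    relax: RelaxationTimes

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.label <= 0:
            raise ValueError("label must be a positive integer")


@dataclass
class VolumeGrid:
    """3D scalar field on an isotropic grid (signal, concentration, ...)."""

    values: np.ndarray
    voxel_size: float
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("VolumeGrid requires a 3D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("VolumeGrid values must be finite")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def with_values(self, values: np.ndarray) -> "VolumeGrid":
        return VolumeGrid(values, self.voxel_size, self.origin)


@dataclass
class LabelMap:
    """Integer tissue segmentation with a legend mapping labels to tissues."""

    labels: np.ndarray
    voxel_size: float
    legend: Dict[int, TissueSpec] = field(default_factory=dict)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("LabelMap requires an integer array")
        if self.labels.ndim != 3:
            raise ValueError("LabelMap requires a 3D array")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"labels missing from legend: {sorted(missing)}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def mask(self, labels: int | Iterable[int]) -> np.ndarray:
        if isinstance(labels, (int, np.integer)):
            labels = (int(labels),)
        return np.isin(self.labels, list(labels))

    def labels_present(self) -> Sequence[int]:
        return [int(v) for v in np.unique(self.labels) if v != 0]

    def concentration_map(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=float)
        for lab, spec in self.legend.items():
            out[self.labels == lab] = spec.concentration
        return out


# ---------------------------------------------------------------------------
# Default tissue table for the Achilles tendon phantom.
# ---------------------------------------------------------------------------

#: Labels of the three tendon sections and their intra-tendinous sub-regions.
TENDON_SECTIONS: Mapping[str, Tuple[int, ...]] = {
    "ins": (1, 4),  # insertion + elevated tip
    "mid": (2, 5),  # middle portion + hyper-intense spot
    "mtj": (3, 6),  # myotendinous junction + hypo-intense spot
}

#: All Achilles tendon labels.
AT_LABELS: Tuple[int, ...] = (1, 2, 3, 4, 5, 6)

#: Soft tissues surrounding the tendon (skin, fat, muscle, bursa, blood).
SURROUND_LABELS: Tuple[int, ...] = (7, 8, 9, 10, 11)

#: Reference phantom labels mapped to their agarose concentrations (mM).
REFERENCE_LABELS: Mapping[int, float] = {13: 50.0, 14: 75.0, 15: 100.0, 16: 125.0}

_AGAROSE_RELAX = RelaxationTimes(t1=38.5, t2l_star=13.0, t2s_star=6.0)


def achilles_tissue_table(short_fraction: float = 0.6) -> Dict[int, TissueSpec]:
    """Default tissue parameter table for the Achilles tendon phantom.

    Concentrations (mM) and relaxation times (ms) follow published literature
    values for the tendon sections, skin, fat, muscle, synovial fluid, blood
    and 4% agarose calibration phantoms.  The calcaneus carries zero sodium;
    its nominal relaxation times only matter for mixed-voxel PSF averaging.
    """

    def rx(t1, t2l, t2s):
        return RelaxationTimes(t1, t2l, t2s, short_fraction=short_fraction)

    specs = [
        TissueSpec("ins", 1, 25.0, rx(18.4, 14.5, 1.4)),
        TissueSpec("mid", 2, 15.0, rx(19.2, 14.2, 1.4)),
        TissueSpec("mtj", 3, 18.0, rx(23.3, 14.6, 1.5)),
        TissueSpec("ins_tip", 4, 30.0, rx(18.4, 14.5, 1.4)),
        TissueSpec("mid_spot", 5, 18.0, rx(19.2, 14.2, 1.4)),
        TissueSpec("mtj_spot", 6, 14.0, rx(23.3, 14.6, 1.5)),
        TissueSpec("skin", 7, 34.2, rx(27.0, 7.6, 0.5)),
        TissueSpec("fat", 8, 13.1, rx(25.2, 14.3, 1.4)),
        TissueSpec("muscle", 9, 20.3, rx(25.2, 14.3, 1.4)),
        TissueSpec(
            "bursa",
            10,
            140.0,
            RelaxationTimes(62.0, 28.0, None, short_fraction=short_fraction),
        ),
        TissueSpec("blood", 11, 81.0, rx(38.4, 15.8, 2.0)),
        TissueSpec("calcaneus", 12, 0.0, rx(18.4, 14.5, 1.4)),
    ]
    specs += [
        TissueSpec(f"ref_{int(conc)}", lab, conc, _AGAROSE_RELAX)
        for lab, conc in REFERENCE_LABELS.items()
    ]
    return {s.label: s for s in specs}


def replace(obj, **changes):
    """Thin re-export of :func:`dataclasses.replace` for convenience."""
    return dataclasses.replace(obj, **changes)
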