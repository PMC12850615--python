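"""NIfTI and sidecar I/O for volumes, label maps and tissue tables."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Mapping, Optional

import nibabel as nib
import numpy as np
import yaml

from .core import LabelMap, RelaxationTimes, TissueSpec, VolumeGrid

__all__ = [
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "read_tissue_table",
    "write_tissue_table",
]


def _check_isotropic(zooms) -> float:
    zooms = [float(z) for z in zooms[:3]]
    if max(zooms) - min(zooms) > 1e-6 * max(zooms):
        raise ValueError(f"anisotropic voxels are not supported (zooms={zooms})")
    return zooms[0]


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a 3D scalar NIfTI volume with isotropic voxels."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise ValueError("volume contains non-finite values")
    voxel = _check_isotropic(img.header.get_zooms())
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VolumeGrid(data, voxel, origin)


def write_volume(path: str | Path, volume: VolumeGrid) -> None:
    """Write a volume as NIfTI; the voxel size goes into the affine."""
    affine = np.diag([volume.voxel_size] * 3 + [1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(volume.values.astype(np.float64), affine), str(path))


def _legend_to_dict(legend: Mapping[int, TissueSpec]) -> Dict:
    out = {}
    for lab, spec in legend.items():
        out[str(lab)] = {
            "name": spec.name,
            "concentration_mM": spec.concentration,
            "t1_ms": spec.relax.t1,
            "t2l_star_ms": spec.relax.t2l_star,
            "t2s_star_ms": spec.relax.t2s_star,
            "short_fraction": spec.relax.short_fraction,
        }
    return out


def _legend_from_dict(data: Mapping) -> Dict[int, TissueSpec]:
    legend = {}
    for lab, row in data.items():
        relax = RelaxationTimes(
            t1=float(row["t1_ms"]),
            t2l_star=float(row["t2l_star_ms"]),
            t2s_star=None if row.get("t2s_star_ms") is None else float(row["t2s_star_ms"]),
            short_fraction=float(row.get("short_fraction", 0.6)),
        )
        legend[int(lab)] = TissueSpec(
            name=str(row["name"]),
            label=int(lab),
            concentration=float(row["concentration_mM"]),
            relax=relax,
        )
    return legend


def write_labels(path: str | Path, label_map: LabelMap) -> None:
    """Write a label map as integer NIfTI plus a JSON legend sidecar."""
    path = Path(path)
    affine = np.diag([label_map.voxel_size] * 3 + [1.0])
    affine[:3, 3] = label_map.origin
    nib.save(
        nib.Nifti1Image(label_map.labels.astype(np.int16), affine), str(path)
    )
    sidecar = path.with_suffix("").with_suffix("") if path.suffix == ".gz" else path
    sidecar = Path(str(sidecar).removesuffix(".nii") + ".labels.json")
    sidecar.write_text(json.dumps(_legend_to_dict(label_map.legend), indent=2))


def read_labels(path: str | Path, legend_path: Optional[str | Path] = None) -> LabelMap:
    """Read an integer label map and its legend sidecar.

    Labels present in the image but absent from the legend raise an error
    naming the label.
    """

    path = Path(path)
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj)
    if labels.ndim != 3:
        raise ValueError(f"expected a 3D label map, got shape {labels.shape}")
    if not np.allclose(labels, np.round(labels)):
        raise ValueError("label map contains non-integer values")
    labels = labels.astype(np.int16)
    voxel = _check_isotropic(img.header.get_zooms())
    if legend_path is None:
        base = str(path)
        base = base.removesuffix(".gz").removesuffix(".nii")
        legend_path = base + ".labels.json"
    data = json.loads(Path(legend_path).read_text())
    legend = _legend_from_dict(data)
    present = set(np.unique(labels).tolist()) - {0}
    missing = sorted(present - set(legend))
    if missing:
        raise ValueError(f"labels absent from legend: {missing}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return LabelMap(labels, voxel, legend, origin)


def write_tissue_table(path: str | Path, table: Mapping[int, TissueSpec]) -> None:
    """Write a tissue parameter table as YAML."""
    Path(path).write_text(yaml.safe_dump(_legend_to_dict(table), sort_keys=True))


def read_tissue_table(path: str | Path) -> Dict[int, TissueSpec]:
    """Read a tissue parameter table from YAML or JSON."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return _legend_from_dict(data)
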