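"""Voxel-volume containers, file I/O, and acquisition-geometry arithmetic.

A microCT scan is held as a :class:`VoxelImage`: a 3D intensity grid whose
axis 0 is the graft's long axis (the slice axis) and whose in-plane axes are
row, col.  Material assignments live in a :class:`LabelVolume` on the same
grid.  Volumes are read and written either as multi-page grayscale TIFF
stacks (with a JSON sidecar carrying the voxel spacing, since TIFF has no
standard z-spacing tag) or as NIfTI-1 files (spacing in ``pixdim``).

Intensities are kept on their native numeric scale; no normalization is
applied, because segmentation masking ranges are calibrated by the operator
in image units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "VoxelImage",
    "LabelVolume",
    "compute_voxel_size",
    "reconstructed_projection_count",
    "read_volume",
    "write_volume",
    "read_label_volume",
    "write_label_volume",
]

#: Canonical material label assignment used throughout the package.
MATERIAL_LABELS: dict[int, str] = {
    0: "background",
    1: "lumen",
    2: "thrombus",
    3: "wall",
    4: "shrink",
}

_TIFF_SUFFIXES = {".tif", ".tiff"}


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


@dataclass(frozen=True)
class VoxelImage:
    """A 3D scalar intensity grid with physical voxel spacing.

    Parameters
    ----------
    data:
        Array of shape ``(n_slices, n_rows, n_cols)``.  Axis 0 is the
        graft's long axis.
    spacing:
        ``(dz, dy, dx)`` in mm per voxel; all strictly positive.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={data.ndim}")
        if data.shape[0] < 1:
            raise ValueError("volume must contain at least one slice")
        if not np.all(np.isfinite(data)):
            raise ValueError("intensities must be finite")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def pixel_area(self) -> float:
        """In-plane area of one pixel in mm^2."""
        return self.spacing[1] * self.spacing[2]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        dz, dy, dx = self.spacing
        return dz * dy * dx


@dataclass(frozen=True)
class LabelVolume:
    """Integer material assignment per voxel (a partition of the grid).

    ``material_names`` maps every label value present in ``labels`` to a
    material name; 0 is conventionally the background.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    material_names: Mapping[int, str] = field(
        default_factory=lambda: dict(MATERIAL_LABELS)
    )

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"expected a 3D label grid, got ndim={labels.ndim}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError(f"labels must be integer-typed, got {labels.dtype}")
        spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in spacing):
            raise ValueError("spacing must be positive")
        names = {int(k): str(v) for k, v in dict(self.material_names).items()}
        present = set(np.unique(labels).tolist())
        missing = present - set(names)
        if missing:
            raise ValueError(f"label values {sorted(missing)} absent from material_names")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "material_names", names)

    @property
    def pixel_area(self) -> float:
        return self.spacing[1] * self.spacing[2]

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def label_of(self, material: str) -> int:
        """Label value of a named material (raises on unknown names)."""
        for value, name in self.material_names.items():
            if name == material:
                return value
        raise KeyError(f"unknown material {material!r}; have {sorted(self.material_names.values())}")

    def mask_of(self, material: str) -> np.ndarray:
        return self.labels == self.label_of(material)


def compute_voxel_size(fov_mm: float, matrix: int) -> float:
    """Isotropic voxel size from field of view and reconstruction matrix.

    The scanner's in-plane voxel size is the field of view divided by the
    matrix size; e.g. a 60 mm field of view reconstructed on a 512 matrix
    gives 0.1171875 mm (117 µm) voxels.

    Parameters
    ----------
    fov_mm:
        Field of view in mm, > 0.
    matrix:
        Number of voxels across the field of view, integer >= 1.
    """
    if not fov_mm > 0:
        raise ValueError(f"field of view must be positive, got {fov_mm}")
    if int(matrix) != matrix or matrix < 1:
        raise ValueError(f"matrix must be a positive integer, got {matrix}")
    return float(fov_mm) / int(matrix)


def reconstructed_projection_count(acquired: int, averaging: int) -> int:
    """Number of projections after frame averaging.

    Acquired projections are averaged in non-overlapping groups of
    ``averaging`` frames (e.g. 3672 acquired projections with 4-projection
    averaging reconstruct from 918 projections).  ``acquired`` must divide
    evenly, otherwise the last averaging group would be undefined.
    """
    if acquired <= 0 or int(acquired) != acquired:
        raise ValueError(f"acquired must be a positive integer, got {acquired}")
    if averaging < 1 or int(averaging) != averaging:
        raise ValueError(f"averaging must be an integer >= 1, got {averaging}")
    acquired, averaging = int(acquired), int(averaging)
    if acquired % averaging:
        raise ValueError(
            f"{acquired} projections do not divide into groups of {averaging}"
        )
    return acquired // averaging


# ---------------------------------------------------------------------------
# volume I/O


def _write_array(data: np.ndarray, spacing: tuple[float, float, float], path: Path,
                 sidecar_extra: dict | None = None) -> None:
    dz, dy, dx = spacing
    if _is_nifti(path):
        import nibabel as nib

        affine = np.diag([dx, dy, dz, 1.0])
        img = nib.Nifti1Image(np.ascontiguousarray(data.T), affine)
        img.header.set_zooms((dx, dy, dz))
        nib.save(img, str(path))
        if sidecar_extra:
            _sidecar_path(path).write_text(json.dumps(sidecar_extra, indent=1))
    elif path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        tifffile.imwrite(str(path), data, photometric="minisblack")
        sidecar = {"spacing_mm": [dz, dy, dx]}
        if sidecar_extra:
            sidecar.update(sidecar_extra)
        _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def _read_array(path: Path, spacing_override=None):
    """Return (data, spacing, sidecar_dict)."""
    path = Path(path)
    sidecar: dict = {}
    sc = _sidecar_path(path)
    if sc.exists():
        sidecar = json.loads(sc.read_text())
    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"expected 3D NIfTI, got shape {data.shape}")
        data = data.T
        zooms = img.header.get_zooms()[:3]  # (dx, dy, dz)
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    elif path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        with tifffile.TiffFile(str(path)) as tif:
            shapes = {page.shape for page in tif.pages}
            if len(shapes) != 1:
                raise ValueError(f"{path.name}: ragged slice shapes {sorted(shapes)}")
            data = tif.asarray()
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"expected a grayscale multi-page TIFF, got shape {data.shape}")
        if "spacing_mm" in sidecar:
            spacing = tuple(float(s) for s in sidecar["spacing_mm"])
        else:
            spacing = None
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)
    if spacing is None:
        raise ValueError(
            f"{path.name}: TIFF stacks need a JSON sidecar with 'spacing_mm' "
            "or an explicit spacing_override"
        )
    return data, spacing, sidecar


def write_volume(image: VoxelImage, path) -> None:
    """Write a :class:`VoxelImage` as TIFF (+sidecar) or NIfTI."""
    _write_array(image.data, image.spacing, Path(path))


def read_volume(path, spacing_override: tuple[float, float, float] | None = None) -> VoxelImage:
    """Read a TIFF stack or NIfTI file into a :class:`VoxelImage`.

    For TIFF, spacing comes from the ``<name>.json`` sidecar
    (``{"spacing_mm": [dz, dy, dx]}``) unless ``spacing_override`` is given.
    """
    data, spacing, _ = _read_array(Path(path), spacing_override)
    return VoxelImage(data, spacing)


def write_label_volume(labels: LabelVolume, path) -> None:
    """Write a label volume; material names persist in the JSON sidecar."""
    extra = {"material_names": {str(k): v for k, v in labels.material_names.items()}}
    _write_array(labels.labels, labels.spacing, Path(path), sidecar_extra=extra)


def read_label_volume(path, spacing_override=None) -> LabelVolume:
    """Read an integer-typed label volume and its material-name sidecar."""
    data, spacing, sidecar = _read_array(Path(path), spacing_override)
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError(f"label volume must be integer-typed, got {data.dtype}")
    names = sidecar.get("material_names")
    if names is None:
        raise ValueError(f"{Path(path).name}: no material_names sidecar found")
    return LabelVolume(data, spacing, {int(k): v for k, v in names.items()})
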