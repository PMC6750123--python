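"""Core image and transform data model plus NIfTI / JSON readers and writers.

All spatial reasoning in this package happens in *world* coordinates
(RAS+ millimetres as carried by the NIfTI affine); voxel indices are only
ever touched at the interpolation boundary.  An :class:`AffineTransform`
labelled ``a -> b`` is a *pull-back* (resampling) map: given a world point
in space *b* it returns the corresponding world point in space *a*.  Under
this convention composing a subject->mediator map with a mediator->template
map is a plain matrix product (see :mod:`medbridge.mediator`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Volume",
    "BinaryMask",
    "AffineTransform",
    "MediatorEntry",
    "MediatorLibrary",
    "TRANSFORM_CONVENTION",
    "params_to_matrix",
    "matrix_to_params",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_transform",
    "write_transform",
    "load_library",
    "write_library_manifest",
]

#: Convention tag stored in every transform JSON file.  Matrices operate on
#: world (mm) coordinates and map points of the ``to_space`` into points of
#: the ``from_space`` (pull-back).
TRANSFORM_CONVENTION = "pullback-ras-mm"

IDENTITY_PARAMS = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 0, 0, 0], dtype=float)


def _check_affine(affine: np.ndarray, what: str = "affine") -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"{what} must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError(f"{what} is singular")
    if not np.allclose(affine[3], [0, 0, 0, 1], atol=1e-9):
        raise ValueError(f"{what} last row must be (0,0,0,1)")
    return affine


@dataclass
class Volume:
    """A 3D scalar voxel grid with a voxel->world (mm) mapping.

    ``voxel_to_world`` maps 0-based voxel *centre* indices to world
    coordinates, following the NIfTI convention.
    """

    data: np.ndarray
    voxel_to_world: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float32)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume intensities must be finite")
        self.voxel_to_world = _check_affine(self.voxel_to_world, "voxel_to_world")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def world_to_voxel(self) -> np.ndarray:
        return np.linalg.inv(self.voxel_to_world)

    def voxel_sizes(self) -> np.ndarray:
        """Edge lengths of a voxel in mm along each axis."""
        return np.sqrt((self.voxel_to_world[:3, :3] ** 2).sum(axis=0))

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """Map an (3, N) array of voxel indices to (3, N) world points."""
        ijk = np.asarray(indices, dtype=float)
        return self.voxel_to_world[:3, :3] @ ijk + self.voxel_to_world[:3, 3:4]

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.voxel_to_world.copy())


@dataclass
class BinaryMask:
    """A {0,1}-valued 3D grid sharing Volume's spatial semantics."""

    data: np.ndarray
    voxel_to_world: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"BinaryMask data must be 3D, got ndim={arr.ndim}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"BinaryMask values must be 0/1, found {uniq[:5]}")
        self.data = arr.astype(np.uint8)
        self.voxel_to_world = _check_affine(self.voxel_to_world, "voxel_to_world")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def world_to_voxel(self) -> np.ndarray:
        return np.linalg.inv(self.voxel_to_world)

    def count(self) -> int:
        return int(self.data.sum())

    def as_volume(self) -> Volume:
        return Volume(self.data.astype(np.float32), self.voxel_to_world.copy())


# ---------------------------------------------------------------------------
# 12-parameter affine transforms
# ---------------------------------------------------------------------------

def _euler_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    # Intrinsic Z-Y-X rotation, angles in degrees.
    return Rotation.from_euler("ZYX", [rz, ry, rx], degrees=True).as_matrix()


def params_to_matrix(params: Sequence[float]) -> np.ndarray:
    """Build the 4x4 world->world matrix from 12 affine parameters.

    Parameter order: ``(rx, ry, rz, tx, ty, tz, sx, sy, sz, hxy, hxz, hyz)``
    with rotations in degrees, translations in mm, scales dimensionless and
    shears dimensionless.  Application order: scale, then shear (unit upper
    triangular), then rotation (intrinsic Z-Y-X), then translation.
    """
    p = np.asarray(params, dtype=float)
    if p.shape != (12,):
        raise ValueError(f"expected 12 parameters, got shape {p.shape}")
    rx, ry, rz, tx, ty, tz, sx, sy, sz, hxy, hxz, hyz = p
    scale = np.diag([sx, sy, sz])
    shear = np.array([[1.0, hxy, hxz], [0.0, 1.0, hyz], [0.0, 0.0, 1.0]])
    rot = _euler_matrix(rx, ry, rz)
    mat = np.eye(4)
    mat[:3, :3] = rot @ shear @ scale
    mat[:3, 3] = (tx, ty, tz)
    return mat


def matrix_to_params(matrix: np.ndarray) -> np.ndarray:
    """Decompose a 4x4 affine into the 12 parameters of :func:`params_to_matrix`.

    Uses a QR factorisation of the linear part with signs normalised so that
    all three scales are positive.  The decomposition is unique (and the
    round-trip exact to ~1e-12) for positive scales and rotations within
    (-90 deg, 90 deg).
    """
    matrix = _check_affine(matrix, "matrix")
    lin = matrix[:3, :3]
    q, r = np.linalg.qr(lin)
    # normalise so the upper-triangular factor has positive diagonal
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    q = q * signs[np.newaxis, :]
    r = r * signs[:, np.newaxis]
    if np.linalg.det(q) < 0:
        # proper rotations only; fold the reflection into the scales
        q = -q
        r = -r
        signs = np.sign(np.diag(r))
        signs[signs == 0] = 1.0
        q = q * signs[np.newaxis, :]
        r = r * signs[:, np.newaxis]
    rz, ry, rx = Rotation.from_matrix(q).as_euler("ZYX", degrees=True)
    scales = np.diag(r).copy()
    shear_mat = r / scales[np.newaxis, :]
    return np.array(
        [
            rx, ry, rz,
            matrix[0, 3], matrix[1, 3], matrix[2, 3],
            scales[0], scales[1], scales[2],
            shear_mat[0, 1], shear_mat[0, 2], shear_mat[1, 2],
        ]
    )


@dataclass
class AffineTransform:
    """12-parameter world->world affine with labelled source/target spaces.

    A transform labelled ``from_space -> to_space`` is the pull-back map:
    ``matrix @ p`` takes a homogeneous world point ``p`` expressed in
    ``to_space`` to the corresponding world point in ``from_space``.
    """

    matrix: np.ndarray
    from_space: str = "unnamed"
    to_space: str = "unnamed"

    def __post_init__(self) -> None:
        self.matrix = _check_affine(self.matrix, "matrix")

    @classmethod
    def identity(cls, from_space: str = "unnamed", to_space: str = "unnamed") -> "AffineTransform":
        return cls(np.eye(4), from_space, to_space)

    @classmethod
    def from_params(
        cls, params: Sequence[float], from_space: str = "unnamed", to_space: str = "unnamed"
    ) -> "AffineTransform":
        return cls(params_to_matrix(params), from_space, to_space)

    @property
    def params(self) -> np.ndarray:
        return matrix_to_params(self.matrix)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (3, N) array of world points of ``to_space`` into ``from_space``."""
        pts = np.asarray(points, dtype=float)
        squeeze = pts.ndim == 1
        if squeeze:
            pts = pts[:, np.newaxis]
        out = self.matrix[:3, :3] @ pts + self.matrix[:3, 3:4]
        return out[:, 0] if squeeze else out

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), self.to_space, self.from_space)

    def relabel(self, from_space: str, to_space: str) -> "AffineTransform":
        return replace(self, from_space=from_space, to_space=to_space)


# ---------------------------------------------------------------------------
# Mediator library
# ---------------------------------------------------------------------------

@dataclass
class MediatorEntry:
    """One mediator: an image with a pre-determined transform into template space."""

    id: str
    volume: Volume
    to_template: AffineTransform
    mask: Optional[BinaryMask] = None


@dataclass
class MediatorLibrary:
    """The library of intermediate images with known transforms to the template."""

    template: Volume
    template_mask: BinaryMask
    entries: list[MediatorEntry] = field(default_factory=list)
    space_label: str = "template"

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate mediator ids in library")
        for e in self.entries:
            if e.to_template.to_space != self.space_label:
                raise ValueError(
                    f"mediator {e.id!r}: transform targets {e.to_template.to_space!r}, "
                    f"library space is {self.space_label!r}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def ids(self) -> list[str]:
        return [e.id for e in self.entries]

    def entry(self, mediator_id: str) -> MediatorEntry:
        for e in self.entries:
            if e.id == mediator_id:
                return e
        raise KeyError(mediator_id)

    def subset(self, keep_ids: Sequence[str]) -> "MediatorLibrary":
        """New library keeping only ``keep_ids``, original order preserved."""
        keep = set(keep_ids)
        unknown = keep - set(self.ids())
        if unknown:
            raise KeyError(f"unknown mediator ids: {sorted(unknown)}")
        return MediatorLibrary(
            template=self.template,
            template_mask=self.template_mask,
            entries=[e for e in self.entries if e.id in keep],
            space_label=self.space_label,
        )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> Volume:
    """Load a 3D scalar NIfTI-1 file as a :class:`Volume`.

    The file's best available spatial mapping (as chosen by nibabel's
    ``affine``) is used; intensities are cast to float32.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[3] == 1 else data
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    affine = img.affine
    if affine is None or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError(f"{path}: degenerate spatial mapping")
    data = np.ascontiguousarray(data, dtype=np.float32)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: non-finite intensities")
    return Volume(data, affine)


def write_volume(v: Volume | BinaryMask, path: str | Path) -> Path:
    """Write a Volume or BinaryMask as NIfTI-1; round-trips through read_volume."""
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    data = v.data
    if isinstance(v, BinaryMask):
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, v.voxel_to_world)
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path) -> BinaryMask:
    """Load a NIfTI file whose values are {0,1} as a :class:`BinaryMask`."""
    v = read_volume(path)
    return BinaryMask((v.data > 0.5).astype(np.uint8), v.voxel_to_world)


def write_mask(m: BinaryMask, path: str | Path) -> Path:
    return write_volume(m, path)


# ---------------------------------------------------------------------------
# Transform JSON I/O
# ---------------------------------------------------------------------------

def read_transform(path: str | Path) -> AffineTransform:
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("matrix", "from_space", "to_space", "convention"):
        if key not in doc:
            raise ValueError(f"{path}: transform file missing {key!r}")
    if doc["convention"] != TRANSFORM_CONVENTION:
        raise ValueError(
            f"{path}: unsupported transform convention {doc['convention']!r} "
            f"(expected {TRANSFORM_CONVENTION!r})"
        )
    vals = np.asarray(doc["matrix"], dtype=float)
    if vals.shape != (16,):
        raise ValueError(f"{path}: matrix must hold 16 row-major values")
    return AffineTransform(vals.reshape(4, 4), doc["from_space"], doc["to_space"])


def write_transform(t: AffineTransform, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "matrix": [float(x) for x in t.matrix.reshape(-1)],
        "from_space": t.from_space,
        "to_space": t.to_space,
        "convention": TRANSFORM_CONVENTION,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
    return path


# ---------------------------------------------------------------------------
# Library manifest I/O
# ---------------------------------------------------------------------------

def load_library(manifest_path: str | Path) -> MediatorLibrary:
    """Load a mediator library from a JSON manifest.

    Manifest schema::

        {"space": str, "template": path, "template_mask": path,
         "mediators": [{"id": str, "volume": path, "transform": path,
                        "mask": path?}, ...]}

    Relative paths are resolved against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        doc = json.load(fh)
    base = manifest_path.parent

    def _p(rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else base / p

    space = doc["space"]
    template = read_volume(_p(doc["template"]))
    template_mask = read_mask(_p(doc["template_mask"]))
    entries = []
    for med in doc["mediators"]:
        t = read_transform(_p(med["transform"]))
        mask = read_mask(_p(med["mask"])) if med.get("mask") else None
        entries.append(
            MediatorEntry(
                id=med["id"],
                volume=read_volume(_p(med["volume"])),
                to_template=t,
                mask=mask,
            )
        )
    return MediatorLibrary(template, template_mask, entries, space)


def write_library_manifest(library: MediatorLibrary, out_dir: str | Path) -> Path:
    """Materialise a library to ``out_dir`` (NIfTI + JSON files + manifest)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_volume(library.template, out_dir / "template.nii.gz")
    write_mask(library.template_mask, out_dir / "template_mask.nii.gz")
    meds = []
    for e in library.entries:
        write_volume(e.volume, out_dir / f"{e.id}.nii.gz")
        write_transform(e.to_template, out_dir / f"{e.id}_to_template.json")
        rec = {
            "id": e.id,
            "volume": f"{e.id}.nii.gz",
            "transform": f"{e.id}_to_template.json",
        }
        if e.mask is not None:
            write_mask(e.mask, out_dir / f"{e.id}_mask.nii.gz")
            rec["mask"] = f"{e.id}_mask.nii.gz"
        meds.append(rec)
    manifest = {
        "space": library.space_label,
        "template": "template.nii.gz",
        "template_mask": "template_mask.nii.gz",
        "mediators": meds,
    }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest_path
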