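"""Synthetic T1-like brain phantoms with exactly known affine ground truth.

The generator emulates the situations that make whole-head affine
registration hard in practice: nested tissue compartments of distinct
intensity (WM core, GM shell, CSF rim, a skull shell), a bright non-brain
"neck" block entering an enlarged sagittal-style field of view, random
affine pose perturbations, additive Gaussian noise and a smooth
multiplicative bias field.  Every sample carries its true pull-back
transform into the canonical (template) space, so registration accuracy,
mediator selection and transform composition are all checkable against
construction rather than against another registration.

All randomness flows from explicit integer seeds; identical calls are
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .registration import resample, resample_mask_nn
from .volumes_io import (
    AffineTransform,
    BinaryMask,
    MediatorEntry,
    MediatorLibrary,
    Volume,
    params_to_matrix,
)

__all__ = ["PhantomSpec", "PhantomSample", "make_canonical_brain", "perturb", "make_cohort"]

# fraction of each axis' world half-extent occupied by the outer skull surface
BASE_AXIS_FRACTIONS = np.array([0.68, 0.84, 0.63])  # x, y, z

# normalised-radius boundaries of the nested compartments
RHO_WM, RHO_GM, RHO_CSF, RHO_SKULL_IN, RHO_SKULL_OUT = 0.62, 0.85, 0.92, 0.98, 1.08

AXIS_JITTER = 0.02        # per-seed, per-axis semi-axis jitter (fraction)
HARMONIC_AMPLITUDE = 0.02  # per-seed low-order surface perturbation
INTERNAL_JITTER = 0.25    # per-seed jitter of internal structures (ventricles etc.)

# pose sanity limits accepted by perturb()
MAX_ROT_DEG, MAX_TRANS_MM, SCALE_RANGE = 30.0, 40.0, (0.8, 1.25)


@dataclass
class PhantomSpec:
    """Study conditions for phantom generation.

    The default desk-scale grid is 96^3 voxels at 2 mm isotropic; tissue
    means are T1-like (WM brightest, CSF darkest, neck muscle/fat bright
    enough to disturb intensity-driven registration).
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    anatomy_seed: int = 0
    tissue_intensities: dict = field(
        default_factory=lambda: {"csf": 45.0, "gm": 140.0, "wm": 210.0, "skull": 90.0, "neck": 170.0}
    )
    noise_sigma: float = 4.0
    bias_field_amplitude: float = 0.10
    neck_extent: float = 40.0  # mm of extra inferior FOV; 0 disables
    fov_pad_mm: float = 24.0   # extra FOV on every face of test subjects
    pose: np.ndarray = field(
        default_factory=lambda: np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 0, 0, 0], dtype=float)
    )

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        vals = list(self.tissue_intensities.values())
        if len(set(vals)) != len(vals):
            raise ValueError("tissue intensity means must be distinct")


@dataclass
class PhantomSample:
    """A generated volume, its brain mask, and the true pull-back to canonical space.

    ``true_to_canonical`` maps canonical-space world points to this sample's
    world points (sample -> canonical in the pull-back sense), so resampling
    the sample through it lands it on the canonical anatomy.
    """

    volume: Volume
    brain_mask: BinaryMask
    true_to_canonical: AffineTransform
    id: str = ""
    generating_mediator: Optional[str] = None


def _centered_affine(shape: Sequence[int], voxel_size: Sequence[float]) -> np.ndarray:
    """Axis-aligned voxel->world map putting the grid centre at the world origin."""
    shape = np.asarray(shape, dtype=float)
    vs = np.asarray(voxel_size, dtype=float)
    aff = np.eye(4)
    aff[:3, :3] = np.diag(vs)
    aff[:3, 3] = -(shape - 1) / 2.0 * vs
    return aff


def _world_axes(shape: Sequence[int], affine: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # axis-aligned affine assumed (always true for generated grids)
    xs = affine[0, 0] * np.arange(shape[0]) + affine[0, 3]
    ys = affine[1, 1] * np.arange(shape[1]) + affine[1, 3]
    zs = affine[2, 2] * np.arange(shape[2]) + affine[2, 3]
    return xs, ys, zs


def make_canonical_brain(seed: int, spec: PhantomSpec | None = None) -> PhantomSample:
    """Deterministic canonical-pose brain phantom for a given anatomy seed.

    Nested smooth ellipsoidal compartments with per-seed shape jitter
    (semi-axis lengths +-5%, plus a low-order harmonic surface
    perturbation); the brain mask covers WM + GM + the CSF interior; the
    pose is identity and ``true_to_canonical`` is the identity transform.
    """
    if spec is None:
        spec = PhantomSpec()
    shape = tuple(int(s) for s in spec.grid_shape)
    if min(shape) < 32:
        raise ValueError("grid too small to contain the brain (need >= 32 voxels per axis)")
    rng = np.random.default_rng(seed)

    affine = _centered_affine(shape, spec.voxel_size)
    half_extent = (np.asarray(shape) - 1) / 2.0 * np.asarray(spec.voxel_size)
    semi_axes = BASE_AXIS_FRACTIONS * half_extent
    semi_axes = semi_axes * (1.0 + rng.uniform(-AXIS_JITTER, AXIS_JITTER, size=3))
    harm = rng.normal(0.0, HARMONIC_AMPLITUDE, size=5)

    xs, ys, zs = _world_axes(shape, affine)
    u = (xs / semi_axes[0])[:, None, None]
    v = (ys / semi_axes[1])[None, :, None]
    w = (zs / semi_axes[2])[None, None, :]
    rho0 = np.sqrt(u * u + v * v + w * w)
    safe = np.maximum(rho0, 1e-9)
    dx, dy, dz = u / safe, v / safe, w / safe
    # low-order real harmonics modulating the surface radius
    mod = 1.0 + (
        harm[0] * dx * dy
        + harm[1] * dy * dz
        + harm[2] * dx * dz
        + harm[3] * (dx * dx - dy * dy)
        + harm[4] * (3.0 * dz * dz - 1.0) / 2.0
    )
    rho = rho0 / np.maximum(mod, 0.5)

    ti = spec.tissue_intensities
    img = np.zeros(shape, dtype=np.float32)
    img[rho < RHO_WM] = ti["wm"]
    img[(rho >= RHO_WM) & (rho < RHO_GM)] = ti["gm"]
    img[(rho >= RHO_GM) & (rho < RHO_CSF)] = ti["csf"]
    img[(rho >= RHO_SKULL_IN) & (rho < RHO_SKULL_OUT)] = ti["skull"]

    # Internal anatomy serves two purposes.  Without it the nested shells
    # are concentric near-ellipsoids, on which rotation and shear are
    # mutually confusable under a 12-dof fit (a rotated ellipsoid is a
    # sheared one); ventricles, nuclei and an off-axis lobe anchor the pose
    # the way real anatomy does.  And its strong per-seed jitter carries
    # most of the between-anatomy variation — mirroring real cohorts, where
    # ventricle size varies far more than the brain envelope — without
    # touching the brain mask, which internal structure does not enter.
    def _blob(center_frac, axes_frac, jitter=INTERNAL_JITTER):
        c = semi_axes * np.asarray(center_frac) * (1 + rng.uniform(-jitter, jitter, 3))
        a = semi_axes * np.asarray(axes_frac) * (1 + rng.uniform(-jitter, jitter, 3))
        return (
            ((xs - c[0]) / a[0])[:, None, None] ** 2
            + ((ys - c[1]) / a[1])[None, :, None] ** 2
            + ((zs - c[2]) / a[2])[None, None, :] ** 2
        ) < 1.0

    inside_wm = rho < RHO_WM
    for side in (-1.0, 1.0):
        vent = _blob((side * 0.16, -0.05, 0.12), (0.07, 0.30, 0.10))
        img[vent & inside_wm] = ti["csf"]
        thal = _blob((side * 0.14, 0.18, -0.05), (0.10, 0.12, 0.10))
        img[thal & inside_wm] = ti["gm"]
    lobe = _blob((0.0, 0.52, -0.45), (0.42, 0.30, 0.28))
    img[lobe & inside_wm] = ti["gm"]
    stem = _blob((0.04, 0.30, -0.55), (0.12, 0.14, 0.30))
    img[stem & (rho < RHO_GM)] = ti["wm"]

    img = ndimage.gaussian_filter(img, sigma=0.75)

    mask = (rho <= RHO_CSF).astype(np.uint8)
    frac = mask.mean()
    if not (0.02 < frac < 0.6):
        raise ValueError(f"degenerate phantom geometry: brain fraction {frac:.3f}")

    return PhantomSample(
        volume=Volume(img, affine),
        brain_mask=BinaryMask(mask, affine),
        true_to_canonical=AffineTransform.identity("canonical", "canonical"),
        id=f"canonical-{seed}",
    )


def _bias_field(shape: Sequence[int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    coarse = rng.normal(size=(4, 4, 4))
    zoom = np.asarray(shape) / 4.0
    fld = ndimage.zoom(coarse, zoom, order=3, grid_mode=True, mode="nearest")
    fld = fld[: shape[0], : shape[1], : shape[2]]
    peak = np.abs(fld).max()
    if peak > 0:
        fld /= peak
    return 1.0 + amplitude * fld


def perturb(
    sample: PhantomSample,
    pose: Sequence[float],
    fov: str = "same",
    noise_sigma: float = 0.0,
    bias_amplitude: float = 0.0,
    seed: int = 0,
    neck_extent: float = 40.0,
    neck_intensity: float = 170.0,
    pad_mm: float = 0.0,
) -> PhantomSample:
    """Re-pose a phantom under an exact affine, with optional FOV/noise/bias.

    ``pose`` gives 12 affine parameters P; the new sample shows the old
    anatomy moved by P (a pure +10 mm x translation moves the brain
    centroid +10 mm in world coordinates).  ``fov="neck"`` pads the grid
    inferiorly by ``neck_extent`` mm and inserts a bright anatomy-attached
    neck block below the brain; ``pad_mm`` grows the FOV on every face,
    emulating the generous sagittal FOVs of clinical T1 protocols (the
    padded margin holds genuine air, so a padded sample fully covers a
    tight-FOV grid after alignment).  The returned ``true_to_canonical``
    is the exact composed pull-back (P applied after the input sample's
    own map); the mask is moved with nearest-neighbour interpolation.
    """
    pose = np.asarray(pose, dtype=float)
    rot, trans, scales = pose[:3], pose[3:6], pose[6:9]
    if np.any(np.abs(rot) > MAX_ROT_DEG) or np.any(np.abs(trans) > MAX_TRANS_MM):
        raise ValueError("pose rotation/translation out of sane range")
    if np.any(scales < SCALE_RANGE[0]) or np.any(scales > SCALE_RANGE[1]):
        raise ValueError("pose scale out of sane range")
    if fov not in ("same", "neck"):
        raise ValueError(f"unknown fov label {fov!r}")

    pose_mat = params_to_matrix(pose)
    rng = np.random.default_rng(seed)

    src_affine = sample.volume.voxel_to_world
    shape = list(sample.volume.shape)
    new_affine = src_affine.copy()
    if pad_mm > 0:
        for ax in range(3):
            step = src_affine[ax, ax]
            n_pad = int(np.ceil(pad_mm / abs(step)))
            shape[ax] += 2 * n_pad
            new_affine[ax, 3] -= n_pad * step
    if fov == "neck" and neck_extent > 0:
        vz = src_affine[2, 2]
        n_extra = int(np.ceil(neck_extent / abs(vz)))
        shape[2] += n_extra
        new_affine[2, 3] -= n_extra * vz

    grid = Volume(np.zeros(tuple(shape), dtype=np.float32), new_affine)
    # new(q) = old(P^-1 q): resample through the inverse pose
    inv_pose = AffineTransform(np.linalg.inv(pose_mat), "old", "new")
    vol = resample(sample.volume, grid, inv_pose)
    mask = resample_mask_nn(sample.brain_mask, grid, inv_pose)

    kept = mask.count()
    expected = sample.brain_mask.count() * abs(np.linalg.det(pose_mat[:3, :3]))
    if kept < 0.95 * expected:
        raise ValueError(
            f"brain clipped by FOV: kept {kept} of ~{expected:.0f} mask voxels"
        )

    data = vol.data.astype(np.float32)
    if fov == "neck" and neck_extent > 0:
        # The neck is anatomy-attached: defined below the brain in the
        # *input* sample's coordinates and carried through the same pose,
        # so it moves rigidly with the head (as a real neck does) while
        # still entering the enlarged FOV differently for every pose.
        src_xs, src_ys, src_zs = _world_axes(sample.volume.shape, src_affine)
        src_idx = np.argwhere(sample.brain_mask.data > 0)
        z_low = src_zs[src_idx[:, 2].min()]
        cx = src_xs[src_idx[:, 0]].mean()
        cy = src_ys[src_idx[:, 1]].mean()
        # input-sample world coordinates of every new-grid voxel
        C = np.linalg.inv(pose_mat) @ vol.voxel_to_world
        ii = np.arange(vol.shape[0])[:, None, None]
        jj = np.arange(vol.shape[1])[None, :, None]
        kk = np.arange(vol.shape[2])[None, None, :]
        x_o = C[0, 0] * ii + C[0, 1] * jj + C[0, 2] * kk + C[0, 3]
        y_o = C[1, 0] * ii + C[1, 1] * jj + C[1, 2] * kk + C[1, 3]
        z_o = C[2, 0] * ii + C[2, 1] * jj + C[2, 2] * kk + C[2, 3]
        neck_region = (
            (((x_o - cx) / 45.0) ** 2 + ((y_o - cy) / 55.0) ** 2 < 1.0)
            & (z_o < z_low - 4.0)
            & (z_o > z_low - 4.0 - (neck_extent + 10.0))
        )
        neck = np.where(neck_region, np.float32(neck_intensity), np.float32(0.0))
        neck = ndimage.gaussian_filter(neck, sigma=1.0)
        data = np.maximum(data, neck)

    if bias_amplitude > 0:
        data = data * _bias_field(vol.shape, bias_amplitude, rng).astype(np.float32)
    if noise_sigma > 0:
        data = data + rng.normal(0.0, noise_sigma, size=vol.shape).astype(np.float32)

    new_true = AffineTransform(
        pose_mat @ sample.true_to_canonical.matrix,
        from_space=sample.id or "sample",
        to_space=sample.true_to_canonical.to_space,
    )
    return PhantomSample(
        volume=Volume(data, vol.voxel_to_world),
        brain_mask=mask,
        true_to_canonical=new_true,
        id=sample.id,
        generating_mediator=sample.generating_mediator,
    )


def _random_pose(
    rng: np.random.Generator,
    max_rot: float,
    max_trans: float,
    scale_lo: float,
    scale_hi: float,
    max_shear: float,
) -> np.ndarray:
    return np.concatenate(
        [
            rng.uniform(-max_rot, max_rot, 3),
            rng.uniform(-max_trans, max_trans, 3),
            rng.uniform(scale_lo, scale_hi, 3),
            rng.uniform(-max_shear, max_shear, 3),
        ]
    )


def make_cohort(
    n_mediators: int,
    n_subjects: int,
    seed: int,
    spec: PhantomSpec | None = None,
    subject_pose_scale: float = 1.0,
) -> tuple[MediatorLibrary, list[PhantomSample]]:
    """Generate a mediator library plus test subjects with full ground truth.

    The canonical space is the template.  Each mediator has its own anatomy
    seed (distinct brain shape) and a random pose; its stored to-template
    transform is the exact inverse-pose pull-back, playing the role of the
    library's pre-determined transforms.  Each subject reuses one
    designated mediator's anatomy seed (recorded in
    ``PhantomSample.generating_mediator``) under an additional random pose,
    noise and bias draw, so the correct mediator for every subject is known
    by construction.
    """
    if n_mediators < 1 or n_subjects < 1:
        raise ValueError("need at least one mediator and one subject")
    if spec is None:
        spec = PhantomSpec()
    master = np.random.default_rng(seed)
    anat_seeds = master.integers(0, 2**31 - 1, size=n_mediators)

    template_sample = make_canonical_brain(int(master.integers(0, 2**31 - 1)), spec)
    template = template_sample.volume
    template_mask = template_sample.brain_mask
    space = "template"

    entries: list[MediatorEntry] = []
    mediator_canonicals: dict[str, PhantomSample] = {}
    for i in range(n_mediators):
        mid = f"m{i:02d}"
        canon = make_canonical_brain(int(anat_seeds[i]), spec)
        canon = replace(canon, id=mid, true_to_canonical=AffineTransform.identity(mid, space))
        mediator_canonicals[mid] = canon
        pose = _random_pose(master, 10.0, 12.0, 0.93, 1.08, 0.03)
        med = perturb(
            canon,
            pose,
            fov="neck" if spec.neck_extent > 0 else "same",
            noise_sigma=spec.noise_sigma,
            bias_amplitude=spec.bias_field_amplitude,
            seed=int(master.integers(0, 2**31 - 1)),
            neck_extent=spec.neck_extent,
            neck_intensity=spec.tissue_intensities["neck"],
        )
        entries.append(
            MediatorEntry(
                id=mid,
                volume=med.volume,
                to_template=med.true_to_canonical.relabel(mid, space),
                mask=med.brain_mask,
            )
        )

    library = MediatorLibrary(template, template_mask, entries, space)

    subjects: list[PhantomSample] = []
    for j in range(n_subjects):
        sid = f"s{j:02d}"
        mid = entries[j % n_mediators].id
        canon = mediator_canonicals[mid]
        canon = replace(
            canon, id=sid, generating_mediator=mid,
            true_to_canonical=AffineTransform.identity(sid, space),
        )
        s = subject_pose_scale
        pose = _random_pose(master, 10.0 * s, 15.0 * s, 1 - 0.1 * s, 1 + 0.1 * s, 0.05 * s)
        subj = perturb(
            canon,
            pose,
            fov="neck" if spec.neck_extent > 0 else "same",
            noise_sigma=spec.noise_sigma,
            bias_amplitude=spec.bias_field_amplitude,
            seed=int(master.integers(0, 2**31 - 1)),
            neck_extent=spec.neck_extent,
            neck_intensity=spec.tissue_intensities["neck"],
            pad_mm=spec.fov_pad_mm,
        )
        subjects.append(subj)

    return library, subjects
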