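"""12-parameter affine registration by ratio-image-uniformity minimisation.

The cost is the coefficient of variation of the voxelwise ratio between the
fixed image and the resampled moving image over a thresholded overlap
domain — zero exactly when the images are proportional, so it needs no
intensity normalisation.  Optimisation runs coarse-to-fine over a Gaussian
pyramid, initialised by a centre-of-mass translation and, at the coarsest
level, staged rigid-before-affine to keep rotation and shear from trading
off against each other.  The default optimiser is L-BFGS-B on an analytic
cost gradient (image-gradient chain rule); a derivative-free Powell mode is
available via ``optimizer_name="powell"``.  Both paths are deterministic:
no stochastic restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from .volumes_io import AffineTransform, Volume, params_to_matrix

__all__ = [
    "RegistrationConfig",
    "RegistrationResult",
    "resample",
    "resample_mask_nn",
    "riu_cost",
    "center_of_mass_init",
    "register_affine",
]

# one step unit per parameter: 1 deg = 1 mm = 0.01 scale = 0.01 shear
PARAM_SCALES = np.array([1, 1, 1, 1, 1, 1, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01])

_RIGID = np.arange(6)
_FULL = np.arange(12)
_FAIL_COST = 1e6


@dataclass
class RegistrationConfig:
    """Knobs of the affine registration engine.

    pyramid_factors
        Integer downsampling factors, strictly decreasing and ending at 1.
        Each level Gaussian-smooths with sigma = factor/2 voxels before
        decimating.
    max_iterations
        Optimiser iteration cap per pyramid level; an int applies to every
        level, a sequence gives one cap per level (coarse to fine).
    param_tolerance
        Convergence tolerance in step units (1 deg / 1 mm / 0.01 scale or
        shear); maps to Powell's ``xtol`` and L-BFGS's projected-gradient
        scale.
    intensity_floor_fraction
        Fraction of each image's robust (99th percentile) maximum below
        which voxels are excluded from the ratio domain; keeps air
        background out of the cost without any segmentation.
    optimizer_name
        ``"lbfgs"`` (default; analytic gradient) or ``"powell"``
        (derivative-free).
    stage_rigid_first
        Keep the coarsest level rigid-only (rotation + translation).  At
        that level the heavily smoothed images cannot distinguish a true
        rotation from a compensating shear, so opening all 12 parameters
        there digs into wrong valleys; rigid-only refinement keeps the
        rotation honest and the full affine opens from the next level.
    rotation_search_deg
        Half-width (degrees) of a deterministic 3x3x3 rotation grid probed
        at the coarsest level around the centre-of-mass start.  The best
        ``n_rotation_starts`` cells are refined at the coarsest level; the
        two best survivors are refined again at the next level, where the
        pyramid has enough detail to tell the basins apart, and a single
        winner continues.  0 disables.
    n_rotation_starts
        How many of the probed rotation cells are refined at the coarsest
        level (>= 1).
    max_sample_points
        Cap on the number of fixed-image foreground voxels the optimiser
        evaluates the cost on per level (deterministic strided subsample);
        the reported ``final_cost`` is always the full-grid cost.
    """

    pyramid_factors: tuple[int, ...] = (4, 2, 1)
    max_iterations: int | Sequence[int] = (80, 40, 15)
    param_tolerance: float = 0.001
    intensity_floor_fraction: float = 0.05
    optimizer_name: str = "lbfgs"
    stage_rigid_first: bool = True
    rotation_search_deg: float = 10.0
    n_rotation_starts: int = 3
    max_sample_points: int = 40_000

    def __post_init__(self) -> None:
        f = tuple(int(x) for x in self.pyramid_factors)
        if not f or f[-1] != 1 or any(a <= b for a, b in zip(f, f[1:])):
            raise ValueError("pyramid_factors must be strictly decreasing and end at 1")
        self.pyramid_factors = f
        if self.param_tolerance <= 0:
            raise ValueError("param_tolerance must be positive")
        if not (0 < self.intensity_floor_fraction < 1):
            raise ValueError("intensity_floor_fraction must lie in (0,1)")
        if self.optimizer_name not in ("lbfgs", "powell"):
            raise ValueError("optimizer_name must be 'lbfgs' or 'powell'")

    def iterations_for_level(self, level: int) -> int:
        if np.isscalar(self.max_iterations):
            return int(self.max_iterations)  # type: ignore[arg-type]
        seq = list(self.max_iterations)  # type: ignore[arg-type]
        return int(seq[min(level, len(seq) - 1)])


@dataclass
class RegistrationResult:
    """Outcome of :func:`register_affine` (moving->fixed pull-back)."""

    transform: AffineTransform
    final_cost: float
    cost_trace: list[float] = field(default_factory=list)
    converged: bool = True


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample(moving: Volume, fixed_grid, t: AffineTransform, order: int = 1) -> Volume:
    """Resample ``moving`` onto ``fixed_grid``'s grid through the pull-back ``t``.

    Each output voxel is the interpolation (trilinear by default) of the
    moving image at the world point ``t`` maps it to; out-of-grid points
    get 0.
    """
    vmap = moving.world_to_voxel @ t.matrix @ fixed_grid.voxel_to_world
    out = ndimage.affine_transform(
        moving.data,
        vmap[:3, :3],
        offset=vmap[:3, 3],
        output_shape=fixed_grid.shape,
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=order > 1,
    )
    return Volume(out, np.array(fixed_grid.voxel_to_world, copy=True))


def resample_mask_nn(mask, fixed_grid, t: AffineTransform):
    """Nearest-neighbour mask resampling; output stays {0,1}."""
    from .volumes_io import BinaryMask

    vmap = np.linalg.inv(mask.voxel_to_world) @ t.matrix @ fixed_grid.voxel_to_world
    out = ndimage.affine_transform(
        mask.data,
        vmap[:3, :3],
        offset=vmap[:3, 3],
        output_shape=fixed_grid.shape,
        order=0,
        mode="constant",
        cval=0,
    )
    return BinaryMask(out.astype(np.uint8), np.array(fixed_grid.voxel_to_world, copy=True))


# ---------------------------------------------------------------------------
# Ratio-image-uniformity cost
# ---------------------------------------------------------------------------

def _robust_floor(data: np.ndarray, floor_fraction: float) -> float:
    return float(floor_fraction * np.percentile(data, 99))


def riu_cost(fixed: Volume, moving_resampled: Volume, floor_fraction: float = 0.05) -> float:
    """sd/mean of the fixed/moving intensity ratio over the overlap domain.

    The overlap domain is the set of voxels where each image exceeds
    ``floor_fraction`` of its own robust (99th percentile) maximum.  The
    standard deviation is the sample (n-1) estimate.  Zero exactly when the
    two images are proportional on the domain.
    """
    if fixed.shape != moving_resampled.shape:
        raise ValueError(f"grid mismatch: {fixed.shape} vs {moving_resampled.shape}")
    fthr = _robust_floor(fixed.data, floor_fraction)
    mthr = _robust_floor(moving_resampled.data, floor_fraction)
    domain = (fixed.data > fthr) & (moving_resampled.data > mthr)
    n = int(domain.sum())
    if n == 0:
        raise ValueError("empty overlap domain")
    ratio = fixed.data[domain].astype(np.float64) / moving_resampled.data[domain]
    mean = ratio.mean()
    if mean == 0:
        raise ValueError("zero mean ratio")
    sd = ratio.std(ddof=1) if n > 1 else 0.0
    return float(sd / mean)


# ---------------------------------------------------------------------------
# Initialisation
# ---------------------------------------------------------------------------

def _centroid_world(v: Volume) -> np.ndarray:
    total = float(v.data.sum())
    if total <= 0:
        raise ValueError("volume has non-positive total intensity")
    idx = np.array(ndimage.center_of_mass(v.data), dtype=float)
    return v.world_coords(idx[:, np.newaxis])[:, 0]


def center_of_mass_init(moving: Volume, fixed: Volume) -> AffineTransform:
    """Pure translation aligning intensity centroids (pull-back moving->fixed)."""
    com_m = _centroid_world(moving)
    com_f = _centroid_world(fixed)
    mat = np.eye(4)
    mat[:3, 3] = com_m - com_f
    return AffineTransform(mat, "moving", "fixed")


# ---------------------------------------------------------------------------
# Pyramid level machinery
# ---------------------------------------------------------------------------

def _smooth_decimate(v: Volume, factor: int) -> Volume:
    if factor == 1:
        return v
    sm = ndimage.gaussian_filter(v.data.astype(np.float32), sigma=factor / 2.0)
    dec = sm[::factor, ::factor, ::factor]
    step = np.diag([factor, factor, factor, 1]).astype(float)
    return Volume(np.ascontiguousarray(dec), v.voxel_to_world @ step)


def _fixed_samples(fixed: Volume, floor_fraction: float, cap: int):
    """World coordinates and values of fixed foreground voxels (strided)."""
    thr = _robust_floor(fixed.data, floor_fraction)
    ijk = np.argwhere(fixed.data > thr)
    if ijk.shape[0] == 0:
        raise ValueError("fixed image has no foreground voxels above the floor")
    stride = max(1, int(np.ceil(ijk.shape[0] / cap)))
    ijk = ijk[::stride]
    world = fixed.world_coords(ijk.T.astype(float))
    vals = fixed.data[tuple(ijk.T)].astype(np.float64)
    return world, vals


def _riu_from_samples(fixed_vals: np.ndarray, moving_vals: np.ndarray, mthr: float) -> float:
    sel = moving_vals > mthr
    n = int(sel.sum())
    if n < 16:
        return _FAIL_COST
    ratio = fixed_vals[sel] / moving_vals[sel]
    mean = ratio.mean()
    if mean <= 0:
        return _FAIL_COST
    return float(ratio.std(ddof=1) / mean)


def _param_jacobians(p: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """d(matrix)/d(param_k) for all 12 params, by central differences."""
    jacs = np.empty((12, 4, 4))
    for k in range(12):
        pp = p.copy()
        pm = p.copy()
        pp[k] += h
        pm[k] -= h
        jacs[k] = (params_to_matrix(pp) - params_to_matrix(pm)) / (2 * h)
    return jacs


class _LevelObjective:
    """RIU cost (and analytic gradient) on one pyramid level's sample points."""

    def __init__(self, fixed: Volume, moving: Volume, floor_fraction: float, cap: int):
        pts_world, self.fvals = _fixed_samples(fixed, floor_fraction, cap)
        self.pts_h = np.vstack([pts_world, np.ones((1, pts_world.shape[1]))])
        self.mthr = _robust_floor(moving.data, floor_fraction)
        self.mdata = moving.data.astype(np.float64)
        self.world_to_voxel3 = moving.world_to_voxel[:3]
        self._grads: tuple[np.ndarray, ...] | None = None

    def _interp(self, vol: np.ndarray, vox: np.ndarray) -> np.ndarray:
        return ndimage.map_coordinates(
            vol, vox, order=1, mode="constant", cval=0.0, prefilter=False
        )

    def value(self, params: np.ndarray) -> float:
        vox = self.world_to_voxel3 @ params_to_matrix(params) @ self.pts_h
        mvals = self._interp(self.mdata, vox)
        return _riu_from_samples(self.fvals, mvals, self.mthr)

    def value_and_grad(self, params: np.ndarray, free: np.ndarray) -> tuple[float, np.ndarray]:
        vox = self.world_to_voxel3 @ params_to_matrix(params) @ self.pts_h
        mvals = self._interp(self.mdata, vox)
        sel = mvals > self.mthr
        n = int(sel.sum())
        if n < 16:
            return _FAIL_COST, np.zeros(free.size)
        f = self.fvals[sel]
        m = mvals[sel]
        r = f / m
        mu = r.mean()
        s = r.std(ddof=1)
        if mu <= 0:
            return _FAIL_COST, np.zeros(free.size)
        cost = s / mu
        if s == 0:
            return 0.0, np.zeros(free.size)
        # dC/dr_i for C = sd(r)/mean(r), then chain through r = f/m and the
        # trilinear moving-image gradient at the mapped voxel coordinates
        dC_dr = (r - mu) / ((n - 1) * s * mu) - s / (mu * mu * n)
        dC_dm = dC_dr * (-f / (m * m))
        if self._grads is None:
            self._grads = tuple(np.ascontiguousarray(g) for g in np.gradient(self.mdata))
        gsel = [self._interp(g, vox)[sel] for g in self._grads]
        jacs = _param_jacobians(params)
        ph_sel = self.pts_h[:, sel]
        grad = np.empty(free.size)
        for out_i, k in enumerate(free):
            dvox = self.world_to_voxel3 @ jacs[k] @ ph_sel
            dm = gsel[0] * dvox[0] + gsel[1] * dvox[1] + gsel[2] * dvox[2]
            grad[out_i] = float(np.dot(dC_dm, dm))
        return cost, grad


def _optimize_level(
    obj: _LevelObjective, p: np.ndarray, free: np.ndarray, cfg: RegistrationConfig, maxiter: int
) -> np.ndarray:
    """Run one optimiser stage over the free parameter subset; keep the best."""
    scales = PARAM_SCALES[free]
    x0 = p[free] / scales

    if cfg.optimizer_name == "lbfgs":

        def fun(x):
            pp = p.copy()
            pp[free] = x * scales
            c, g = obj.value_and_grad(pp, free)
            return c, g * scales

        res = minimize(
            fun, x0, jac=True, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-10},
        )
    else:

        def fun(x):
            pp = p.copy()
            pp[free] = x * scales
            return obj.value(pp)

        res = minimize(
            fun, x0, method="Powell",
            options={"maxiter": maxiter, "xtol": cfg.param_tolerance, "ftol": 1e-8},
        )

    c0 = obj.value(p)
    if np.isfinite(res.fun) and res.fun <= c0:
        out = p.copy()
        out[free] = res.x * scales
        return out
    return p


def register_affine(
    moving: Volume, fixed: Volume, cfg: RegistrationConfig | None = None
) -> RegistrationResult:
    """Find the 12-parameter pull-back transform minimising the RIU cost.

    Returns the moving->fixed transform (given a fixed-space world point it
    yields the matching moving-space point), the full-grid cost at that
    transform, the per-level cost trace and a convergence flag
    (``converged=False`` when no pyramid level improved on the
    centre-of-mass initialisation).  Deterministic for a given config.
    """
    if cfg is None:
        cfg = RegistrationConfig()

    init = center_of_mass_init(moving, fixed)
    p = np.array(
        [0, 0, 0, init.matrix[0, 3], init.matrix[1, 3], init.matrix[2, 3], 1, 1, 1, 0, 0, 0],
        dtype=float,
    )

    cost_trace: list[float] = []
    improved_any = False
    multi_start = cfg.rotation_search_deg > 0 and cfg.n_rotation_starts >= 1
    candidates = [p]
    for level, factor in enumerate(cfg.pyramid_factors):
        fx = _smooth_decimate(fixed, factor)
        mv = _smooth_decimate(moving, factor)
        obj = _LevelObjective(fx, mv, cfg.intensity_floor_fraction, cfg.max_sample_points)
        maxiter = cfg.iterations_for_level(level)
        c_before = obj.value(candidates[0])

        # coarsest level: rigid only (shear would impersonate rotation in
        # the smoothed images); all 12 parameters from the next level on
        free = _RIGID if (level == 0 and cfg.stage_rigid_first) else _FULL

        if level == 0 and multi_start:
            # probe a rotation grid and refine the best few cells; the
            # smoothed coarsest level cannot reliably rank the resulting
            # basins, so the two best survivors are decided at the next
            # level
            step = cfg.rotation_search_deg
            probes = []
            for rx in (-step, 0.0, step):
                for ry in (-step, 0.0, step):
                    for rz in (-step, 0.0, step):
                        cand = candidates[0].copy()
                        cand[:3] += (rx, ry, rz)
                        probes.append((obj.value(cand), cand))
            probes.sort(key=lambda t: t[0])
            starts = [cand for _, cand in probes[: cfg.n_rotation_starts]]
        else:
            starts = candidates

        refined = [_optimize_level(obj, c, free, cfg, maxiter) for c in starts]
        refined.sort(key=obj.value)
        candidates = refined[: (2 if level == 0 and multi_start else 1)]

        c_after = obj.value(candidates[0])
        cost_trace.append(c_after)
        if c_after < c_before - 1e-15:
            improved_any = True

    transform = AffineTransform(params_to_matrix(candidates[0]), "moving", "fixed")
    final = riu_cost(fixed, resample(moving, fixed, transform), cfg.intensity_floor_fraction)
    return RegistrationResult(
        transform=transform,
        final_cost=final,
        cost_trace=cost_trace,
        converged=improved_any,
    )
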