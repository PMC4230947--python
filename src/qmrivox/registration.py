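"""Spatial normalisation: Gaussian smoothing, 12-parameter affine
registration and resampling onto a common isotropic grid.

Registration minimises the mean squared intensity difference between a
synthetic contrast image of the subject and the template image, over 12
affine parameters (3 translations mm, 3 rotations deg, 3 scales, 3 shears),
using analytic gradients and L-BFGS-B at three resolutions (coarse to
fine).  The estimated transform is the *pull-back* matrix M (template world
-> source world): resampling the source through M renders it on the
template grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .geometry import Grid
from .relaxometry import ParameterMaps

__all__ = [
    "AffineTransform",
    "smooth_gaussian",
    "estimate_affine",
    "apply_transform",
    "apply_and_regrid",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

_NEUTRAL = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 0, 0, 0], dtype=float)


def params_to_matrix(params: np.ndarray) -> np.ndarray:
    """Compose T * Rz * Ry * Rx * Shear * Scale into a 4x4 world matrix."""
    tx, ty, tz, rx, ry, rz, sx, sy, sz, hxy, hxz, hyz = params
    ax, ay, az = np.deg2rad([rx, ry, rz])
    cx, sx_ = np.cos(ax), np.sin(ax)
    cy, sy_ = np.cos(ay), np.sin(ay)
    cz, sz_ = np.cos(az), np.sin(az)
    rmx = np.array([[1, 0, 0], [0, cx, -sx_], [0, sx_, cx]])
    rmy = np.array([[cy, 0, sy_], [0, 1, 0], [-sy_, 0, cy]])
    rmz = np.array([[cz, -sz_, 0], [sz_, cz, 0], [0, 0, 1]])
    shear = np.array([[1, hxy, hxz], [0, 1, hyz], [0, 0, 1]], dtype=float)
    scale = np.diag([sx, sy, sz]).astype(float)
    m = np.eye(4)
    m[:3, :3] = rmz @ rmy @ rmx @ shear @ scale
    m[:3, 3] = (tx, ty, tz)
    return m


@dataclass
class AffineTransform:
    """12-parameter affine with its composed world-to-world matrix (mm).

    ``matrix`` maps template-world points to source-world points (pull-back
    convention used for resampling).
    """

    params: np.ndarray = field(default_factory=lambda: _NEUTRAL.copy())
    converged: bool = True
    final_cost: float = np.nan

    PARAM_NAMES = ("tx_mm", "ty_mm", "tz_mm", "rx_deg", "ry_deg", "rz_deg",
                   "sx", "sy", "sz", "hxy", "hxz", "hyz")

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.shape != (12,):
            raise ValueError("expected 12 affine parameters")

    @property
    def matrix(self) -> np.ndarray:
        return params_to_matrix(self.params)

    @property
    def translation_mm(self) -> np.ndarray:
        return self.params[:3]

    def inverse_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()

    def to_dict(self) -> dict:
        return {"convention": "pull-back, template world (mm) -> source world (mm)",
                "params": dict(zip(self.PARAM_NAMES, self.params.tolist())),
                "matrix": self.matrix.tolist(),
                "converged": bool(self.converged),
                "final_cost": float(self.final_cost)}


def smooth_gaussian(image: np.ndarray, fwhm: float, grid: Grid) -> np.ndarray:
    """Separable Gaussian smoothing with full-width-half-maximum in mm."""
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm == 0:
        return image.copy()
    sigma_vox = fwhm * FWHM_TO_SIGMA / grid.voxel_size
    return ndimage.gaussian_filter(np.asarray(image, dtype=float), sigma_vox,
                                   mode="constant", cval=0.0)


def _downsample(image: np.ndarray, grid: Grid, factor: int):
    """Block-mean downsampling with the matching affine."""
    if factor == 1:
        return image, grid
    shape = tuple(s // factor for s in image.shape)
    trimmed = image[: shape[0] * factor, : shape[1] * factor, : shape[2] * factor]
    small = trimmed.reshape(shape[0], factor, shape[1], factor,
                            shape[2], factor).mean(axis=(1, 3, 5))
    affine = grid.affine.copy()
    affine[:3, :3] *= factor
    # centre of the factor^3 block in old voxel coords is (factor-1)/2
    affine[:3, 3] = grid.affine[:3, :3] @ (np.full(3, (factor - 1) / 2.0)) \
        + grid.affine[:3, 3]
    return small, Grid(shape, affine)


def _cost_and_grad(params, src, src_grad, src_grid, tmpl, tmpl_world, dmats):
    """Mean squared difference and its gradient w.r.t. the 12 parameters."""
    m = params_to_matrix(params)
    w2v = np.linalg.inv(src_grid.affine)
    pts = (w2v @ m) @ tmpl_world  # (4, n) voxel coords in source
    coords = pts[:3]
    warped = ndimage.map_coordinates(src, coords, order=1, mode="constant",
                                     cval=0.0, prefilter=False)
    diff = warped - tmpl
    n = diff.size
    cost = float((diff ** 2).mean())
    # gradient of source in world units, sampled at the warped locations
    g = np.empty((3, n))
    for a in range(3):
        g[a] = ndimage.map_coordinates(src_grad[a], coords, order=1,
                                       mode="constant", cval=0.0,
                                       prefilter=False)
    g_world = w2v[:3, :3].T @ g  # chain rule voxel->world
    grad = np.empty(12)
    for k in range(12):
        dpts = dmats[k] @ tmpl_world  # (4, n) world displacement per unit param
        grad[k] = 2.0 / n * (diff * (g_world * dpts[:3]).sum(axis=0)).sum()
    return cost, grad


def _dmatrices(params: np.ndarray, h: float = 1e-6) -> list[np.ndarray]:
    mats = []
    for k in range(12):
        p1 = params.copy()
        p2 = params.copy()
        p1[k] -= h
        p2[k] += h
        mats.append((params_to_matrix(p2) - params_to_matrix(p1)) / (2 * h))
    return mats


def estimate_affine(
    source_image: np.ndarray,
    template_image: np.ndarray,
    source_grid: Grid,
    template_grid: Grid | None = None,
    levels: tuple[int, ...] = (4, 2, 1),
    max_iter: tuple[int, ...] = (120, 60, 30),
    init: AffineTransform | None = None,
) -> AffineTransform:
    """Estimate the 12-parameter affine aligning source to template.

    Both images should already be smoothed; the optimisation is a
    deterministic multi-resolution L-BFGS-B descent on the mean squared
    difference, warm-started from the previous level (or ``init``).
    Divergence at any level keeps the best parameters seen so far and sets
    ``converged`` to False.
    """
    template_grid = template_grid or source_grid
    if source_image.shape != tuple(source_grid.shape):
        raise ValueError("source image does not match its grid")
    if template_image.shape != tuple(template_grid.shape):
        raise ValueError("template image does not match its grid")
    scale = max(float(np.abs(template_image).max()),
                float(np.abs(source_image).max()), 1e-30)
    src_full = np.asarray(source_image, dtype=float) / scale
    tmpl_full = np.asarray(template_image, dtype=float) / scale

    params = (init.params.copy() if init is not None else _NEUTRAL.copy())
    ok = True
    cost = np.inf
    for level, iters in zip(levels, max_iter):
        src, sgrid = _downsample(src_full, source_grid, level)
        tmpl, tgrid = _downsample(tmpl_full, template_grid, level)
        src_grad = np.array(np.gradient(src))  # voxel units
        idx = np.indices(tgrid.shape, dtype=float).reshape(3, -1)
        tmpl_world = tgrid.affine @ np.vstack([idx, np.ones(idx.shape[1])])
        tmpl_flat = tmpl.reshape(-1)

        # scale parameters to comparable sensitivity for the optimiser
        # (mm, deg, unit scale/shear)
        psc = np.array([5.0, 5.0, 5.0, 5.0, 5.0, 5.0,
                        0.05, 0.05, 0.05, 0.05, 0.05, 0.05])
        offset = _NEUTRAL
        best = {"cost": np.inf, "params": params.copy()}

        def fun(q):
            p = offset + q * psc
            c, g = _cost_and_grad(p, src, src_grad, sgrid, tmpl_flat,
                                  tmpl_world, _dmatrices(p))
            if c < best["cost"]:
                best["cost"], best["params"] = c, p.copy()
            return c, g * psc

        cost_start = fun((params - offset) / psc)[0]
        # restart around aborted line searches: the sampled image gradient is
        # approximate, so L-BFGS can terminate early past the optimum
        prev = np.inf
        for _ in range(3):
            optimize.minimize(
                fun, (best["params"] - offset) / psc, jac=True,
                method="L-BFGS-B",
                options={"maxiter": iters, "ftol": 1e-14, "gtol": 1e-12})
            if best["cost"] >= prev * (1.0 - 1e-6):
                break
            prev = best["cost"]
        if np.isfinite(best["cost"]) and best["cost"] <= cost_start + 1e-12:
            params, cost = best["params"], float(best["cost"])
        else:
            ok = False
            cost = float(cost_start)
    return AffineTransform(params, converged=ok, final_cost=cost)


def apply_transform(data: np.ndarray, source_grid: Grid, matrix: np.ndarray,
                    target_grid: Grid, order: int = 1) -> np.ndarray:
    """Resample ``data`` through a pull-back ``matrix`` onto ``target_grid``."""
    vox2vox = np.linalg.inv(source_grid.affine) @ matrix @ target_grid.affine
    return ndimage.affine_transform(
        np.asarray(data, dtype=float), vox2vox[:3, :3], vox2vox[:3, 3],
        output_shape=tuple(target_grid.shape), order=order, mode="constant",
        cval=0.0, prefilter=(order > 1))


def apply_and_regrid(maps: ParameterMaps, transform: AffineTransform,
                     target_grid: Grid) -> ParameterMaps:
    """Normalise parameter maps onto the common isotropic grid.

    Trilinear interpolation for the parameter values, nearest neighbour for
    the brain mask.  Raises if the transform moves the brain entirely
    outside the target field of view.
    """
    m = transform.matrix
    r1 = apply_transform(maps.r1, maps.grid, m, target_grid, order=1)
    r2 = apply_transform(maps.r2, maps.grid, m, target_grid, order=1)
    pdm = apply_transform(maps.pd, maps.grid, m, target_grid, order=1)
    mask = apply_transform(maps.mask.astype(float), maps.grid, m,
                           target_grid, order=0) > 0.5
    if maps.mask.any() and not mask.any():
        raise ValueError("transform maps the brain outside the target field of view")
    return ParameterMaps(r1, r2, pdm, target_grid, mask, dict(maps.qc))
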