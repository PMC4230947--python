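"""Voxel-wise inference on normalised cohorts.

Group differences are estimated by a per-voxel linear model
``y = b0 + b1*group + b2*age`` (a two-sample t-test controlling for age);
disability correlation by ``y = b0 + b1*EDSS + b2*age`` within the patient
group.  Family-wise error over regions of interest is controlled by a
max-T permutation test (group labels permuted, ages kept with their
subjects) with a Bonferroni factor over the number of ROIs.

Sign convention for group contrasts: positive T means the reference group
exceeds the patients, matching the direction in which demyelinating damage
moves R1 and R2.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import Grid

__all__ = [
    "StatMap",
    "DesignInfo",
    "glm_group_contrast",
    "edss_slope_map",
    "threshold_map",
    "permutation_fwe_svc",
    "map_regression",
]


@dataclass
class StatMap:
    """Voxel-wise statistic with its provenance."""

    data: np.ndarray
    kind: str  # "t" or "slope"
    df: int
    contrast: str
    grid: Grid
    mask: np.ndarray
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.data.shape != tuple(self.grid.shape) or \
                self.mask.shape != tuple(self.grid.shape):
            raise ValueError("statistic and mask must live on the grid")


@dataclass
class DesignInfo:
    """Subject-level design: ids, group labels, ages and (optionally) EDSS."""

    ids: list[str]
    group: np.ndarray  # 1 = patient, 0 = reference
    age: np.ndarray
    edss: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=float)
        self.age = np.asarray(self.age, dtype=float)
        n = len(self.ids)
        if self.group.shape != (n,) or self.age.shape != (n,):
            raise ValueError("design columns must have one row per subject")
        if self.edss is not None:
            self.edss = np.asarray(self.edss, dtype=float)
            if self.edss.shape != (n,):
                raise ValueError("EDSS must have one row per subject")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DesignInfo":
        missing = {"id", "group", "age"} - set(frame.columns)
        if missing:
            raise ValueError(f"subject table missing columns: {sorted(missing)}")
        edss = frame["edss"].to_numpy(float) if "edss" in frame else None
        return cls(list(frame["id"]), (frame["group"] == "patient").to_numpy(float),
                   frame["age"].to_numpy(float), edss)

    @property
    def n(self) -> int:
        return len(self.ids)


def _stack_cohort(maps_list, mask):
    y = np.stack([np.asarray(m)[mask] for m in maps_list])  # (n, V)
    return y


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # name the offending columns: those whose removal restores full rank
        base_rank = np.linalg.matrix_rank(x)
        bad = [names[j] for j in range(x.shape[1])
               if np.linalg.matrix_rank(np.delete(x, j, axis=1)) == base_rank]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def _glm_t(y: np.ndarray, x: np.ndarray, contrast: np.ndarray):
    """Vectorised OLS t-statistics for a single contrast over many voxels.

    y: (n, V), x: (n, p).  Returns (t, beta_c) with df = n - p.
    """
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y  # (p, V)
    resid = y - x @ beta
    df = n - p
    sigma2 = (resid ** 2).sum(axis=0) / df
    c = np.asarray(contrast, dtype=float)
    var_c = float(c @ xtx_inv @ c)
    beta_c = c @ beta
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta_c / np.sqrt(sigma2 * var_c)
    t[~np.isfinite(t)] = 0.0
    # a residual variance at rounding-error level means the model fits
    # exactly; the t ratio is then 0/0 noise, not evidence
    degenerate = sigma2 <= 1e-28 * np.maximum((y ** 2).mean(axis=0), 1e-300)
    t[degenerate] = 0.0
    return t, beta_c


def _design_matrix(design: DesignInfo, column: str) -> tuple[np.ndarray, list[str]]:
    age_c = design.age - design.age.mean()  # centring stabilises the intercept
    if column == "group":
        x = np.column_stack([np.ones(design.n), design.group, age_c])
        names = ["intercept", "group", "age"]
    else:
        if design.edss is None:
            raise ValueError("design has no EDSS column")
        if np.ptp(design.edss) == 0:
            raise ValueError("EDSS is constant across subjects")
        x = np.column_stack([np.ones(design.n), design.edss, age_c])
        names = ["intercept", "edss", "age"]
    _check_rank(x, names)
    return x, names


def glm_group_contrast(maps_list, design: DesignInfo, grid: Grid,
                       mask: np.ndarray,
                       contrast_name: str = "reference>patient") -> StatMap:
    """Two-sample t-test controlling for age, per voxel.

    ``maps_list`` holds one volume per subject in design order.  Positive T
    means reference above patient.
    """
    if len(maps_list) != design.n:
        raise ValueError("one map per design row required")
    if design.group.sum() < 2 or (design.n - design.group.sum()) < 2:
        raise ValueError("need at least two subjects per group")
    x, _ = _design_matrix(design, "group")
    y = _stack_cohort(maps_list, mask)
    t, _ = _glm_t(y, x, [0.0, -1.0, 0.0])  # minus: group codes patient = 1
    out = np.zeros(grid.shape)
    out[mask] = t
    return StatMap(out, "t", design.n - 3, contrast_name, grid, mask)


def edss_slope_map(maps_list, design: DesignInfo, grid: Grid,
                   mask: np.ndarray, return_t: bool = False):
    """Voxel-wise regression slope on EDSS with age as nuisance.

    Returns the slope map (units of the parameter per EDSS point); with
    ``return_t`` also the accompanying T map.
    """
    if len(maps_list) != design.n:
        raise ValueError("one map per design row required")
    x, _ = _design_matrix(design, "edss")
    y = _stack_cohort(maps_list, mask)
    t, beta = _glm_t(y, x, [0.0, 1.0, 0.0])
    slope = np.zeros(grid.shape)
    slope[mask] = beta
    slope_map = StatMap(slope, "slope", design.n - 3, "edss", grid, mask)
    if not return_t:
        return slope_map
    tvol = np.zeros(grid.shape)
    tvol[mask] = t
    return slope_map, StatMap(tvol, "t", design.n - 3, "edss", grid, mask)


def threshold_map(stat_map: StatMap, t_min: float,
                  two_sided: bool = False) -> np.ndarray:
    """Binary overlay of voxels exceeding the statistic threshold.

    One-sided by default (strictly greater than ``t_min``), matching
    display conventions for directional contrasts.
    """
    if stat_map.kind != "t":
        raise ValueError("thresholding expects a T map")
    vals = np.abs(stat_map.data) if two_sided else stat_map.data
    overlay = (vals > t_min) & stat_map.mask
    stat_map.threshold = t_min
    return overlay


def _roi_max_t(y, x, contrast, roi_flat_indices):
    t, _ = _glm_t(y, x, contrast)
    return np.array([t[idx].max() if idx.size else -np.inf
                     for idx in roi_flat_indices])


def permutation_fwe_svc(maps_list, design: DesignInfo, grid: Grid,
                        mask: np.ndarray, rois: dict[str, np.ndarray],
                        n_perm: int = 1000, seed: int = 0,
                        direction: str = "reference>patient") -> pd.DataFrame:
    """Small-volume FWE-corrected group inference per ROI (max-T permutation).

    Group labels are permuted across subjects (each subject keeps its age);
    the observed per-ROI maximum T is ranked against the permutation
    distribution of the same quantity and Bonferroni-corrected for the
    number of ROIs.  When fewer distinct label reassignments exist than
    ``n_perm`` the full enumeration is used instead (exact test).
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    for name, roi in rois.items():
        if np.any(roi & ~mask):
            raise ValueError(f"ROI {name!r} extends outside the analysis mask")
    x, _ = _design_matrix(design, "group")
    sign = -1.0 if direction == "reference>patient" else 1.0
    contrast = np.array([0.0, sign, 0.0])
    y = _stack_cohort(maps_list, mask)

    flat_idx = {}
    mask_flat_positions = np.cumsum(mask.reshape(-1)) - 1
    for name, roi in rois.items():
        flat_idx[name] = mask_flat_positions[roi.reshape(-1)]
    roi_names = list(rois)
    idx_list = [flat_idx[n] for n in roi_names]

    obs = _roi_max_t(y, x, contrast, idx_list)

    n = design.n
    n_pat = int(design.group.sum())
    n_distinct = comb(n, n_pat)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(roi_names))
    if n_distinct <= n_perm:
        total = 0
        for pat_idx in combinations(range(n), n_pat):
            g = np.zeros(n)
            g[list(pat_idx)] = 1.0
            xp = x.copy()
            xp[:, 1] = g
            exceed += _roi_max_t(y, xp, contrast, idx_list) >= obs
            total += 1
        p = exceed / total
    else:
        for _ in range(n_perm):
            xp = x.copy()
            xp[:, 1] = rng.permutation(design.group)
            exceed += _roi_max_t(y, xp, contrast, idx_list) >= obs
        p = (1.0 + exceed) / (1.0 + n_perm)
    p_corr = np.minimum(p * len(roi_names), 1.0)
    return pd.DataFrame({
        "roi": roi_names,
        "max_t": obs,
        "p_uncorrected": p,
        "p_fwe": p_corr,
        "n_perm": min(n_perm, n_distinct),
        "seed": seed,
    })


def map_regression(t_map: StatMap, slope_map: StatMap,
                   mask: np.ndarray | None = None) -> tuple[float, float]:
    """Ordinary least squares of slope-map values on T-map values.

    All in-mask voxels enter, significant or not; returns the fitted slope
    and the goodness of fit R^2.
    """
    t_map.grid.require_match(slope_map.grid, "statistic maps")
    if mask is None:
        mask = t_map.mask & slope_map.mask
    if not mask.any():
        raise ValueError("empty mask for map regression")
    xv = t_map.data[mask].astype(float)
    yv = slope_map.data[mask].astype(float)
    res = stats.linregress(xv, yv)
    return float(res.slope), float(res.rvalue ** 2)
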