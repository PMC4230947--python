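"""Tissue classification and brain-volume measures from (R1, R2, PD) maps.

Voxels are classified into white matter, grey matter and CSF by their
position in the three-dimensional parameter space: each class owns an
acceptance box around a central (R1, R2, PD) point.  A voxel inside exactly
one box belongs fully to that class; intermediate voxels receive partial-
volume fractions by inverse-squared-distance weighting over the class
centres (distances normalised by the acceptance radii); voxels far from all
classes are non-brain.

Volume measures follow the standard definitions: brain volume is the
largest contiguous region of white+grey matter, intracranial volume the
largest contiguous region of brain tissue plus CSF, the brain parenchymal
fraction (BPF) and ventricular fraction (VF) are percent ratios against the
intracranial volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import Grid
from .relaxometry import ParameterMaps

__all__ = [
    "TissueClassRanges",
    "SegmentationResult",
    "VolumeReport",
    "classify_tissue",
    "compute_volumes",
]

CLASS_ORDER = ("wm", "gm", "csf")


def _default_centers() -> dict[str, tuple[float, float, float]]:
    # Healthy-group white matter / cortical grey matter values; CSF from the
    # partial-volume-cropped ventricle values with PD at the pure-water
    # ceiling, matching the phantom tissue model.
    return {"wm": (1.20, 11.1, 74.0),
            "gm": (1.02, 10.0, 75.0),
            "csf": (0.29, 3.4, 100.0)}


def _default_radii() -> dict[str, tuple[float, float, float]]:
    return {"wm": (0.09, 0.55, 3.0),
            "gm": (0.09, 0.55, 3.0),
            "csf": (0.20, 2.0, 6.0)}


@dataclass(frozen=True)
class TissueClassRanges:
    """Class centres and per-parameter acceptance radii in map units."""

    centers: dict[str, tuple[float, float, float]] = field(default_factory=_default_centers)
    radii: dict[str, tuple[float, float, float]] = field(default_factory=_default_radii)
    max_distance: float = 6.0  # normalised distance beyond which a voxel is non-brain

    def __post_init__(self) -> None:
        for name in CLASS_ORDER:
            if name not in self.centers or name not in self.radii:
                raise ValueError(f"missing class {name!r}")
            if any(r <= 0 for r in self.radii[name]):
                raise ValueError("acceptance radii must be positive")
        pts = [np.asarray(self.centers[c]) for c in CLASS_ORDER]
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if np.allclose(pts[i], pts[j]):
                    raise ValueError("class centers must be pairwise distinct")
        # a class whose box lies entirely inside another's box is unreachable
        for i, a in enumerate(CLASS_ORDER):
            for b in CLASS_ORDER[i + 1:]:
                ca, ra = np.asarray(self.centers[a]), np.asarray(self.radii[a])
                cb, rb = np.asarray(self.centers[b]), np.asarray(self.radii[b])
                if np.all(np.abs(ca - cb) + ra <= rb):
                    raise ValueError(f"class {a!r} box is unreachable inside {b!r}")
                if np.all(np.abs(ca - cb) + rb <= ra):
                    raise ValueError(f"class {b!r} box is unreachable inside {a!r}")


@dataclass
class SegmentationResult:
    """Per-voxel partial-volume fractions (wm, gm, csf, non-brain); sum 1."""

    fractions: np.ndarray  # (4, *shape)
    grid: Grid

    FRACTION_ORDER = ("wm", "gm", "csf", "nonbrain")

    def __post_init__(self) -> None:
        f = self.fractions
        if f.shape != (4,) + tuple(self.grid.shape):
            raise ValueError("fractions must be (4, *grid shape)")
        if np.any(f < -1e-9) or np.any(np.abs(f.sum(axis=0) - 1) > 1e-6):
            raise ValueError("fractions must be non-negative and sum to 1")

    def fraction(self, name: str) -> np.ndarray:
        return self.fractions[self.FRACTION_ORDER.index(name)]


@dataclass(frozen=True)
class VolumeReport:
    """Compartment volumes (mL) and derived fractions (%)."""

    intracranial_volume: float
    brain_volume: float
    ventricular_volume: float

    @property
    def brain_parenchymal_fraction(self) -> float:
        return 100.0 * self.brain_volume / self.intracranial_volume \
            if self.intracranial_volume > 0 else 0.0

    @property
    def ventricular_fraction(self) -> float:
        return 100.0 * self.ventricular_volume / self.intracranial_volume \
            if self.intracranial_volume > 0 else 0.0


def classify_tissue(maps: ParameterMaps,
                    ranges: TissueClassRanges | None = None) -> SegmentationResult:
    """Partial-volume tissue classification in parameter space."""
    ranges = ranges or TissueClassRanges()
    shape = maps.grid.shape
    vals = np.stack([maps.r1, maps.r2, maps.pd], axis=-1).reshape(-1, 3)

    n = vals.shape[0]
    k = len(CLASS_ORDER)
    dist = np.empty((n, k))
    inside = np.empty((n, k), dtype=bool)
    for ci, name in enumerate(CLASS_ORDER):
        c = np.asarray(ranges.centers[name])
        r = np.asarray(ranges.radii[name])
        z = (vals - c) / r
        dist[:, ci] = np.sqrt((z ** 2).sum(axis=1))
        inside[:, ci] = np.all(np.abs(z) <= 1.0, axis=1)

    frac = np.zeros((n, k))
    n_inside = inside.sum(axis=1)

    # pure voxels: inside exactly one acceptance box
    pure = n_inside == 1
    frac[pure, :] = 0.0
    frac[pure, np.argmax(inside[pure], axis=1)] = 1.0

    # intermediate voxels: inverse-squared-distance mix over the classes
    mixed = (~pure) & (dist.min(axis=1) <= ranges.max_distance)
    if mixed.any():
        w = 1.0 / np.maximum(dist[mixed], 1e-12) ** 2
        frac[mixed] = w / w.sum(axis=1, keepdims=True)

    # outside the brain mask nothing is tissue
    brain = np.asarray(maps.mask, dtype=bool).reshape(-1)
    frac[~brain] = 0.0
    nonbrain = 1.0 - frac.sum(axis=1)
    out = np.concatenate([frac, nonbrain[:, None]], axis=1)
    out = np.moveaxis(out.reshape(shape + (4,)), -1, 0)
    return SegmentationResult(out, maps.grid)


def compute_volumes(seg: SegmentationResult,
                    ventricle_mask: np.ndarray,
                    component_threshold: float = 0.1) -> VolumeReport:
    """Brain, intracranial and ventricular volumes from a segmentation.

    Contiguity uses 6-connectivity on voxels whose compartment fraction
    exceeds ``component_threshold``; fractional volumes are summed inside
    the largest connected component.  Ventricular volume is the CSF
    fraction summed inside ``ventricle_mask``.
    """
    if ventricle_mask.shape != tuple(seg.grid.shape):
        raise ValueError("ventricle mask and segmentation share geometry")
    voxvol = seg.grid.voxel_volume_ml
    wm, gm, csf = (seg.fraction(n) for n in ("wm", "gm", "csf"))
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity

    def largest_component_sum(frac_sum: np.ndarray) -> float:
        fg = frac_sum > component_threshold
        if not fg.any():
            return 0.0
        labels, n = ndimage.label(fg, structure=structure)
        if n == 0:
            return 0.0
        sums = ndimage.sum_labels(frac_sum, labels, index=np.arange(1, n + 1))
        return float(sums.max())

    brain_sum = largest_component_sum(wm + gm)
    icv_sum = largest_component_sum(wm + gm + csf)
    if icv_sum == 0.0:
        warnings.warn("empty segmentation: zero volume report", stacklevel=2)
        return VolumeReport(0.0, 0.0, 0.0)
    vent_sum = float(csf[ventricle_mask.astype(bool)].sum())
    return VolumeReport(icv_sum * voxvol, brain_sum * voxvol, vent_sum * voxvol)
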