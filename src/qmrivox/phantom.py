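"""Digital brain phantom cohorts for quantitative-MRI group analysis.

The phantom is a deliberately simple head: an ellipsoidal intracranial
space holding a thin sulcal-CSF shell, a cortical grey-matter band, deep
grey nuclei, white matter and two lateral ventricles.  Tissue fractions are
computed on a supersampled lattice so interfaces carry realistic partial
volume.  A "patient" cohort differs from the reference cohort by

* ventricular enlargement (atrophy),
* a diffuse shift of the white-matter parameter means (normal-appearing
  white matter damage), stronger in frontal white matter for subjects with
  higher disability scores,
* focal spherical lesions, preferentially periventricular, whose
  parameters move toward cerebrospinal-fluid values, and
* the same acquisition noise and small affine misalignments as the
  reference group.

Every subject is emitted together with its ground truth (tissue fractions,
lesion mask, applied misalignment), so each downstream stage of the
pipeline can be validated against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import Grid
from .relaxometry import ParameterMaps

__all__ = [
    "ClassParams",
    "LesionModel",
    "MisalignmentModel",
    "PhantomSpec",
    "TemplateLabel",
    "SubjectRecord",
    "Subject",
    "Cohort",
    "build_template",
    "sample_subject_maps",
    "generate_cohort",
]

CLASSES = ("wm", "gm", "csf")
PARAMS = ("r1", "r2", "pd")


@dataclass(frozen=True)
class ClassParams:
    """Gaussian parameter model of one tissue class.

    ``mean`` is (R1 s^-1, R2 s^-1, PD %); ``between_sd`` the
    between-subject SD of the class mean and ``within_sd`` the voxel-wise
    texture SD within one subject, per parameter.
    """

    mean: tuple[float, float, float]
    between_sd: tuple[float, float, float]
    within_sd: tuple[float, float, float]

    def __post_init__(self) -> None:
        r1, r2, pdv = self.mean
        if r1 <= 0 or r2 <= 0:
            raise ValueError("class mean R1 and R2 must be positive")
        if not 0 < pdv <= 110:
            raise ValueError("class mean PD must lie in (0, 110]")
        if any(s < 0 for s in self.between_sd + self.within_sd):
            raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True)
class LesionModel:
    """Focal-lesion generator: Poisson count, uniform radii (mm),
    periventricular placement preference, severity in [0, 1] interpolating
    lesion parameters toward CSF values."""

    count_mean: float = 8.0
    radius_range: tuple[float, float] = (2.0, 5.0)
    periventricular_prob: float = 0.8
    severity: float = 0.7

    def __post_init__(self) -> None:
        lo, hi = self.radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("lesion radii must be positive and ordered")
        if not 0 <= self.severity <= 1:
            raise ValueError("lesion severity must lie in [0, 1]")
        if not 0 <= self.periventricular_prob <= 1:
            raise ValueError("periventricular probability must lie in [0, 1]")


@dataclass(frozen=True)
class MisalignmentModel:
    """Per-subject rigid+scale jitter bounds (uniform in +/- max)."""

    max_translation_mm: float = 4.0
    max_rotation_deg: float = 3.0
    max_scale: float = 0.03


def _default_tissue_params() -> dict[str, ClassParams]:
    # Class means: whole-ROI white matter / cortical grey matter of the
    # healthy reference group; CSF R1/R2 from the cropped ventricle ROI with
    # PD at the pure-water ceiling.  SDs are chosen so that the between-
    # subject spread dominates group inference while voxel texture remains
    # visible.
    return {
        "wm": ClassParams((1.20, 11.1, 74.0), (0.05, 0.45, 2.0), (0.10, 1.0, 4.0)),
        "gm": ClassParams((1.02, 10.0, 75.0), (0.05, 0.40, 2.0), (0.10, 1.0, 4.0)),
        "csf": ClassParams((0.29, 3.4, 100.0), (0.03, 0.30, 1.5), (0.06, 0.6, 2.0)),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a simulated cohort's generating conditions."""

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_size: float = 2.0
    tissue_params: dict[str, ClassParams] = field(default_factory=_default_tissue_params)
    lesion_model: LesionModel = field(default_factory=LesionModel)
    diffuse_delta: tuple[float, float, float] = (-0.13, -0.9, 3.0)
    atrophy_factor: float = 2.5
    noise_sigma: float = 0.02
    misalignment: MisalignmentModel = field(default_factory=MisalignmentModel)
    edss_coupling: float = 1.0
    edss_reference: float = 3.7
    age_mean: float = 47.7
    age_sd: float = 11.9
    age_match_sd: float = 2.6
    edss_range: tuple[float, float] = (1.0, 8.5)
    clip_floor: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 16 for s in self.grid_shape):
            raise ValueError("grid must be at least 16 voxels per axis")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        if self.atrophy_factor < 1:
            raise ValueError("atrophy factor must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        for name in CLASSES:
            if name not in self.tissue_params:
                raise ValueError(f"missing tissue class {name!r}")

    @property
    def grid(self) -> Grid:
        return Grid.isotropic(self.grid_shape, self.voxel_size)


@dataclass
class TemplateLabel:
    """Ground-truth anatomy: per-voxel tissue fractions plus named ROIs."""

    fractions: np.ndarray  # (4, *shape): wm, gm, csf, background
    rois: dict[str, np.ndarray]
    grid: Grid

    FRACTION_ORDER = ("wm", "gm", "csf", "background")

    def __post_init__(self) -> None:
        f = self.fractions
        if f.shape != (4,) + tuple(self.grid.shape):
            raise ValueError("fractions must be (4, *grid shape)")
        if np.any(f < -1e-6) or np.any(np.abs(f.sum(axis=0) - 1) > 1e-6):
            raise ValueError("fractions must be in [0,1] and sum to 1 per voxel")
        brain = self.brain_mask
        for name, mask in self.rois.items():
            if mask.shape != tuple(self.grid.shape):
                raise ValueError(f"ROI {name!r} shape mismatch")
            if np.any(mask & ~brain):
                raise ValueError(f"ROI {name!r} leaves the in-brain region")

    @property
    def brain_mask(self) -> np.ndarray:
        """Voxels with any intracranial content (brain tissue or CSF)."""
        return self.fractions[3] < 0.5

    def fraction(self, name: str) -> np.ndarray:
        return self.fractions[self.FRACTION_ORDER.index(name)]


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's metadata row."""

    id: str
    group: str  # "reference" | "patient"
    age: float
    edss: float | None = None
    msss: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("reference", "patient"):
            raise ValueError("group must be 'reference' or 'patient'")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.edss is not None and not 0 <= self.edss <= 10:
            raise ValueError("EDSS must lie in [0, 10]")


@dataclass
class Subject:
    """A simulated subject with its ground truth."""

    record: SubjectRecord
    maps: ParameterMaps            # template-space truth (before misalignment)
    native_maps: ParameterMaps     # misaligned acquisition-space maps
    fractions: np.ndarray          # subject anatomy (atrophy applied), template space
    lesion_mask: np.ndarray
    ventricle_mask: np.ndarray     # subject anatomy, template space
    native_ventricle_mask: np.ndarray
    jitter_matrix: np.ndarray      # pull-back applied to create native maps
    true_registration: np.ndarray  # matrix that re-aligns native to template
    qc: dict = field(default_factory=dict)


@dataclass
class Cohort:
    spec: PhantomSpec
    template: TemplateLabel
    subjects: list[Subject]

    def records_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            r = s.record
            rows.append({"id": r.id, "group": r.group, "age": r.age,
                         "edss": r.edss, "msss": r.msss})
        frame = pd.DataFrame(rows)
        if frame["edss"].isna().all():
            frame = frame.drop(columns=["edss", "msss"])
        return frame

    def group(self, name: str) -> list[Subject]:
        return [s for s in self.subjects if s.record.group == name]


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

def _ellipsoid(coords, center, semi):
    """Boolean membership of world coordinates in an axis-aligned ellipsoid."""
    d = ((coords[0] - center[0]) / semi[0]) ** 2 \
        + ((coords[1] - center[1]) / semi[1]) ** 2 \
        + ((coords[2] - center[2]) / semi[2]) ** 2
    return d <= 1.0


def _geometry_mm(spec: PhantomSpec) -> dict:
    """Structure centres and semi-axes in mm, scaled to the grid extent."""
    extent = np.asarray(spec.grid_shape) * spec.voxel_size  # mm per axis
    s = extent / np.array([128.0, 128.0, 96.0])  # reference design box
    rad = spec.atrophy_factor ** (1.0 / 3.0)
    return {
        "icv_semi": np.array([56.0, 60.0, 42.0]) * s,
        "csf_shell_mm": 2.0,
        "gm_band_mm": 6.0,
        "vent_centers": [np.array([-11.0, 4.0, 0.0]) * s,
                         np.array([11.0, 4.0, 0.0]) * s],
        "vent_semi": np.array([6.0, 16.0, 8.0]) * s * rad,
        "nucleus_centers": [np.array([-20.0, -8.0, 2.0]) * s,
                            np.array([20.0, -8.0, 2.0]) * s],
        "nucleus_semi": np.array([10.0, 12.0, 10.0]) * s,
        "cc_center": np.array([0.0, 4.0, 11.0]) * s,
        "cc_semi": np.array([16.0, 20.0, 5.0]) * s,
        "frontal_y_mm": 18.0 * s[1],
        "periventricular_mm": 8.0,
    }


def _class_id_volume(spec: PhantomSpec, supersample: int,
                     atrophy_factor: float | None = None) -> np.ndarray:
    """Integer class labels (0 wm, 1 gm, 2 csf, 3 background) on a lattice
    ``supersample`` times finer than the target grid."""
    if atrophy_factor is not None:
        spec = replace(spec, atrophy_factor=atrophy_factor)
    geo = _geometry_mm(spec)
    fine = Grid.isotropic(tuple(s * supersample for s in spec.grid_shape),
                          spec.voxel_size / supersample)
    xyz = fine.world_coords()
    icv = _ellipsoid(xyz, np.zeros(3), geo["icv_semi"])
    paren = _ellipsoid(xyz, np.zeros(3), geo["icv_semi"] - geo["csf_shell_mm"])
    inner = _ellipsoid(xyz, np.zeros(3),
                       geo["icv_semi"] - geo["csf_shell_mm"] - geo["gm_band_mm"])
    vent = np.zeros_like(icv)
    for c in geo["vent_centers"]:
        vent |= _ellipsoid(xyz, c, geo["vent_semi"])
    nucleus = np.zeros_like(icv)
    for c in geo["nucleus_centers"]:
        nucleus |= _ellipsoid(xyz, c, geo["nucleus_semi"])

    labels = np.full(fine.shape, 3, dtype=np.int8)  # background
    labels[icv] = 2                                 # sulcal CSF shell
    labels[paren & ~inner] = 1                      # cortical band
    labels[inner] = 0                               # white matter
    labels[inner & nucleus] = 1                     # deep grey nuclei
    labels[vent & icv] = 2                          # ventricles
    return labels


def _downsample_fractions(labels: np.ndarray, supersample: int) -> np.ndarray:
    """Average one-hot class memberships over supersampled blocks."""
    shape = tuple(s // supersample for s in labels.shape)
    frac = np.empty((4,) + shape)
    view = labels.reshape(shape[0], supersample, shape[1], supersample,
                          shape[2], supersample)
    for c in range(4):
        frac[c] = (view == c).mean(axis=(1, 3, 5))
    return frac


def build_template(spec: PhantomSpec,
                   atrophy_factor: float | None = None,
                   supersample: int = 2) -> TemplateLabel:
    """Construct the ground-truth anatomy on the spec's grid.

    Deterministic for a given spec (the anatomy is analytic); ``atrophy_factor``
    overrides the spec value so per-subject ventricular enlargement reuses the
    same construction.
    """
    if any(s < 16 for s in spec.grid_shape):
        raise ValueError("grid must be at least 16 voxels per axis")
    labels = _class_id_volume(spec, supersample, atrophy_factor)
    frac = _downsample_fractions(labels, supersample)
    grid = spec.grid
    geo = _geometry_mm(spec if atrophy_factor is None
                       else replace(spec, atrophy_factor=atrophy_factor))
    xyz = grid.world_coords()

    wm = frac[0] > 0.5
    gm = frac[1] > 0.5
    vent = np.zeros(grid.shape, dtype=bool)
    for c in geo["vent_centers"]:
        vent |= _ellipsoid(xyz, c, geo["vent_semi"])
    vent &= frac[2] > 0.5

    from scipy import ndimage

    n_dilate = max(1, int(round(geo["periventricular_mm"] / spec.voxel_size)))
    shell = ndimage.binary_dilation(vent, iterations=n_dilate) & wm
    nucleus = np.zeros(grid.shape, dtype=bool)
    for c in geo["nucleus_centers"]:
        nucleus |= _ellipsoid(xyz, c, geo["nucleus_semi"])
    rois = {
        "ventricles": vent,
        "periventricular_wm": shell,
        "corpus_callosum": _ellipsoid(xyz, geo["cc_center"], geo["cc_semi"]) & wm,
        "deep_gm": nucleus & gm,
        "cortical_gm": gm & ~nucleus,
        "white_matter": wm,
        "frontal_wm": wm & (xyz[1] > geo["frontal_y_mm"]),
    }
    for name in ("ventricles", "periventricular_wm", "white_matter"):
        if not rois[name].any():
            raise ValueError(f"degenerate template: empty {name} region")
    return TemplateLabel(frac, rois, grid)


# ---------------------------------------------------------------------------
# subject sampling
# ---------------------------------------------------------------------------

def _edss_factor(record: SubjectRecord, spec: PhantomSpec) -> float:
    """Multiplier linking frontal-WM diffuse damage to disability."""
    if record.edss is None:
        return 1.0
    return 1.0 + spec.edss_coupling * (record.edss - spec.edss_reference) / spec.edss_reference


def sample_subject_maps(
    template: TemplateLabel,
    record: SubjectRecord,
    spec: PhantomSpec,
    seed: int | np.random.Generator = 0,
    return_truth: bool = False,
):
    """Draw one subject's (R1, R2, PD) maps from the tissue model.

    Per class, a subject-level mean is drawn from the between-subject
    Gaussian and voxel texture from the within-subject Gaussian; voxel
    values are the tissue-fraction-weighted mixture of the class draws.
    Patients additionally receive the diffuse white-matter shift (scaled in
    frontal WM by disability), focal lesions and whatever atrophy the
    supplied ``template`` encodes.  R1/R2 draws below ``spec.clip_floor``
    are clipped (counted in QC); PD is clipped to [0, 110].
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    shape = template.grid.shape
    is_patient = record.group == "patient"

    class_means = {}
    for name in CLASSES:
        cp = spec.tissue_params[name]
        class_means[name] = np.asarray(cp.mean) + \
            np.asarray(cp.between_sd) * rng.standard_normal(3)
    if is_patient:
        class_means["wm"] = class_means["wm"] + np.asarray(spec.diffuse_delta)

    maps = np.zeros((3,) + shape)
    for ci, name in enumerate(CLASSES):
        cp = spec.tissue_params[name]
        frac = template.fractions[ci]
        for p in range(3):
            field_p = class_means[name][p] + \
                cp.within_sd[p] * rng.standard_normal(shape)
            maps[p] += frac * field_p

    if is_patient:
        # disability-linked extra diffuse damage in frontal white matter
        factor = _edss_factor(record, spec)
        frontal = template.rois["frontal_wm"]
        wm_frac = template.fraction("wm")
        for p in range(3):
            maps[p][frontal] += (factor - 1.0) * spec.diffuse_delta[p] \
                * wm_frac[frontal]

    lesion_mask = np.zeros(shape, dtype=bool)
    if is_patient and spec.lesion_model.count_mean > 0:
        lesion_mask = _add_lesions(maps, template, spec, rng)

    brain_vox = template.brain_mask
    qc = {"n_clipped": int(((maps[0] < spec.clip_floor) & brain_vox).sum()
                           + ((maps[1] < spec.clip_floor) & brain_vox).sum())}
    np.clip(maps[0], spec.clip_floor, None, out=maps[0])
    np.clip(maps[1], spec.clip_floor, None, out=maps[1])
    np.clip(maps[2], 0.0, 110.0, out=maps[2])
    brain = template.brain_mask
    maps *= brain  # background carries no signal
    result = ParameterMaps(maps[0], maps[1], maps[2], template.grid,
                           brain.copy(), qc)
    if return_truth:
        return result, lesion_mask
    return result


def _add_lesions(maps, template, spec, rng):
    """Insert spherical lesions whose parameters move toward CSF values."""
    lm = spec.lesion_model
    wm_vox = np.argwhere(template.rois["white_matter"])
    peri_vox = np.argwhere(template.rois["periventricular_wm"])
    n = rng.poisson(lm.count_mean)
    mask = np.zeros(template.grid.shape, dtype=bool)
    if n == 0 or len(wm_vox) == 0:
        return mask
    xyz = template.grid.world_coords()
    wm_frac = template.fraction("wm")
    wm_mean = np.asarray(spec.tissue_params["wm"].mean)
    csf_mean = np.asarray(spec.tissue_params["csf"].mean)
    for _ in range(n):
        pool = peri_vox if (len(peri_vox) and rng.random() < lm.periventricular_prob) \
            else wm_vox
        center_vox = pool[rng.integers(len(pool))]
        center = template.grid.affine @ np.append(center_vox, 1.0)
        radius = rng.uniform(*lm.radius_range)
        d2 = ((xyz[0] - center[0]) ** 2 + (xyz[1] - center[1]) ** 2
              + (xyz[2] - center[2]) ** 2)
        sphere = d2 <= radius ** 2
        mask |= sphere
        shift = lm.severity * (csf_mean - wm_mean)
        for p in range(3):
            maps[p][sphere] += shift[p] * wm_frac[sphere]
    return mask


# ---------------------------------------------------------------------------
# misalignment
# ---------------------------------------------------------------------------

def _jitter_matrix(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Random small affine (world -> world, mm) within the misalignment bounds."""
    m = spec.misalignment
    t = rng.uniform(-m.max_translation_mm, m.max_translation_mm, 3)
    angles = np.deg2rad(rng.uniform(-m.max_rotation_deg, m.max_rotation_deg, 3))
    scales = 1.0 + rng.uniform(-m.max_scale, m.max_scale, 3)
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    a = np.eye(4)
    a[:3, :3] = rz @ ry @ rx @ np.diag(scales)
    a[:3, 3] = t
    return a


def _resample_pullback(data: np.ndarray, grid: Grid, matrix: np.ndarray,
                       order: int = 1) -> np.ndarray:
    """out(v) = data(voxel coords of matrix @ world(v)); trilinear by default."""
    from scipy import ndimage

    vox2vox = np.linalg.inv(grid.affine) @ matrix @ grid.affine
    return ndimage.affine_transform(
        data, vox2vox[:3, :3], vox2vox[:3, 3], order=order,
        mode="constant", cval=0.0, prefilter=(order > 1))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _sample_records(spec: PhantomSpec, n_ref: int, n_pat: int,
                    rng: np.random.Generator) -> list[SubjectRecord]:
    ref_ages = np.clip(rng.normal(spec.age_mean, spec.age_sd, n_ref), 18.0, 85.0)
    if n_pat == n_ref:
        pat_ages = rng.permutation(ref_ages) + rng.normal(0.0, spec.age_match_sd, n_pat)
    else:
        pat_ages = rng.normal(spec.age_mean, spec.age_sd, n_pat)
    pat_ages = np.clip(pat_ages, 18.0, 85.0)
    lo, hi = spec.edss_range
    edss = np.clip(rng.normal(spec.edss_reference, 2.0, n_pat), lo, hi)
    edss = np.round(edss * 2.0) / 2.0
    msss = np.clip(edss + rng.normal(0.5, 1.0, n_pat), 0.5, 9.6)
    records = [SubjectRecord(f"ref{i:03d}", "reference", float(ref_ages[i]))
               for i in range(n_ref)]
    records += [SubjectRecord(f"pat{i:03d}", "patient", float(pat_ages[i]),
                              float(edss[i]), float(np.round(msss[i], 1)))
                for i in range(n_pat)]
    return records


def generate_cohort(spec: PhantomSpec, n_ref: int, n_pat: int,
                    seed: int | None = None) -> Cohort:
    """Simulate a full two-group cohort with ground truth.

    All randomness flows from ``seed`` (default: ``spec.seed``).  Reference
    subjects use the unscaled template; each patient's anatomy is rebuilt
    with a subject-specific ventricular enlargement drawn around
    ``spec.atrophy_factor``.
    """
    if n_ref < 1 and n_pat < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    template = build_template(spec, atrophy_factor=1.0)
    records = _sample_records(spec, n_ref, n_pat, rng)

    subjects = []
    for rec in records:
        if rec.group == "patient":
            factor = max(1.0, spec.atrophy_factor * rng.uniform(0.8, 1.2))
            subj_template = build_template(spec, atrophy_factor=factor)
        else:
            subj_template = template
        maps, lesion_mask = sample_subject_maps(
            subj_template, rec, spec, rng, return_truth=True)
        jitter = _jitter_matrix(spec, rng)
        native = ParameterMaps(
            _resample_pullback(maps.r1, maps.grid, jitter),
            _resample_pullback(maps.r2, maps.grid, jitter),
            _resample_pullback(maps.pd, maps.grid, jitter),
            maps.grid,
            _resample_pullback(maps.mask.astype(float), maps.grid, jitter,
                               order=0) > 0.5,
        )
        vent = subj_template.rois["ventricles"]
        native_vent = _resample_pullback(
            vent.astype(float), maps.grid, jitter, order=0) > 0.5
        subjects.append(Subject(
            record=rec,
            maps=maps,
            native_maps=native,
            fractions=subj_template.fractions.astype(np.float32),
            lesion_mask=lesion_mask,
            ventricle_mask=vent,
            native_ventricle_mask=native_vent,
            jitter_matrix=jitter,
            true_registration=np.linalg.inv(jitter),
            qc=dict(maps.qc),
        ))
    return Cohort(spec, template, subjects)
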