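"""End-to-end orchestration of the voxel-based qMRI group analysis.

Stage order mirrors the acquisition-to-statistics workflow:

    simulate -> fit -> segment -> normalize -> stats / hist / roi

Each stage reads its inputs from, and writes its products to, a work
directory, so stages can be re-run individually from the command line; a
missing upstream product raises an error naming the stage to run first.
All randomness derives from the single configured seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import multiparametric, roitools, voxelstats
from .geometry import Grid, load_volume, save_volume
from .phantom import (CLASSES, PhantomSpec, TemplateLabel, build_template,
                      generate_cohort)
from .registration import AffineTransform, apply_and_regrid, apply_transform, \
    estimate_affine, smooth_gaussian
from .relaxometry import (AcquisitionProtocol, ParameterMaps,
                          fit_parameter_maps, simulate_stack,
                          synthesize_contrast_image)
from .segmentation import TissueClassRanges, classify_tissue, compute_volumes

__all__ = ["RunConfig", "run_pipeline", "read_cohort", "write_cohort",
            "template_parameter_maps"]

PARAMS = ("r1", "r2", "pd")
STAGES = ("simulate", "fit", "segment", "normalize", "stats", "hist", "roi")

# ROIs entering the small-volume corrected white-matter-family tests
WM_FAMILY = ("white_matter", "frontal_wm", "periventricular_wm", "corpus_callosum")
SUMMARY_ROIS = ("ventricles", "corpus_callosum", "deep_gm", "white_matter")
MARKER_ROIS = ("cortical_gm", "deep_gm", "white_matter", "corpus_callosum")


@dataclass
class RunConfig:
    """All pipeline parameters; round-trips through JSON/YAML unchanged."""

    workdir: str = "qmrivox_run"
    seed: int = 7
    n_ref: int = 19
    n_pat: int = 19
    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_size: float = 2.0
    # acquisition timing (ms) and noise
    saturation_delays: tuple[float, ...] = (100.0, 400.0, 1380.0, 2860.0)
    echo_times: tuple[float, ...] = (14.0, 28.0, 42.0, 56.0, 70.0)
    repetition_time: float = 2950.0
    noise_sigma: float = 0.02
    # registration / normalisation
    fwhm_mm: float = 8.0
    target_voxel_mm: float = 2.0
    synth_te_ms: float = 100.0
    synth_tr_ms: float = 4500.0
    registration_levels: tuple[int, ...] = (4, 2)
    # statistics
    t_threshold: float = 2.0
    n_perm: int = 300
    # histograms
    bins_whole: int = 200
    bins_roi: int = 50
    threshold_frac: float = 0.10
    # ROI erosion
    erosion_levels: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0)
    # stage toggles
    stages: tuple[str, ...] = STAGES
    fit_max_iter: int = 30

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("grid_shape", "saturation_delays", "echo_times", "stages",
                    "erosion_levels", "registration_levels"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_file(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    # -- derived objects ----------------------------------------------------
    def phantom_spec(self) -> PhantomSpec:
        return PhantomSpec(grid_shape=self.grid_shape,
                           voxel_size=self.voxel_size,
                           noise_sigma=self.noise_sigma,
                           seed=self.seed)

    def protocol(self) -> AcquisitionProtocol:
        return AcquisitionProtocol(self.saturation_delays, self.echo_times,
                                   self.repetition_time)

    def seeds(self) -> dict[str, int]:
        """Explicit per-stage seeds, all derived from the base seed."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        names = ("simulate", "noise", "permutation")
        return {n: int(c.generate_state(1)[0] % (2 ** 31))
                for n, c in zip(names, children)}


def template_parameter_maps(template: TemplateLabel,
                            spec: PhantomSpec) -> ParameterMaps:
    """Noise-free class-mean maps of the template anatomy (registration target)."""
    maps = np.zeros((3,) + tuple(template.grid.shape))
    for ci, name in enumerate(CLASSES):
        mean = np.asarray(spec.tissue_params[name].mean)
        for p in range(3):
            maps[p] += template.fractions[ci] * mean[p]
    return ParameterMaps(maps[0], maps[1], maps[2], template.grid,
                         template.brain_mask.copy())


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort, directory) -> Path:
    """Persist native maps, the subject table and the ground-truth sidecar."""
    directory = Path(directory)
    truth = directory / "truth"
    truth.mkdir(parents=True, exist_ok=True)
    frame = cohort.records_frame()
    frame.to_csv(directory / "subjects.tsv", sep="\t", index=False)
    affines = {}
    for s in cohort.subjects:
        sid = s.record.id
        grid = s.native_maps.grid
        for p in PARAMS:
            save_volume(getattr(s.native_maps, p), grid,
                        directory / f"{sid}_{p.upper()}.nii.gz")
        save_volume(s.native_maps.mask.astype(np.uint8), grid,
                    directory / f"{sid}_mask.nii.gz")
        save_volume(s.fractions, grid, truth / f"{sid}_fractions.nii.gz")
        save_volume(s.lesion_mask.astype(np.uint8), grid,
                    truth / f"{sid}_lesions.nii.gz")
        save_volume(s.ventricle_mask.astype(np.uint8), grid,
                    truth / f"{sid}_ventricles.nii.gz")
        save_volume(s.native_ventricle_mask.astype(np.uint8), grid,
                    truth / f"{sid}_ventricles_native.nii.gz")
        affines[sid] = {"jitter": s.jitter_matrix.tolist(),
                        "true_registration": s.true_registration.tolist()}
    (truth / "affines.json").write_text(json.dumps(affines, indent=1))
    return directory


def read_cohort(directory) -> tuple[pd.DataFrame, dict[str, ParameterMaps]]:
    """Load a cohort directory: the subject table and per-subject maps.

    Rejects malformed tables (missing columns) and geometry mismatches,
    naming the offending file.
    """
    directory = Path(directory)
    table = directory / "subjects.tsv"
    if not table.exists():
        raise FileNotFoundError(f"no subject table at {table}")
    frame = pd.read_csv(table, sep="\t")
    missing = {"id", "group", "age"} - set(frame.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    maps = {}
    ref_grid = None
    for sid in frame["id"]:
        vols = {}
        for p in PARAMS:
            path = directory / f"{sid}_{p.upper()}.nii.gz"
            if not path.exists():
                raise FileNotFoundError(f"missing map {path}")
            data, grid = load_volume(path)
            if ref_grid is None:
                ref_grid = grid
            elif not grid.matches(ref_grid):
                raise ValueError(f"geometry mismatch in {path}")
            vols[p] = data
        mask_path = directory / f"{sid}_mask.nii.gz"
        mask = load_volume(mask_path)[0] > 0.5 if mask_path.exists() else None
        maps[sid] = ParameterMaps(vols["r1"], vols["r2"], vols["pd"],
                                  ref_grid, mask)
    return frame, maps


def _read_stage_maps(directory, frame, what: str) -> dict[str, ParameterMaps]:
    directory = Path(directory)
    if not directory.exists():
        raise FileNotFoundError(
            f"missing {what} outputs at {directory}; run the '{what}' stage first")
    maps = {}
    grid = None
    for sid in frame["id"]:
        vols = {}
        for p in PARAMS:
            path = directory / f"{sid}_{p.upper()}.nii.gz"
            if not path.exists():
                raise FileNotFoundError(
                    f"missing {path}; run the '{what}' stage first")
            data, g = load_volume(path)
            grid = grid or g
            vols[p] = data
        mask_path = directory / f"{sid}_mask.nii.gz"
        mask = load_volume(mask_path)[0] > 0.5 if mask_path.exists() else None
        maps[sid] = ParameterMaps(vols["r1"], vols["r2"], vols["pd"], grid, mask)
    return maps


def _write_maps(maps: dict[str, ParameterMaps], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sid, m in maps.items():
        for p in PARAMS:
            save_volume(getattr(m, p), m.grid, directory / f"{sid}_{p.upper()}.nii.gz")
        save_volume(m.mask.astype(np.uint8), m.grid, directory / f"{sid}_mask.nii.gz")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, workdir: Path) -> dict:
    spec = config.phantom_spec()
    cohort = generate_cohort(spec, config.n_ref, config.n_pat,
                             seed=config.seeds()["simulate"])
    write_cohort(cohort, workdir / "cohort")
    clipped = sum(s.qc.get("n_clipped", 0) for s in cohort.subjects)
    return {"n_subjects": len(cohort.subjects), "n_clipped_draws": clipped}


def stage_fit(config: RunConfig, workdir: Path) -> dict:
    frame, native = _cohort_inputs(config, workdir)
    truth = workdir / "cohort" / "truth"
    protocol = config.protocol()
    rng = np.random.default_rng(config.seeds()["noise"])
    fitted = {}
    qc = {"n_nonconverged": 0, "n_fitted": 0}
    from scipy import ndimage

    for sid, maps in native.items():
        stack = simulate_stack(maps, protocol, config.noise_sigma, rng)
        vent = load_volume(truth / f"{sid}_ventricles_native.nii.gz")[0] > 0.5
        core = ndimage.binary_erosion(vent)  # pure-CSF calibration core
        reference = core if core.any() else vent
        result = fit_parameter_maps(stack, csf_reference=reference,
                                    max_iter=config.fit_max_iter)
        fitted[sid] = result
        qc["n_nonconverged"] += result.qc["n_nonconverged"]
        qc["n_fitted"] += result.qc["n_fitted"]
    _write_maps(fitted, workdir / "fitted")
    (workdir / "fitted" / "qc.json").write_text(json.dumps(qc, indent=1))
    return qc


def stage_segment(config: RunConfig, workdir: Path) -> dict:
    frame, fitted = _fitted_inputs(config, workdir)
    truth = workdir / "cohort" / "truth"
    rows = []
    for sid, maps in fitted.items():
        seg = classify_tissue(maps, TissueClassRanges())
        vent = load_volume(truth / f"{sid}_ventricles_native.nii.gz")[0] > 0.5
        report = compute_volumes(seg, vent)
        rows.append({
            "id": sid,
            "intracranial_volume_ml": report.intracranial_volume,
            "brain_volume_ml": report.brain_volume,
            "ventricular_volume_ml": report.ventricular_volume,
            "bpf_percent": report.brain_parenchymal_fraction,
            "vf_percent": report.ventricular_fraction,
        })
    out = pd.DataFrame(rows).merge(frame, on="id")
    outdir = workdir / "segmented"
    outdir.mkdir(exist_ok=True)
    out.to_csv(outdir / "volumes.tsv", sep="\t", index=False)
    by_group = out.groupby("group")[["bpf_percent", "vf_percent"]].mean()
    return {"group_means": by_group.to_dict()}


def stage_normalize(config: RunConfig, workdir: Path) -> dict:
    frame, fitted = _fitted_inputs(config, workdir)
    truth = workdir / "cohort" / "truth"
    spec = config.phantom_spec()
    template = build_template(spec, atrophy_factor=1.0)
    target = template.grid
    tmpl_maps = template_parameter_maps(template, spec)
    tmpl_image = smooth_gaussian(
        synthesize_contrast_image(tmpl_maps, config.synth_te_ms, config.synth_tr_ms),
        config.fwhm_mm, target)

    max_iters = tuple({4: 200, 2: 120, 1: 30}.get(level, 60)
                      for level in config.registration_levels)
    normalized = {}
    transforms = {}
    dice = {}
    for sid, maps in fitted.items():
        source = smooth_gaussian(
            synthesize_contrast_image(maps, config.synth_te_ms, config.synth_tr_ms),
            config.fwhm_mm, maps.grid)
        t = estimate_affine(source, tmpl_image, maps.grid, target,
                            levels=config.registration_levels,
                            max_iter=max_iters)
        normalized[sid] = apply_and_regrid(maps, t, target)
        transforms[sid] = t.to_dict()
        vent_native = load_volume(truth / f"{sid}_ventricles_native.nii.gz")[0] > 0.5
        vent_subject = load_volume(truth / f"{sid}_ventricles.nii.gz")[0] > 0.5
        moved = apply_transform(vent_native.astype(float), maps.grid,
                                t.matrix, target, order=0) > 0.5
        inter = (moved & vent_subject).sum()
        dice[sid] = float(2.0 * inter / max(moved.sum() + vent_subject.sum(), 1))
    _write_maps(normalized, workdir / "normalized")
    outdir = workdir / "normalized"
    (outdir / "transforms.json").write_text(json.dumps(transforms, indent=1))
    (outdir / "qc.json").write_text(json.dumps({"ventricle_dice": dice}, indent=1))
    return {"mean_ventricle_dice": float(np.mean(list(dice.values()))),
            "min_ventricle_dice": float(np.min(list(dice.values())))}


def _analysis_context(config: RunConfig, workdir: Path):
    frame, normalized = _normalized_inputs(config, workdir)
    spec = config.phantom_spec()
    template = build_template(spec, atrophy_factor=1.0)
    all_masks = np.all([normalized[sid].mask for sid in frame["id"]], axis=0)
    mask = template.brain_mask & all_masks
    return frame, normalized, template, mask


def stage_stats(config: RunConfig, workdir: Path) -> dict:
    frame, normalized, template, mask = _analysis_context(config, workdir)
    outdir = workdir / "stats"
    outdir.mkdir(exist_ok=True)
    design = voxelstats.DesignInfo.from_frame(frame)
    grid = template.grid
    rois = {name: template.rois[name] & mask for name in WM_FAMILY}

    report = {}
    fwe_frames = []
    patients = frame[frame["group"] == "patient"]
    pat_design = voxelstats.DesignInfo.from_frame(patients) \
        if "edss" in patients else None
    for p in PARAMS:
        maps_list = [getattr(normalized[sid], p) for sid in frame["id"]]
        direction = "patient>reference" if p == "pd" else "reference>patient"
        tmap = voxelstats.glm_group_contrast(maps_list, design, grid, mask)
        if p == "pd":
            tmap.data = -tmap.data  # report patient-minus-reference direction
            tmap.contrast = "patient>reference"
        overlay = voxelstats.threshold_map(tmap, config.t_threshold)
        save_volume(tmap.data, grid, outdir / f"tmap_{p}.nii.gz")
        save_volume(overlay.astype(np.uint8), grid,
                    outdir / f"tmap_{p}_thresholded.nii.gz")
        (outdir / f"tmap_{p}.json").write_text(json.dumps({
            "kind": tmap.kind, "df": tmap.df, "contrast": tmap.contrast,
            "threshold": tmap.threshold}, indent=1))
        fwe = voxelstats.permutation_fwe_svc(
            maps_list, design, grid, mask, rois, n_perm=config.n_perm,
            seed=config.seeds()["permutation"], direction=direction)
        fwe.insert(0, "parameter", p)
        fwe_frames.append(fwe)
        report[f"t_{p}_wm_mean"] = float(
            tmap.data[template.rois["white_matter"] & mask].mean())

        if pat_design is not None:
            pat_maps = [getattr(normalized[sid], p) for sid in patients["id"]]
            slope_map, slope_t = voxelstats.edss_slope_map(
                pat_maps, pat_design, grid, mask, return_t=True)
            save_volume(slope_map.data, grid, outdir / f"edss_slope_{p}.nii.gz")
            save_volume(slope_t.data, grid, outdir / f"edss_t_{p}.nii.gz")
            group_t = tmap if p != "pd" else None
            reg_t = voxelstats.StatMap(
                -tmap.data if p == "pd" else tmap.data, "t", tmap.df,
                "reference>patient", grid, mask)
            slope, r2 = voxelstats.map_regression(reg_t, slope_map, mask)
            report[f"map_regression_{p}"] = {"slope": slope, "r2": r2}
    fwe_all = pd.concat(fwe_frames, ignore_index=True)
    fwe_all.to_csv(outdir / "roi_fwe.tsv", sep="\t", index=False)
    (outdir / "map_regression.json").write_text(json.dumps(
        {k: v for k, v in report.items() if k.startswith("map_regression")},
        indent=1))
    report["fwe_max_p"] = float(fwe_all["p_fwe"].max())
    return report


def stage_hist(config: RunConfig, workdir: Path) -> dict:
    frame, normalized, template, mask = _analysis_context(config, workdir)
    outdir = workdir / "hist"
    outdir.mkdir(exist_ok=True)
    ref_ids = frame.loc[frame["group"] == "reference", "id"]
    pat_ids = frame.loc[frame["group"] == "patient", "id"]
    cohort_a = [normalized[sid] for sid in ref_ids]
    cohort_b = [normalized[sid] for sid in pat_ids]
    grid = template.grid

    marker_masks = {name: roitools.erode_roi(template.rois[name], 2.0, grid)
                    for name in MARKER_ROIS}
    marker_masks = {k: v for k, v in marker_masks.items() if v.any()}
    report = {}
    for pair in multiparametric.PAIRS:
        hist = multiparametric.difference_histogram(
            cohort_a, cohort_b, pair, bins=config.bins_whole,
            threshold_frac=config.threshold_frac)
        markers = multiparametric.roi_markers(cohort_a, cohort_b,
                                              marker_masks, pair)
        _write_histogram(hist, outdir / f"wholebrain_{pair}.tsv")
        multiparametric.plot_difference_histogram(
            hist, outdir / f"wholebrain_{pair}.png", markers)
        report[f"net_mass_{pair}"] = hist.net_mass
    # ROI-level histograms on percentile ranges with fewer bins
    for roi_name in ("deep_gm", "white_matter"):
        roi = roitools.erode_roi(template.rois[roi_name], 2.0, grid)
        if not roi.any():
            continue
        ranges = multiparametric.roi_ranges(cohort_a, cohort_b, roi, "r1_r2")
        hist = multiparametric.difference_histogram(
            cohort_a, cohort_b, "r1_r2", bins=config.bins_roi,
            ranges=ranges, mask=roi)
        _write_histogram(hist, outdir / f"roi_{roi_name}_r1_r2.tsv")
        multiparametric.plot_difference_histogram(
            hist, outdir / f"roi_{roi_name}_r1_r2.png")
    return report


def _write_histogram(hist, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# pair\t" + hist.pair + "\n")
        fh.write("# x_edges\t" + "\t".join(f"{v:.6g}" for v in hist.x_edges) + "\n")
        fh.write("# y_edges\t" + "\t".join(f"{v:.6g}" for v in hist.y_edges) + "\n")
        np.savetxt(fh, hist.counts, delimiter="\t", fmt="%.6g")


def stage_roi(config: RunConfig, workdir: Path) -> dict:
    frame, normalized, template, mask = _analysis_context(config, workdir)
    outdir = workdir / "roi"
    outdir.mkdir(exist_ok=True)
    grid = template.grid
    cohorts = {
        "reference": [normalized[sid] for sid in
                      frame.loc[frame["group"] == "reference", "id"]],
        "patient": [normalized[sid] for sid in
                    frame.loc[frame["group"] == "patient", "id"]],
    }
    rois = {name: template.rois[name] for name in SUMMARY_ROIS}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summary = roitools.roi_summary(cohorts, rois, grid,
                                       levels=config.erosion_levels)
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)

    all_maps = [normalized[sid] for sid in frame["id"]]
    labels = (frame["group"] == "patient").to_numpy()
    rows = []
    for roi_name, roi in rois.items():
        for p in PARAMS:
            res = roitools.mixed_model_group_test(all_maps, labels, roi, p)
            rows.append({"roi": roi_name, "parameter": p, **res})
    mixed = pd.DataFrame(rows)
    mixed.to_csv(outdir / "mixed_model.tsv", sep="\t", index=False)

    bands = []
    for roi_name in ("deep_gm", "white_matter"):
        for group, maps_list in cohorts.items():
            b = roitools.distance_band_means(maps_list, rois[roi_name], grid)
            b.insert(0, "roi", roi_name)
            b.insert(1, "group", group)
            bands.append(b)
    pd.concat(bands, ignore_index=True).to_csv(
        outdir / "distance_bands.tsv", sep="\t", index=False)
    return {"mixed_model_max_p": float(mixed["p"].max()),
            "n_summary_rows": len(summary)}


# ---------------------------------------------------------------------------
# stage wiring
# ---------------------------------------------------------------------------

def _cohort_inputs(config, workdir):
    cohort_dir = workdir / "cohort"
    if not (cohort_dir / "subjects.tsv").exists():
        raise FileNotFoundError(
            f"no cohort at {cohort_dir}; run the 'simulate' stage first")
    return read_cohort(cohort_dir)


def _fitted_inputs(config, workdir):
    frame, _ = _cohort_inputs(config, workdir)
    return frame, _read_stage_maps(workdir / "fitted", frame, "fit")


def _normalized_inputs(config, workdir):
    frame, _ = _cohort_inputs(config, workdir)
    return frame, _read_stage_maps(workdir / "normalized", frame, "normalize")


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages in dependency order; returns the run report.

    The report collects per-stage QC (fit failures, registration overlap,
    clipping rates) and is also written to ``workdir/report.json``.
    """
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    config.to_file(workdir / "config.json")
    report = {"config_hash": config.config_hash(), "seeds": config.seeds(),
              "stages": {}}
    runners = {
        "simulate": stage_simulate,
        "fit": stage_fit,
        "segment": stage_segment,
        "normalize": stage_normalize,
        "stats": stage_stats,
        "hist": stage_hist,
        "roi": stage_roi,
    }
    for stage in STAGES:
        if stage in config.stages:
            report["stages"][stage] = runners[stage](config, workdir)
    (workdir / "report.json").write_text(json.dumps(report, indent=1))
    return report
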