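"""Signed two-dimensional parameter histograms comparing two groups.

Every in-mask voxel of every subject contributes one point in a parameter
pair plane -- (R1, R2), (R1, PD) or (R2, PD).  Counts are pooled per group,
divided by the group's subject count (so unequal cohorts stay comparable)
and subtracted: positive bins hold more (normalised) voxels in group A,
negative bins more in group B.  A 10 % signal-intensity inclusion threshold
(on the reference-group mean PD map, the intensity proxy available after
normalisation) removes background.  Whole-brain histograms default to 200
bins per axis, ROI histograms to 50.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PAIRS",
    "DEFAULT_RANGES",
    "DiffHistogram",
    "ROIMarkerSet",
    "inclusion_mask",
    "build_histogram",
    "difference_histogram",
    "roi_markers",
    "plot_difference_histogram",
]

PAIRS = ("r1_r2", "r1_pd", "r2_pd")

# display windows of the parameter maps: R1 0-3 1/s, R2 0-15 1/s, PD 50-100 %
DEFAULT_RANGES = {
    "r1": (0.0, 3.0),
    "r2": (0.0, 15.0),
    "pd": (50.0, 100.0),
}


def _pair_axes(pair: str) -> tuple[str, str]:
    if pair not in PAIRS:
        raise ValueError(f"pair must be one of {PAIRS}")
    a, b = pair.split("_")
    return a, b


@dataclass
class DiffHistogram:
    """Signed bin-count matrix for one parameter pair."""

    pair: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray  # signed, normalised to equal subject counts
    threshold_frac: float
    n_voxels_a: int
    n_voxels_b: int
    n_subjects_a: int
    n_subjects_b: int

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.x_edges) - 1, len(self.y_edges) - 1):
            raise ValueError("count matrix shape must match the bin edges")

    @property
    def net_mass(self) -> float:
        """Total signed mass = normalised included-voxel-count difference."""
        return float(self.counts.sum())


@dataclass
class ROIMarkerSet:
    """Group mean positions per ROI in one parameter plane, with arrows
    pointing from the reference mean to the patient mean."""

    pair: str
    markers: dict[str, dict]  # roi -> {"reference": (x, y), "patient": (x, y)}

    def arrow(self, roi: str) -> np.ndarray:
        m = self.markers[roi]
        return np.asarray(m["patient"]) - np.asarray(m["reference"])


def inclusion_mask(reference_maps, threshold_frac: float = 0.10) -> np.ndarray:
    """Voxels whose mean reference intensity (PD) exceeds the threshold
    fraction of its ceiling.

    The ceiling is the 99.5th percentile of the positive mean-PD values
    rather than the raw maximum: near-background voxels can fit to
    arbitrarily large amplitudes, and a single such outlier would otherwise
    push the 10 % threshold above every real brain voxel.
    """
    mean_pd = np.mean([np.asarray(m.pd) for m in reference_maps], axis=0)
    positive = mean_pd[mean_pd > 0]
    if positive.size == 0:
        return np.zeros(mean_pd.shape, dtype=bool)
    ceiling = np.percentile(positive, 99.5)
    return mean_pd > threshold_frac * ceiling


def _pooled_values(maps_list, pair, mask):
    ax, ay = _pair_axes(pair)
    xs, ys = [], []
    for m in maps_list:
        vol = {"r1": m.r1, "r2": m.r2, "pd": m.pd}
        xs.append(np.asarray(vol[ax])[mask])
        ys.append(np.asarray(vol[ay])[mask])
    return np.concatenate(xs), np.concatenate(ys)


def build_histogram(maps_list, pair: str, bins: int = 200,
                    ranges: dict | None = None,
                    mask: np.ndarray | None = None):
    """Pooled 2-D histogram of one group's voxels.

    Voxels outside the axis ranges are dropped.  Returns
    (counts, x_edges, y_edges, n_included).
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    if not maps_list:
        raise ValueError("empty cohort")
    ax, ay = _pair_axes(pair)
    ranges = {**DEFAULT_RANGES, **(ranges or {})}
    if mask is None:
        mask = np.ones(maps_list[0].grid.shape, dtype=bool)
    x, y = _pooled_values(maps_list, pair, mask)
    counts, xe, ye = np.histogram2d(
        x, y, bins=bins, range=[ranges[ax], ranges[ay]])
    return counts, xe, ye, int(counts.sum())


def difference_histogram(cohort_a, cohort_b, pair: str, bins: int = 200,
                         ranges: dict | None = None,
                         threshold_frac: float = 0.10,
                         mask: np.ndarray | None = None) -> DiffHistogram:
    """Signed difference histogram between two groups of normalised maps.

    ``cohort_a`` and ``cohort_b`` are lists of :class:`ParameterMaps` on a
    common grid (conventionally A = reference, B = patients).  Counts are
    divided by the subject count of each group before differencing.  The
    default inclusion mask keeps voxels above ``threshold_frac`` of the
    maximum mean reference intensity.
    """
    if not cohort_a or not cohort_b:
        raise ValueError("both cohorts must be non-empty")
    grid = cohort_a[0].grid
    for m in cohort_a + cohort_b:
        grid.require_match(m.grid, "cohort maps")
    if mask is None:
        mask = inclusion_mask(cohort_a, threshold_frac)
    ca, xe, ye, na = build_histogram(cohort_a, pair, bins, ranges, mask)
    cb, _, _, nb = build_histogram(cohort_b, pair, bins, ranges, mask)
    signed = ca / len(cohort_a) - cb / len(cohort_b)
    return DiffHistogram(pair, xe, ye, signed, threshold_frac, na, nb,
                         len(cohort_a), len(cohort_b))


def roi_markers(cohort_a, cohort_b, roi_masks: dict[str, np.ndarray],
                pair: str) -> ROIMarkerSet:
    """Group mean (x, y) per ROI in the pair's parameter plane.

    ROI masks should already be eroded (cropped) to limit partial-volume
    contamination at the edges; empty ROIs are skipped with a warning.
    """
    import warnings

    ax, ay = _pair_axes(pair)
    markers: dict[str, dict] = {}
    for name, roi in roi_masks.items():
        if not np.asarray(roi).any():
            warnings.warn(f"ROI {name!r} is empty; skipped", stacklevel=2)
            continue
        entry = {}
        for label, cohort in (("reference", cohort_a), ("patient", cohort_b)):
            xs, ys = _pooled_values(cohort, pair, np.asarray(roi, dtype=bool))
            entry[label] = (float(xs.mean()), float(ys.mean()))
        markers[name] = entry
    return ROIMarkerSet(pair, markers)


def plot_difference_histogram(hist: DiffHistogram, path=None,
                              marker_set: ROIMarkerSet | None = None,
                              ax=None):
    """Render a signed histogram with a diverging blue/red colour map.

    Blue indicates reference-group excess, red patient excess; colour
    limits are symmetric.  Optional ROI markers: squares for the reference
    group, circles for patients, arrows from reference to patient.
    """
    import matplotlib
    if path is not None and matplotlib.get_backend().lower() != "agg":
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    created = ax is None
    if created:
        fig, ax = plt.subplots(figsize=(5, 4.2))
    else:
        fig = ax.figure
    vmax = np.abs(hist.counts).max() or 1.0
    xa, ya = _pair_axes(hist.pair)
    im = ax.pcolormesh(hist.x_edges, hist.y_edges, hist.counts.T,
                       cmap="RdBu", vmin=-vmax, vmax=vmax)
    labels = {"r1": "R1 (1/s)", "r2": "R2 (1/s)", "pd": "PD (%)"}
    ax.set_xlabel(labels[xa])
    ax.set_ylabel(labels[ya])
    fig.colorbar(im, ax=ax, label="reference excess  <->  patient excess")
    if marker_set is not None:
        for name, m in marker_set.markers.items():
            rx, ry = m["reference"]
            px, py = m["patient"]
            ax.plot(rx, ry, "ks", ms=5, mfc="none")
            ax.plot(px, py, "ko", ms=5, mfc="none")
            ax.annotate("", xy=(px, py), xytext=(rx, ry),
                        arrowprops={"arrowstyle": "->", "lw": 1.0})
            ax.annotate(name, (rx, ry), fontsize=7,
                        textcoords="offset points", xytext=(3, 3))
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax


def roi_ranges(cohort_a, cohort_b, roi: np.ndarray, pair: str,
               percentiles: tuple[float, float] = (1.0, 99.0)) -> dict:
    """Pooled percentile-based axis ranges for ROI-level histograms, so a
    50-bin histogram stays informative on a small value range."""
    ax, ay = _pair_axes(pair)
    xs, ys = [], []
    for cohort in (cohort_a, cohort_b):
        x, y = _pooled_values(cohort, pair, np.asarray(roi, dtype=bool))
        xs.append(x)
        ys.append(y)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    return {ax: tuple(np.percentile(x, percentiles)),
            ay: tuple(np.percentile(y, percentiles))}
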