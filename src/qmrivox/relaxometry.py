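"""Saturation-recovery multi-echo relaxometry.

The acquisition acquires, for every slice, a grid of spin-echo images at
several saturation delays (longitudinal recovery, sensitive to R1) crossed
with several echo times (transverse decay, sensitive to R2).  With the
default protocol of 4 delays x 5 echoes each voxel carries 20 intensity
samples

    S(td, te) = k * PD * (1 - exp(-td * R1)) * exp(-te * R2)

assuming mono-exponential relaxation and ideal saturation, where ``td`` is
the saturation delay, ``te`` the echo time, ``k`` an arbitrary scanner gain
and PD the proton density.  This module provides the forward model, a
simulator, a vectorised per-voxel estimator of (R1, R2, PD) and synthetic
contrast-weighted image reconstruction from fitted maps.

Units: delays/echoes are milliseconds, relaxation rates s^-1; PD is
expressed in percent where 100 % is pure water at 37 degC after calibration
against a cerebrospinal-fluid reference region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Grid

__all__ = [
    "AcquisitionProtocol",
    "SignalStack",
    "ParameterMaps",
    "predict_signal",
    "simulate_stack",
    "fit_parameter_maps",
    "calibrate_pd",
    "synthesize_contrast_image",
]

MS_TO_S = 1e-3  # delays/echoes are ms, rates s^-1


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing grid of the multi-delay multi-echo acquisition (ms)."""

    saturation_delays: tuple[float, ...] = (100.0, 400.0, 1380.0, 2860.0)
    echo_times: tuple[float, ...] = (14.0, 28.0, 42.0, 56.0, 70.0)
    repetition_time: float = 2950.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        td = np.asarray(self.saturation_delays, dtype=float)
        te = np.asarray(self.echo_times, dtype=float)
        if td.size < 1 or np.any(np.diff(td) <= 0):
            raise ValueError("saturation delays must be strictly increasing")
        if np.any(td >= self.repetition_time):
            raise ValueError("saturation delays must be below the repetition time")
        if te.size < 1 or np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be positive and strictly increasing")
        object.__setattr__(self, "saturation_delays", tuple(float(x) for x in td))
        object.__setattr__(self, "echo_times", tuple(float(x) for x in te))

    @property
    def n_images(self) -> int:
        """Images acquired per slice (delays x echoes)."""
        return len(self.saturation_delays) * len(self.echo_times)


@dataclass
class SignalStack:
    """Acquired intensities indexed (delay, echo, i, j, k)."""

    data: np.ndarray
    protocol: AcquisitionProtocol
    grid: Grid

    def __post_init__(self) -> None:
        nd, ne = len(self.protocol.saturation_delays), len(self.protocol.echo_times)
        if self.data.ndim != 5 or self.data.shape[:2] != (nd, ne):
            raise ValueError(
                f"stack shape {self.data.shape} does not match protocol "
                f"({nd} delays x {ne} echoes)")
        if tuple(self.data.shape[2:]) != self.grid.shape:
            raise ValueError("stack spatial shape does not match its grid")


@dataclass
class ParameterMaps:
    """Co-registered R1 (s^-1), R2 (s^-1) and PD (%) volumes with a brain mask."""

    r1: np.ndarray
    r2: np.ndarray
    pd: np.ndarray
    grid: Grid
    mask: np.ndarray | None = None
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.r1.shape == self.r2.shape == self.pd.shape == tuple(self.grid.shape)):
            raise ValueError("R1/R2/PD maps must share the grid shape")
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        elif self.mask.shape != tuple(self.grid.shape):
            raise ValueError("mask shape must match the maps")

    def stacked(self) -> np.ndarray:
        """(3, *shape) view in the order (R1, R2, PD)."""
        return np.stack([self.r1, self.r2, self.pd])


def predict_signal(r1, r2, pd, delay, echo, gain: float = 1.0):
    """Forward spin-echo saturation-recovery signal.

    Monotone increasing in ``delay`` (recovery) and decreasing in ``echo``
    (decay); broadcasts over array arguments.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    pd = np.asarray(pd, dtype=float)
    if np.any(r1 < 0) or np.any(r2 < 0) or np.any(pd < 0):
        raise ValueError("R1, R2 and PD must be non-negative")
    if np.any(np.asarray(delay) < 0) or np.any(np.asarray(echo) < 0):
        raise ValueError("delay and echo must be non-negative")
    recovery = 1.0 - np.exp(-np.asarray(delay, dtype=float) * MS_TO_S * r1)
    decay = np.exp(-np.asarray(echo, dtype=float) * MS_TO_S * r2)
    return gain * pd * recovery * decay


def simulate_stack(
    maps: ParameterMaps,
    protocol: AcquisitionProtocol | None = None,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> SignalStack:
    """Simulate the acquisition from parameter maps.

    ``noise_sigma`` is additive Gaussian noise expressed as a fraction of
    the maximum noiseless signal (magnitude-signal approximation; negative
    samples are clipped to zero).
    """
    protocol = protocol or AcquisitionProtocol()
    td = np.asarray(protocol.saturation_delays)[:, None, None, None, None]
    te = np.asarray(protocol.echo_times)[None, :, None, None, None]
    signal = predict_signal(maps.r1, maps.r2, maps.pd, td, te, protocol.gain)
    if noise_sigma > 0:
        rng = np.random.default_rng(rng)
        signal = signal + rng.normal(
            0.0, noise_sigma * signal.max(), size=signal.shape)
        np.clip(signal, 0.0, None, out=signal)
    return SignalStack(signal, protocol, maps.grid)


def _initial_estimates(y: np.ndarray, td: np.ndarray, te: np.ndarray):
    """Two-stage initialiser exploiting the separable delay x echo structure.

    Stage 1: per delay, a log-linear fit of intensity on echo time gives a
    per-delay R2 and the echo-extrapolated amplitude A_d = M(1-exp(-td R1)).
    Stage 2: R1 (and M) from the recovery of the amplitudes via a coarse
    1-D search over R1 with the amplitude solved in closed form.
    """
    n_vox = y.shape[0]
    eps = max(float(y.max()), 1e-30) * 1e-12
    logy = np.log(np.maximum(y, eps))  # (vox, nd, ne)
    w = y ** 2  # weight down low-SNR late echoes
    sw = w.sum(axis=2)
    sw = np.maximum(sw, 1e-30)
    mx = (w * te).sum(axis=2) / sw
    my = (w * logy).sum(axis=2) / sw
    sxx = (w * (te - mx[..., None]) ** 2).sum(axis=2)
    sxy = (w * (te - mx[..., None]) * (logy - my[..., None])).sum(axis=2)
    slope = sxy / np.maximum(sxx, 1e-30)  # per delay
    r2_d = -slope / MS_TO_S
    amp_d = np.exp(my - slope * mx)  # A_d at te = 0
    # pool R2 across delays, weighting by amplitude
    wa = np.maximum(amp_d, 0.0) + 1e-30
    r2 = np.clip((wa * r2_d).sum(axis=1) / wa.sum(axis=1), 1e-3, 200.0)

    # stage 2: coarse search for R1
    grid = np.geomspace(0.02, 10.0, 64)
    best_sse = np.full(n_vox, np.inf)
    r1 = np.full(n_vox, 1.0)
    m = amp_d.max(axis=1)
    for r1_cand in grid:
        f = 1.0 - np.exp(-td * MS_TO_S * r1_cand)  # (nd,)
        m_cand = (amp_d * f).sum(axis=1) / (f ** 2).sum()
        sse = ((amp_d - m_cand[:, None] * f) ** 2).sum(axis=1)
        better = sse < best_sse
        best_sse[better] = sse[better]
        r1[better] = r1_cand
        m[better] = m_cand[better]
    return r1, r2, np.maximum(m, eps)


def _levenberg_marquardt(y, td, te, r1, r2, m, max_iter=50, tol=1e-14):
    """Batched Levenberg-Marquardt on theta = (M, R1, R2) per voxel.

    Solves the 3x3 normal equations for all voxels simultaneously; returns
    refined parameters and a per-voxel convergence flag.
    """
    n_vox = y.shape[0]
    yf = y.reshape(n_vox, -1)
    tdf = np.broadcast_to(td[:, None], (td.size, te.size)).reshape(-1) * MS_TO_S
    tef = np.broadcast_to(te[None, :], (td.size, te.size)).reshape(-1) * MS_TO_S
    lam = np.full(n_vox, 1e-3)
    theta = np.stack([m, r1, r2], axis=1)

    def residual_sse(th):
        e1 = np.exp(-tdf[None, :] * th[:, 1:2])
        e2 = np.exp(-tef[None, :] * th[:, 2:3])
        model = th[:, 0:1] * (1.0 - e1) * e2
        res = model - yf
        return res, e1, e2, (res ** 2).sum(axis=1)

    res, e1, e2, sse = residual_sse(theta)
    scale = np.maximum(sse.max(), 1e-300)
    active = np.ones(n_vox, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        th = theta[active]
        r, a1, a2, s = res[active], e1[active], e2[active], sse[active]
        j = np.empty((th.shape[0], r.shape[1], 3))
        j[:, :, 0] = (1.0 - a1) * a2
        j[:, :, 1] = th[:, 0:1] * tdf[None, :] * a1 * a2
        j[:, :, 2] = -th[:, 0:1] * tef[None, :] * (1.0 - a1) * a2
        jtj = np.einsum("nsa,nsb->nab", j, j)
        jtr = np.einsum("nsa,ns->na", j, r)
        diag = np.maximum(np.einsum("naa->na", jtj), 1e-12)
        aug = jtj + lam[active, None, None] * diag[:, :, None] * np.eye(3)
        try:
            step = np.linalg.solve(aug, -jtr[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = -np.einsum("nab,nb->na", np.linalg.pinv(aug), jtr)
        th_new = th + step
        th_new[:, 0] = np.maximum(th_new[:, 0], 0.0)
        th_new[:, 1] = np.clip(th_new[:, 1], 1e-4, 100.0)
        th_new[:, 2] = np.clip(th_new[:, 2], 1e-4, 500.0)
        b1 = np.exp(-tdf[None, :] * th_new[:, 1:2])
        b2 = np.exp(-tef[None, :] * th_new[:, 2:3])
        r_new = th_new[:, 0:1] * (1.0 - b1) * b2 - yf[active]
        s_new = (r_new ** 2).sum(axis=1)
        improved = s_new < s
        lam_a = lam[active]
        lam_a[improved] = np.maximum(lam_a[improved] * 0.3, 1e-12)
        lam_a[~improved] = np.minimum(lam_a[~improved] * 10.0, 1e12)
        lam[active] = lam_a
        idx = np.where(active)[0][improved]
        theta[idx] = th_new[improved]
        res[idx] = r_new[improved]
        e1[idx], e2[idx] = b1[improved], b2[improved]
        sse[idx] = s_new[improved]
        # deactivate voxels whose improvement is negligible
        done = np.zeros(active.sum(), dtype=bool)
        done[improved] = (s[improved] - s_new[improved]) < tol * scale
        still = np.where(active)[0]
        active[still[done]] = False
    converged = ~active if max_iter > 0 else np.ones(n_vox, bool)
    return theta, converged


def fit_parameter_maps(
    stack: SignalStack,
    background_floor: float = 0.05,
    csf_reference: np.ndarray | None = None,
    max_iter: int = 50,
    pd_ceiling: float = 150.0,
) -> ParameterMaps:
    """Estimate per-voxel (R1, R2, PD) by nonlinear least squares.

    Voxels whose maximum intensity over all samples is below
    ``background_floor`` times the stack maximum are masked out.  The fitted
    amplitude is proportional to PD times the scanner gain; if a
    ``csf_reference`` mask is given the amplitudes are calibrated to percent
    via :func:`calibrate_pd`, otherwise raw amplitudes are returned in
    ``pd`` (gain-dependent units) and ``qc['pd_calibrated']`` is False.

    Calibrated voxels outside the physical range (negative or above
    ``pd_ceiling`` percent; pure water is 100 %) are unstable edge fits
    where almost no recovery signal constrains the amplitude.  They are
    removed from the mask and counted in ``qc['n_pd_out_of_range']``.

    Non-convergent voxels keep the two-stage initial estimate and are
    counted in ``qc['n_nonconverged']``.
    """
    nd, ne = stack.data.shape[:2]
    if nd < 2 or ne < 2:
        raise ValueError("need at least 2 delays and 2 echoes to fit")
    shape = stack.grid.shape
    peak = stack.data.max(axis=(0, 1))
    mask = peak > background_floor * peak.max()
    y = np.moveaxis(stack.data, (0, 1), (3, 4))[mask]  # (vox, nd, ne)
    td = np.asarray(stack.protocol.saturation_delays)
    te = np.asarray(stack.protocol.echo_times)

    r1_0, r2_0, m_0 = _initial_estimates(y, td, te)
    theta, converged = _levenberg_marquardt(
        y, td, te, r1_0, r2_0, m_0, max_iter=max_iter)
    theta[~converged] = np.stack(
        [m_0[~converged], r1_0[~converged], r2_0[~converged]], axis=1)

    r1 = np.zeros(shape)
    r2 = np.zeros(shape)
    amp = np.zeros(shape)
    r1[mask], r2[mask], amp[mask] = theta[:, 1], theta[:, 2], theta[:, 0]
    amp /= stack.protocol.gain
    qc = {
        "n_fitted": int(mask.sum()),
        "n_nonconverged": int((~converged).sum()),
        "pd_calibrated": False,
    }
    maps = ParameterMaps(r1, r2, amp, stack.grid, mask, qc)
    if csf_reference is not None:
        calibrate_pd(maps, csf_reference)
    if qc["pd_calibrated"]:
        bad = maps.mask & ((maps.pd < 0) | (maps.pd > pd_ceiling))
        qc["n_pd_out_of_range"] = int(bad.sum())
        if bad.any():
            maps.mask &= ~bad
            maps.r1[bad] = 0.0
            maps.r2[bad] = 0.0
            maps.pd[bad] = 0.0
    else:
        qc["n_pd_out_of_range"] = 0
    return maps


def calibrate_pd(maps: ParameterMaps, csf_reference: np.ndarray,
                 reference_pd: float = 100.0) -> ParameterMaps:
    """Express fitted amplitudes in percent of pure water.

    Divides the amplitude map by the mean amplitude inside the designated
    pure-CSF reference region and multiplies by ``reference_pd`` (100 % =
    pure water at 37 degC).  Modifies ``maps`` in place and returns it.
    """
    ref = np.asarray(csf_reference, dtype=bool)
    if ref.shape != tuple(maps.grid.shape):
        raise ValueError("CSF reference mask shape does not match the maps")
    ref = ref & maps.mask
    if not ref.any():
        raise ValueError("CSF reference region is empty inside the brain mask")
    mean_amp = float(maps.pd[ref].mean())
    if mean_amp <= 0:
        raise ValueError("CSF reference region has non-positive mean amplitude")
    maps.pd = maps.pd * (reference_pd / mean_amp)
    maps.qc["pd_calibrated"] = True
    maps.qc["pd_scale"] = reference_pd / mean_amp
    return maps


def synthesize_contrast_image(
    maps: ParameterMaps, echo: float, repetition: float
) -> np.ndarray:
    """Reconstruct a contrast-weighted image from quantitative maps.

    Per voxel ``S = PD * (1 - exp(-TR * R1)) * exp(-TE * R2)`` (ms); long
    TE / long TR gives a T2-weighted appearance, the registration source
    contrast.
    """
    if echo < 0 or repetition <= 0:
        raise ValueError("echo must be non-negative and repetition positive")
    img = predict_signal(maps.r1, maps.r2, maps.pd, repetition, echo)
    return np.where(maps.mask, img, 0.0)
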