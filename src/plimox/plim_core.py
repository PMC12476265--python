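"""Decay-trace processing: intensity images, averaging, smoothing, fitting.

The per-pixel model is a single-exponential decay on a constant baseline,

    I(t) = I0 * exp(-k t) + offset,

fitted by unweighted nonlinear least squares over the post-pulse,
post-guard samples.  The offset absorbs the detector baseline and, in
simultaneous-imaging mode, the CW steady-state term, so the fitted rate is
insensitive to either.  Lifetime is tau = 1/k.

Averaging rules follow the acquisition protocol: repeated volumes are
averaged sample-wise; point-by-point maps are smoothed with a 3x3 moving
average of neighbouring traces before fitting; vessel-level values average
the traces over the vessel mask first and fit once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit

from .trace_sim import AcquisitionConfig, TraceStack

__all__ = [
    "DecayFit",
    "RateMap",
    "intensity_image",
    "average_acquisitions",
    "spatial_smooth_3x3",
    "fit_decay",
    "fit_map",
    "average_vessel_trace",
]


@dataclass(frozen=True)
class DecayFit:
    """Result of a single-exponential fit to one decay trace."""

    I0: float
    k: float            # s^-1; NaN on failure
    offset: float
    tau: float          # s, = 1/k; NaN on failure
    rss: float
    success: bool
    n_points: int

    @classmethod
    def failed(cls, n_points: int = 0) -> "DecayFit":
        return cls(I0=np.nan, k=np.nan, offset=np.nan, tau=np.nan,
                   rss=np.nan, success=False, n_points=n_points)


@dataclass
class RateMap:
    """Per-pixel fitted decay-rate image with a success mask."""

    k_image: np.ndarray          # s^-1, NaN where fit failed/skipped
    success_mask: np.ndarray     # bool
    config: AcquisitionConfig | None = None
    temperature: float | None = None

    @property
    def tau_image(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.success_mask, 1.0 / self.k_image, np.nan)


def intensity_image(stack: TraceStack) -> np.ndarray:
    """Mean of the in-pulse samples: the phosphorescence intensity image.

    Averages the samples recorded while the excitation pulse is on
    (t in [0, pulse_duration)), exactly round(pulse_duration *
    sampling_rate) of them.
    """
    n = stack.config.n_pulse_samples
    if n < 1:
        raise ValueError("no samples inside the excitation pulse window")
    return stack.data[:n].mean(axis=0)


def average_acquisitions(stacks: Sequence[TraceStack]) -> TraceStack:
    """Element-wise mean of repeated acquisitions ("volume" averaging)."""
    if len(stacks) == 0:
        raise ValueError("no stacks to average")
    first = stacks[0]
    for s in stacks[1:]:
        if s.data.shape != first.data.shape:
            raise ValueError("stack shapes differ")
        if s.config != first.config:
            raise ValueError("stack configs differ")
    data = np.mean([s.data for s in stacks], axis=0)
    return TraceStack(data=data, config=first.config,
                      temperature=first.temperature, seed=first.seed)


def spatial_smooth_3x3(stack: TraceStack) -> TraceStack:
    """3x3 moving average of each trace with its neighbouring traces.

    Applied per time sample.  Edge pixels average over their shrunken
    neighbourhood (no padding), so corners use 4 pixels and edges 6.
    """
    ny, nx = stack.data.shape[1:]
    if ny < 3 or nx < 3:
        raise ValueError("grid must be at least 3x3")
    kern = np.ones((1, 3, 3))
    summed = ndimage.convolve(stack.data, kern, mode="constant", cval=0.0)
    counts = ndimage.convolve(np.ones((1, ny, nx)), kern,
                              mode="constant", cval=0.0)
    return TraceStack(data=summed / counts, config=stack.config,
                      temperature=stack.temperature, seed=stack.seed)


def _decay_samples(config: AcquisitionConfig):
    """(decay_time, index) of samples used for fitting: post-pulse, post-guard."""
    t = config.time_axis
    sel = t >= config.pulse_duration + config.guard_interval
    return t[sel] - config.pulse_duration, np.nonzero(sel)[0]


def fit_decay(trace: np.ndarray, config: AcquisitionConfig) -> DecayFit:
    """Fit I0*exp(-k t) + offset to one trace's decay window.

    The initializer is a log-linear regression on baseline-subtracted
    samples (baseline = mean of the last 5% of the window); the refined
    fit is unweighted nonlinear least squares with k bounded in
    (0, sampling_rate/2].  Returns a failed fit (NaN rate) rather than
    raising when the trace carries no usable decay.
    """
    trace = np.asarray(trace, dtype=float)
    td, idx = _decay_samples(config)
    if td.size < 10:
        raise ValueError("need at least 10 post-pulse, post-guard samples")
    y = trace[idx]

    n_tail = max(5, int(round(0.05 * y.size)))
    baseline = float(y[-n_tail:].mean())
    ybs = y - baseline
    pos = ybs > 0
    if pos.sum() <= y.size // 2:
        return DecayFit.failed(n_points=y.size)

    # log-linear initial guess on the positive, baseline-subtracted part
    slope, logi0 = np.polyfit(td[pos], np.log(ybs[pos]), 1)
    k0 = -slope
    if not np.isfinite(k0) or k0 <= 0:
        return DecayFit.failed(n_points=y.size)
    k_hi = config.sampling_rate / 2.0
    k0 = min(k0, k_hi * 0.999)
    i0 = float(np.exp(logi0))

    def model(t, i0_, k_, c_):
        return i0_ * np.exp(-k_ * t) + c_

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model, td, y, p0=(i0, k0, baseline),
                bounds=([0.0, 1e-12, -np.inf], [np.inf, k_hi, np.inf]),
                max_nfev=2000)
    except RuntimeError:
        return DecayFit.failed(n_points=y.size)
    i0_f, k_f, c_f = (float(v) for v in popt)
    if k_f <= 0 or not np.isfinite(k_f):
        return DecayFit.failed(n_points=y.size)
    rss = float(((model(td, *popt) - y) ** 2).sum())
    return DecayFit(I0=i0_f, k=k_f, offset=c_f, tau=1.0 / k_f,
                    rss=rss, success=True, n_points=y.size)


def fit_map(stack: TraceStack, smoothing: bool = True,
            intensity_floor_mult: float = 2.0) -> RateMap:
    """Per-pixel decay-rate map.

    Optionally applies the 3x3 trace smoothing first, then fits every
    pixel whose intensity-image value clears a floor of
    ``intensity_floor_mult`` times the median per-pixel tail baseline
    (an estimate of the detector baseline); pixels below the floor are
    reported as failures, never as zero rate.
    """
    work = spatial_smooth_3x3(stack) if smoothing else stack
    img = intensity_image(work)

    n_tail = max(5, int(round(0.05 * work.data.shape[0])))
    baseline_map = work.data[-n_tail:].mean(axis=0)
    floor = intensity_floor_mult * float(np.median(baseline_map))

    ny, nx = img.shape
    k_img = np.full((ny, nx), np.nan)
    ok = np.zeros((ny, nx), dtype=bool)
    for iy in range(ny):
        for ix in range(nx):
            if img[iy, ix] < floor:
                continue
            fit = fit_decay(work.data[:, iy, ix], work.config)
            if fit.success:
                k_img[iy, ix] = fit.k
                ok[iy, ix] = True
    return RateMap(k_image=k_img, success_mask=ok, config=stack.config,
                   temperature=stack.temperature)


def average_vessel_trace(stack: TraceStack, mask: np.ndarray) -> np.ndarray:
    """Time-sample-wise mean trace over a vessel mask (average-then-fit)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.data.shape[1:]:
        raise ValueError("mask shape does not match stack grid")
    if not mask.any():
        raise ValueError("mask is empty")
    return stack.data[:, mask].mean(axis=1)
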