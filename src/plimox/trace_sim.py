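"""Time-resolved phosphorescence trace and raster-acquisition simulation.

Each raster pixel records a short pulsed-excitation plateau followed by a
phosphorescence decay captured for the rest of the pixel dwell.  The
noiseless decay, measured from the end of the excitation pulse, is

    I(t) = I_C * exp(-(k_Ox2P + k_OCT) * t) + I_SS + I_PMT

where k_Ox2P = 1/tau(pO2, T) comes from the inverse oxygen calibration,
k_OCT is the extra apparent decay rate contributed by continuous-wave
visible-light background excitation during simultaneous OCT imaging
(zero for lifetime-only imaging), I_SS is the steady-state phosphorescence
driven by that CW light, and I_PMT is the constant detector baseline.
With no CW source the model reduces to I_C*exp(-k*t) + I_PMT.

The simulator is the package's ground-truth generator: everything the
fitting pipeline is tested against comes from here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .oximetry import CalibrationConstants, lifetime_from_po2
from .phantom import Phantom, SectioningModel, render_scene

__all__ = [
    "AcquisitionConfig",
    "TraceStack",
    "simulate_trace",
    "simulate_acquisition",
    "simulate_pair",
]

NOISE_MODELS = ("none", "gaussian", "poisson_gaussian")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Raster-acquisition timing, gain, baseline and noise parameters.

    Defaults mirror the imaging protocol: 10 us excitation pulse within a
    200 us pixel dwell on a 256x256 raster.  The digitizer rate is a free
    choice (5 MHz default, i.e. 1000 samples per pixel, at least ten
    samples per lifetime at the fastest physiological decays).

    ``noise_a``/``noise_b`` parameterize shot-like Gaussian noise with
    variance a + b*mean; ``guard_interval`` excludes early post-pulse
    samples from fitting.
    """

    grid_shape: tuple = (256, 256)
    pixel_dwell: float = 200e-6          # s
    pulse_duration: float = 10e-6        # s
    sampling_rate: float = 5e6           # Hz
    excitation_gain: float = 1.0         # plateau / decay amplitude scale
    pmt_baseline: float = 0.05           # I_PMT, intensity units
    noise_model: str = "gaussian"
    noise_a: float = 1e-5                # variance floor
    noise_b: float = 2e-4                # variance per unit mean
    k_oct: float = 0.0                   # s^-1; CW background excitation rate
    steady_state_scale: float = 1.0      # scales I_SS
    guard_interval: float = 2e-6         # s after pulse end, excluded from fits

    def __post_init__(self) -> None:
        if self.pulse_duration >= self.pixel_dwell:
            raise ValueError("pulse_duration must be shorter than pixel_dwell")
        if self.sampling_rate * self.pixel_dwell < 20:
            raise ValueError("need at least 20 samples per pixel dwell")
        if self.k_oct < 0:
            raise ValueError("k_oct must be non-negative")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {NOISE_MODELS}")

    @property
    def n_time(self) -> int:
        return int(round(self.pixel_dwell * self.sampling_rate))

    @property
    def time_axis(self) -> np.ndarray:
        """Sample times within the dwell, seconds from pulse start."""
        return np.arange(self.n_time) / self.sampling_rate

    @property
    def n_pulse_samples(self) -> int:
        return int(round(self.pulse_duration * self.sampling_rate))

    def with_k_oct(self, k_oct: float) -> "AcquisitionConfig":
        return replace(self, k_oct=k_oct)


@dataclass
class TraceStack:
    """Time-resolved intensity cube (n_time, ny, nx) with timing metadata."""

    data: np.ndarray
    config: AcquisitionConfig
    temperature: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.data.shape[0] != self.config.n_time:
            raise ValueError("data time dimension does not match config")
        if self.data.shape[1:] != tuple(self.config.grid_shape):
            raise ValueError("data grid does not match config grid_shape")

    @property
    def time_axis(self) -> np.ndarray:
        return self.config.time_axis


def _mean_trace(true_po2, temperature, weight, config, cal):
    """Noiseless per-pixel trace; inputs may be scalars or (ny, nx) maps."""
    t = config.time_axis
    po2 = np.atleast_1d(np.asarray(true_po2, dtype=float))
    w = np.atleast_1d(np.asarray(weight, dtype=float))
    po2, w = np.broadcast_arrays(po2, w)
    shape = po2.shape

    k = np.empty(shape)
    vessel = w > 0
    if vessel.any():
        k[vessel] = 1.0 / np.asarray(
            lifetime_from_po2(po2[vessel], temperature, cal))
    k[~vessel] = 1.0  # irrelevant: amplitude is zero there

    i_c = config.excitation_gain * w
    k_tot = k + config.k_oct
    if config.k_oct > 0:
        i_ss = i_c * config.k_oct / k_tot * config.steady_state_scale
    else:
        i_ss = np.zeros(shape)

    out = np.empty((t.size,) + shape)
    in_pulse = t < config.pulse_duration
    out[in_pulse] = i_c + i_ss + config.pmt_baseline
    td = t[~in_pulse] - config.pulse_duration
    out[~in_pulse] = (i_c[None] * np.exp(-np.multiply.outer(td, k_tot))
                      + i_ss[None] + config.pmt_baseline)
    return out


def _add_noise(mean, config, rng=None, normals=None):
    """Apply the configured noise model.

    ``normals`` lets callers share one standard-normal draw between two
    simulations (used by simulate_pair so the with/without-CW members see
    the same noise stream).
    """
    if config.noise_model == "none":
        return mean.copy()
    if config.noise_model == "gaussian":
        sigma = np.sqrt(config.noise_a
                        + config.noise_b * np.clip(mean, 0.0, None))
        if normals is None:
            normals = rng.standard_normal(mean.shape)
        return mean + sigma * normals
    # poisson_gaussian: scaled photon counting plus additive readout noise
    gain = max(config.noise_b, 1e-12)
    counts = rng.poisson(np.clip(mean, 0.0, None) / gain) * gain
    return counts + rng.normal(0.0, np.sqrt(config.noise_a), mean.shape)


def simulate_trace(true_po2: float, temperature: float, weight: float,
                   config: AcquisitionConfig,
                   rng: np.random.Generator | None = None,
                   cal: CalibrationConstants | None = None) -> np.ndarray:
    """Simulate one pixel's time-resolved trace.

    ``weight`` in [0, 1] is the depth-sectioning weight scaling the
    collected phosphorescence; weight 0 (or no vessel) gives a
    baseline-only trace.
    """
    if true_po2 < 0:
        raise ValueError("true_po2 must be non-negative")
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must lie in [0, 1]")
    cal = cal or CalibrationConstants()
    mean = _mean_trace(true_po2, temperature, weight, config, cal)[:, 0]
    if config.noise_model == "none":
        return mean
    if rng is None:
        raise ValueError("rng required for noisy simulation")
    return _add_noise(mean, config, rng=rng)


def simulate_acquisition(phantom: Phantom, sectioning: SectioningModel,
                         config: AcquisitionConfig, seed: int = 0,
                         cal: CalibrationConstants | None = None,
                         _normals: np.ndarray | None = None) -> TraceStack:
    """Simulate a full raster acquisition of a phantom.

    Renders the scene at the sectioning model's focal depth, then fills
    every pixel with a simulated trace.  Deterministic per seed.
    """
    if tuple(phantom.grid_shape) != tuple(config.grid_shape):
        raise ValueError("phantom grid does not match acquisition grid")
    cal = cal or CalibrationConstants()
    _, weight, po2 = render_scene(phantom, sectioning)
    po2 = np.where(np.isnan(po2), 0.0, po2)
    mean = _mean_trace(po2, phantom.temperature, weight, config, cal)
    if config.noise_model == "none":
        data = mean
    else:
        rng = np.random.default_rng(seed)
        data = _add_noise(mean, config, rng=rng, normals=_normals)
    return TraceStack(data=data, config=config,
                      temperature=phantom.temperature, seed=seed)


def simulate_pair(phantom: Phantom, sectioning: SectioningModel,
                  config: AcquisitionConfig, k_oct: float, seed: int = 0,
                  cal: CalibrationConstants | None = None):
    """Simulate matched acquisitions without and with CW background light.

    Emulates collecting lifetime-image pairs with and without the OCT
    source in rapid succession: identical scene and identical noise
    stream, differing only in the CW excitation term.  Returns
    ``(stack_plim_only, stack_simultaneous)``.
    """
    if k_oct < 0:
        raise ValueError("k_oct must be non-negative")
    normals = None
    if config.noise_model == "gaussian":
        rng = np.random.default_rng(seed)
        normals = rng.standard_normal((config.n_time,) + tuple(config.grid_shape))
    plim = simulate_acquisition(phantom, sectioning, config.with_k_oct(0.0),
                                seed=seed, cal=cal, _normals=normals)
    simul = simulate_acquisition(phantom, sectioning, config.with_k_oct(k_oct),
                                 seed=seed, cal=cal, _normals=normals)
    return plim, simul
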