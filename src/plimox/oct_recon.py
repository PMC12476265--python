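"""Minimal spectral-domain visible-light OCT processing chain.

The spectrometer samples the interferogram uniformly in wavenumber over a
500.07-635.36 nm band, so a single inverse FFT along k yields a complex
A-scan.  The chain implemented here is: background subtraction, application
of a supplied dispersion-compensation phase, optional apodization, FFT,
retina-surface flattening, B-scan averaging, en face projection, Doppler
phase from adjacent A-lines, and the 10-to-1 A-line averaging used when
OCT lines are interleaved with lifetime pixels.  A synthetic interferogram
generator provides matched ground truth for all of it.

Only the *application* of a dispersion phase is in scope; estimating one
from data is a separate problem not addressed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpectrometerConfig",
    "reconstruct",
    "doppler",
    "flatten",
    "average_bscans",
    "en_face",
    "average_alines",
    "alines_per_pixel",
    "simulate_interferogram",
]


@dataclass(frozen=True)
class SpectrometerConfig:
    """Linear-in-k spectrometer geometry.

    Wavelength band defaults to the instrument's 500.07-635.36 nm; the
    detector pixel count is a free choice (2048 default).  ``n_medium``
    is the refractive index used for optical-path/physical-depth
    conversion (1.35, vitreous-like).
    """

    n_pixels: int = 2048
    wavelength_min: float = 500.07e-9    # m
    wavelength_max: float = 635.36e-9    # m
    n_medium: float = 1.35
    line_rate: float = 50e3              # Hz

    def __post_init__(self) -> None:
        if self.wavelength_min >= self.wavelength_max:
            raise ValueError("wavelength_min must be below wavelength_max")
        if self.n_pixels < 16:
            raise ValueError("n_pixels too small")

    @property
    def k_axis(self) -> np.ndarray:
        """Angular wavenumber samples (rad/m), ascending, uniform."""
        k_min = 2 * np.pi / self.wavelength_max
        k_max = 2 * np.pi / self.wavelength_min
        return np.linspace(k_min, k_max, self.n_pixels)

    @property
    def dk(self) -> float:
        k = self.k_axis
        return float(k[1] - k[0])

    @property
    def center_wavelength(self) -> float:
        """Wavelength of the central wavenumber sample (m)."""
        return float(2 * np.pi / self.k_axis.mean())

    @property
    def axial_pitch(self) -> float:
        """Physical depth per FFT bin (m): pi / (N * dk * n_medium)."""
        return float(np.pi / (self.n_pixels * self.dk * self.n_medium))

    @property
    def max_depth(self) -> float:
        """Nyquist-limited unambiguous physical depth (m)."""
        return self.axial_pitch * (self.n_pixels // 2)


def reconstruct(frames: np.ndarray, background: np.ndarray,
                dispersion_phase: np.ndarray | None = None,
                config: SpectrometerConfig | None = None,
                window: np.ndarray | None = None) -> np.ndarray:
    """Spectral frames -> complex A-scans.

    Per frame: subtract the mean (background) spectrum, multiply by
    exp(i * dispersion_phase), apply the apodization window if given
    (default none), inverse-FFT along k, and keep the positive-depth
    half-space.

    Parameters
    ----------
    frames : (..., n_pixels) real array
    background : (n_pixels,) mean reference spectrum
    dispersion_phase : (n_pixels,) radians, or None for zero
    """
    config = config or SpectrometerConfig()
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[-1]
    if n != config.n_pixels:
        raise ValueError("frame length does not match spectrometer pixels")
    background = np.asarray(background, dtype=float)
    if background.shape != (n,):
        raise ValueError("background length mismatch")
    sig = (frames - background).astype(complex)
    if dispersion_phase is not None:
        phase = np.asarray(dispersion_phase, dtype=float)
        if phase.shape != (n,):
            raise ValueError("dispersion phase length mismatch")
        sig = sig * np.exp(1j * phase)
    if window is not None:
        sig = sig * np.asarray(window)
    # forward FFT (normalized) so the positive-depth peak carries the
    # +2 n k z phase: adjacent-A-line phase shifts then follow the usual
    # +4 pi n dz / lambda_c Doppler convention
    ascan = np.fft.fft(sig, axis=-1) / n
    return ascan[..., : n // 2]


def doppler(volume: np.ndarray) -> np.ndarray:
    """Phase shift between adjacent A-lines, wrapped to (-pi, pi].

    ``volume`` is a complex A-scan stack shaped (n_alines, n_z) or
    (n_positions, n_repeats, n_z); with repeats, adjacent-line products are
    averaged (complex mean) within each position before taking the angle,
    which is the phase-noise-optimal estimator.
    """
    v = np.asarray(volume)
    if v.ndim == 2:
        if v.shape[0] < 2:
            raise ValueError("need at least 2 A-lines")
        prod = v[1:] * np.conj(v[:-1])
        return np.angle(prod)
    if v.ndim == 3:
        if v.shape[1] < 2:
            raise ValueError("need at least 2 repeats per position")
        prod = (v[:, 1:] * np.conj(v[:, :-1])).mean(axis=1)
        return np.angle(prod)
    raise ValueError("volume must be 2-D or 3-D")


def flatten(bscan: np.ndarray, threshold_frac: float = 0.5,
            smooth: int = 3, target_row: int | None = None):
    """Align the retinal surface across A-lines of a magnitude B-scan.

    Surface per A-line = first axial index whose (axially median-smoothed)
    magnitude exceeds ``threshold_frac`` of that A-line's maximum; each
    column is circularly shifted so all surfaces land on a common row
    (the median surface by default).  Returns
    ``(flattened, surface, shifts)``; columns with no detectable surface
    are flagged with surface -1 and left unshifted.
    """
    from scipy.ndimage import median_filter

    b = np.asarray(bscan, dtype=float)
    if b.ndim != 2 or b.size == 0:
        raise ValueError("bscan must be a non-empty 2-D (z, x) array")
    nz, nx = b.shape
    sm = median_filter(b, size=(smooth, 1)) if smooth > 1 else b
    surface = np.full(nx, -1, dtype=int)
    for ix in range(nx):
        col = sm[:, ix]
        peak = col.max()
        if peak <= 0:
            continue
        above = np.nonzero(col >= threshold_frac * peak)[0]
        if above.size:
            surface[ix] = above[0]
    found = surface >= 0
    if not found.any():
        warnings.warn("no surface detected in any A-line", stacklevel=2)
        return b.copy(), surface, np.zeros(nx, dtype=int)
    if target_row is None:
        target_row = int(round(np.median(surface[found])))
    shifts = np.where(found, target_row - surface, 0)
    out = np.empty_like(b)
    for ix in range(nx):
        out[:, ix] = np.roll(b[:, ix], shifts[ix])
    return out, surface, shifts


def average_bscans(stack: np.ndarray, n: int | None = None) -> np.ndarray:
    """Pixel-wise mean of the first ``n`` (flattened, magnitude) B-scans."""
    s = np.asarray(stack)
    if s.ndim != 3:
        raise ValueError("stack must be (n_bscans, z, x)")
    n = s.shape[0] if n is None else n
    if n > s.shape[0] or n < 1:
        raise ValueError("n out of range")
    return np.abs(s[:n]).mean(axis=0)


def en_face(volume: np.ndarray, depth_range: tuple,
            mode: str = "mean") -> np.ndarray:
    """Project a magnitude volume (z first axis) over an axial slab."""
    v = np.abs(np.asarray(volume))
    lo, hi = depth_range
    if not 0 <= lo < hi <= v.shape[0]:
        raise ValueError("empty or out-of-bounds depth range")
    slab = v[lo:hi]
    if mode == "mean":
        return slab.mean(axis=0)
    if mode == "max":
        return slab.max(axis=0)
    raise ValueError("mode must be 'mean' or 'max'")


def average_alines(volume: np.ndarray, group: int = 10,
                   mode: str = "complex") -> np.ndarray:
    """Combine groups of consecutive A-lines into one.

    Used for simultaneous imaging, where the OCT camera collects several
    lines per lifetime pixel (10 at a 50 kHz trigger with 200 us dwell)
    that are then merged.  Complex averaging (default) preserves phase for
    Doppler use; magnitude averaging is available as ``mode="magnitude"``.
    A non-divisible remainder is dropped with a warning.
    """
    v = np.asarray(volume)
    if v.ndim != 2:
        raise ValueError("volume must be (n_alines, n_z)")
    n = v.shape[0]
    n_keep = (n // group) * group
    if n_keep == 0:
        raise ValueError("fewer A-lines than one group")
    if n_keep < n:
        warnings.warn(f"dropping {n - n_keep} trailing A-line(s) "
                      "not filling a group", stacklevel=2)
    grouped = v[:n_keep].reshape(n // group, group, v.shape[1])
    if mode == "complex":
        return grouped.mean(axis=1)
    if mode == "magnitude":
        return np.abs(grouped).mean(axis=1)
    raise ValueError("mode must be 'complex' or 'magnitude'")


def alines_per_pixel(line_rate: float, pixel_dwell: float) -> int:
    """OCT A-lines collected during one lifetime pixel dwell."""
    if line_rate <= 0 or pixel_dwell <= 0:
        raise ValueError("line_rate and pixel_dwell must be positive")
    return int(round(line_rate * pixel_dwell))


def simulate_interferogram(reflectors, motion: float = 0.0,
                           config: SpectrometerConfig | None = None,
                           n_frames: int = 1,
                           dispersion_phase: np.ndarray | None = None,
                           dc_level: float = 10.0,
                           noise_sigma: float = 0.0,
                           rng: np.random.Generator | None = None) -> np.ndarray:
    """Synthetic k-linear spectral frames for a set of point reflectors.

    samples(k) = DC + sum_j r_j cos(2 n k z_j(frame) + phi_disp(k)) + noise,
    with z_j(frame) = z_j + frame * motion (physical depth, metres).

    Returns a (n_frames, n_pixels) array; feed it to :func:`reconstruct`
    with ``background=np.full(n_pixels, dc_level)`` (or the frame mean).
    """
    config = config or SpectrometerConfig()
    k = config.k_axis
    phase = (np.zeros_like(k) if dispersion_phase is None
             else np.asarray(dispersion_phase, dtype=float))
    if phase.shape != k.shape:
        raise ValueError("dispersion phase length mismatch")
    frames = np.full((n_frames, k.size), float(dc_level))
    for fi in range(n_frames):
        for depth, refl in reflectors:
            z = depth + fi * motion
            if not 0 <= z < config.max_depth:
                raise ValueError(
                    f"reflector depth {z:.3e} m outside the unambiguous "
                    f"range [0, {config.max_depth:.3e})")
            frames[fi] += refl * np.cos(2 * config.n_medium * k * z + phase)
    if noise_sigma > 0:
        if rng is None:
            raise ValueError("rng required for noisy simulation")
        frames += rng.normal(0.0, noise_sigma, frames.shape)
    return frames
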