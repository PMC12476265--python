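"""Lifetime-to-oxygen conversion for the Oxyphor 2P phosphorescent probe.

Molecular oxygen quenches the triplet state of the probe, so the
phosphorescence decay rate rises (the lifetime shortens) with oxygen
partial pressure.  The conversion used here is the probe's published
Stern-Volmer-like calibration

    pO2(tau, T) = (P10 + beta*T) * tau**p - (P20 + gamma*T)

with temperature-dependent slope and offset terms.  The calibration is
analytically invertible, which is what the trace simulator uses to inject
a decay rate for a chosen ground-truth pO2.

Also provided: per-pixel pO2 maps from fitted rate maps, a thresholding
vessel-segmentation stand-in, and per-vessel statistics following the
average-the-traces-then-fit convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label

__all__ = [
    "CalibrationConstants",
    "PO2Map",
    "VesselStats",
    "po2_from_lifetime",
    "lifetime_from_po2",
    "po2_map",
    "segment_vessels_threshold",
    "vessel_stats",
]


@dataclass(frozen=True)
class CalibrationConstants:
    """Oxyphor 2P calibration constants.

    Units: ``p`` unitless (negative), ``P10`` mmHg s^-p, ``beta``
    mmHg s^-p / degC, ``P20`` mmHg, ``gamma`` mmHg / degC.
    """

    p: float = -1.265777
    P10: float = 3.06907e-4
    beta: float = -4.6205e-6
    P20: float = 114.4061
    gamma: float = -1.60147

    def __post_init__(self) -> None:
        if self.p >= 0:
            raise ValueError("calibration exponent p must be negative")

    def slope(self, temperature: float) -> float:
        """P10 + beta*T, the temperature-corrected pre-factor."""
        return self.P10 + self.beta * temperature

    def offset(self, temperature: float) -> float:
        """P20 + gamma*T, the temperature-corrected offset."""
        return self.P20 + self.gamma * temperature


def po2_from_lifetime(tau, temperature: float, cal: CalibrationConstants | None = None):
    """Oxygen partial pressure (mmHg) from phosphorescence lifetime (s).

    Negative results (possible for very long lifetimes under noise) are
    returned as-is with a warning; clipping, if wanted, is a display-level
    choice.

    Parameters
    ----------
    tau : float or array
        Lifetime in seconds, > 0.
    temperature : float
        Blood temperature in degC.
    cal : CalibrationConstants, optional
        Calibration constants; the packaged Oxyphor 2P set by default.
    """
    cal = cal or CalibrationConstants()
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("lifetime must be positive")
    out = cal.slope(temperature) * tau**cal.p - cal.offset(temperature)
    if np.any(out < 0):
        warnings.warn("computed pO2 below 0 mmHg (long lifetime); not clipped",
                      stacklevel=2)
    return out if out.ndim else float(out)


def lifetime_from_po2(po2, temperature: float, cal: CalibrationConstants | None = None):
    """Phosphorescence lifetime (s) for a given pO2 (mmHg); inverse calibration.

    Strictly decreasing in pO2: more oxygen, faster quenching, shorter
    lifetime.
    """
    cal = cal or CalibrationConstants()
    po2 = np.asarray(po2, dtype=float)
    num = po2 + cal.offset(temperature)
    if np.any(num <= 0):
        raise ValueError("po2 + P20 + gamma*T must be positive")
    out = (num / cal.slope(temperature)) ** (1.0 / cal.p)
    return out if out.ndim else float(out)


@dataclass
class PO2Map:
    """Per-pixel oxygen tension image derived from a fitted rate map.

    ``po2_image`` is NaN wherever the source fit failed; ``no_data`` is the
    matching boolean mask.  The temperature used for the conversion is
    recorded so maps remain self-describing.
    """

    po2_image: np.ndarray
    temperature: float
    no_data: np.ndarray
    calibration: CalibrationConstants = field(default_factory=CalibrationConstants)

    def clipped(self) -> np.ndarray:
        """Display copy with negative pO2 clipped to 0."""
        return np.clip(self.po2_image, 0.0, None)


def po2_map(rate_map, temperature: float,
            cal: CalibrationConstants | None = None) -> PO2Map:
    """Convert a fitted rate-constant map into an oxygen tension map.

    Each successful pixel's lifetime 1/k is pushed through the calibration;
    failed pixels propagate as NaN.
    """
    cal = cal or CalibrationConstants()
    k = np.asarray(rate_map.k_image, dtype=float)
    ok = np.asarray(rate_map.success_mask, dtype=bool) & np.isfinite(k) & (k > 0)
    po2 = np.full(k.shape, np.nan)
    if ok.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            po2[ok] = po2_from_lifetime(1.0 / k[ok], temperature, cal)
    return PO2Map(po2_image=po2, temperature=temperature, no_data=~ok, calibration=cal)


def segment_vessels_threshold(intensity: np.ndarray, min_size: int = 8,
                              invert: bool = False) -> np.ndarray:
    """Global-threshold vessel segmentation stand-in.

    Otsu threshold on the intensity image, then connected components above
    ``min_size`` pixels.  This deliberately simple labeller exists so the
    pipeline runs without an external mask; phantom ground-truth labels and
    user-supplied masks bypass it.

    A blank (constant) image yields an empty labeling rather than an error.
    """
    img = np.asarray(intensity, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("intensity image must be finite")
    if invert:
        img = img.max() - img
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    thr = threshold_otsu(img)
    lab = _cc_label(img > thr, connectivity=2)
    counts = np.bincount(lab.ravel())
    keep = counts >= min_size
    keep[0] = False
    return _cc_label(keep[lab], connectivity=2).astype(np.int32)


@dataclass
class VesselStats:
    """Per-vessel and per-class pO2 summaries (average-trace-then-fit)."""

    per_vessel: "list[dict]"          # vessel_id, vessel_class, n_pixels, k, tau, po2, rss
    class_means: "dict[str, float]"   # unweighted mean of vessel pO2 per class
    temperature: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.per_vessel)


_CLASSES = ("arteriole", "venule", "capillary")


def vessel_stats(stack, labels: np.ndarray, classes: Mapping[int, str],
                 temperature: float,
                 cal: CalibrationConstants | None = None) -> VesselStats:
    """Average each labelled vessel's traces, fit once, convert to pO2.

    Averaging the raw traces before fitting (rather than averaging pixel
    fits) is the convention for vessel-level values: it raises SNR where a
    single decay rate is shared across the mask.

    Parameters
    ----------
    stack : TraceStack
    labels : integer label image, 0 = background
    classes : mapping vessel_id -> class name in {arteriole, venule, capillary}
    """
    from .plim_core import average_vessel_trace, fit_decay

    cal = cal or CalibrationConstants()
    labels = np.asarray(labels)
    if labels.shape != stack.data.shape[1:]:
        raise ValueError("label map shape does not match stack grid")
    ids = [int(v) for v in np.unique(labels) if v != 0]
    for vid in ids:
        if vid not in classes:
            raise KeyError(f"vessel id {vid} missing from classes map")
        if classes[vid] not in _CLASSES:
            raise ValueError(f"unknown vessel class {classes[vid]!r}")

    rows = []
    for vid in ids:
        mask = labels == vid
        trace = average_vessel_trace(stack, mask)
        fit = fit_decay(trace, stack.config)
        po2 = np.nan
        if fit.success:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                po2 = po2_from_lifetime(fit.tau, temperature, cal)
        rows.append({
            "vessel_id": vid,
            "vessel_class": classes[vid],
            "n_pixels": int(mask.sum()),
            "k": fit.k,
            "tau": fit.tau,
            "po2": po2,
            "rss": fit.rss,
        })
    class_means = {}
    for cls in _CLASSES:
        vals = [r["po2"] for r in rows
                if r["vessel_class"] == cls and np.isfinite(r["po2"])]
        if vals:
            class_means[cls] = float(np.mean(vals))
    return VesselStats(per_vessel=rows, class_means=class_means,
                       temperature=temperature)
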