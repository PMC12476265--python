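"""Background-excitation rate correction for simultaneous OCT + PLIM imaging.

The continuous-wave visible-light OCT beam weakly excites the oxygen probe
while lifetime traces are being recorded, adding a constant rate k_OCT to
every fitted decay rate: k_simul = k_native + k_OCT.  The correction
constant k_corr (= k_OCT) is estimated empirically by fitting vessel pairs
imaged with and without the CW source and regressing k_simul on k_native:
the intercept is k_corr and the slope should approach unity.

k_corr is specific to one illumination condition; change the CW power or
spectrum and it must be re-estimated.  KcorrFit therefore carries an
illumination tag, and applying a fit tagged for a different illumination
raises a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .plim_core import RateMap

__all__ = ["KPair", "KcorrFit", "estimate_kcorr", "correct_rate", "correct_map"]


@dataclass(frozen=True)
class KPair:
    """Fitted decay rates for one vessel with and without CW illumination."""

    vessel_id: int
    k_simul: float      # s^-1, with CW background
    k_native: float     # s^-1, without

    def __post_init__(self) -> None:
        # NaN members mark failed fits; they are dropped at regression time
        if self.k_simul <= 0 or self.k_native <= 0:
            raise ValueError("rate constants must be positive")
        if self.k_simul < self.k_native:
            warnings.warn(
                f"vessel {self.vessel_id}: k_simul < k_native "
                "(expected k_simul >= k_native; noise can invert the order)",
                stacklevel=2)


@dataclass(frozen=True)
class KcorrFit:
    """OLS fit of k_simul against k_native: intercept is the correction."""

    slope: float
    k_corr: float               # s^-1, the regression intercept
    r_squared: float
    n_pairs: int
    intercept_stderr: float
    slope_stderr: float
    illumination: str = "default"

    def intercept_ci(self, level: float = 0.95) -> tuple:
        """Two-sided confidence interval for the intercept."""
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.n_pairs - 2)
        half = tcrit * self.intercept_stderr
        return (self.k_corr - half, self.k_corr + half)


def estimate_kcorr(pairs: Sequence[KPair],
                   illumination: str = "default") -> KcorrFit:
    """Least-squares regression of simultaneous on native decay rates.

    The slope is left free; a slope far from the theoretical unity is
    reported with a warning, not an error, since the intercept remains the
    empirical correction either way.  Pairs with non-finite members are
    dropped (count noted in the warning).
    """
    clean = [p for p in pairs
             if np.isfinite(p.k_simul) and np.isfinite(p.k_native)]
    dropped = len(pairs) - len(clean)
    if dropped:
        warnings.warn(f"dropped {dropped} pair(s) with failed fits",
                      stacklevel=2)
    if len(clean) < 2:
        raise ValueError("need at least 2 valid pairs")
    x = np.array([p.k_native for p in clean])
    y = np.array([p.k_simul for p in clean])
    if np.ptp(x) == 0:
        raise ValueError("degenerate pairs: all k_native equal")
    res = stats.linregress(x, y)
    if abs(res.slope - 1.0) > 0.2:
        warnings.warn(f"regression slope {res.slope:.3f} far from unity",
                      stacklevel=2)
    return KcorrFit(slope=float(res.slope), k_corr=float(res.intercept),
                    r_squared=float(res.rvalue**2), n_pairs=len(clean),
                    intercept_stderr=float(res.intercept_stderr),
                    slope_stderr=float(res.stderr),
                    illumination=illumination)


def correct_rate(k_simul: float, k_corr: float) -> float:
    """Native decay rate from a simultaneous-imaging fit: k_simul - k_corr.

    Returns NaN (with a warning) when the simultaneous rate does not
    exceed the correction — such a rate carries no native-decay
    information.
    """
    if k_simul <= k_corr:
        warnings.warn("k_simul <= k_corr: corrected rate undefined, "
                      "returning no-data", stacklevel=2)
        return float("nan")
    return k_simul - k_corr


def correct_map(rate_map: RateMap, k_corr: float,
                fit: KcorrFit | None = None,
                illumination: str = "default") -> RateMap:
    """Subtract the background-excitation rate from a fitted rate map.

    Pixels whose rate does not exceed k_corr become no-data.  When the
    KcorrFit used to derive k_corr is supplied, its illumination tag is
    checked against the map's.
    """
    if fit is not None and fit.illumination != illumination:
        warnings.warn(
            f"k_corr estimated under illumination {fit.illumination!r} "
            f"applied to {illumination!r}: recalibration recommended",
            stacklevel=2)
    k = np.asarray(rate_map.k_image, dtype=float)
    ok = np.asarray(rate_map.success_mask, dtype=bool) & (k > k_corr)
    corrected = np.where(ok, k - k_corr, np.nan)
    return RateMap(k_image=corrected, success_mask=ok,
                   config=rate_map.config, temperature=rate_map.temperature)
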