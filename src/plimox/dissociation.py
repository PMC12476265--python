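"""Hemoglobin oxygen-dissociation analysis.

Relates measured intravascular pO2 to hemoglobin oxygen saturation:

* Kelman environmental correction factor
  f = 10^[-0.024 (T - 37) + 0.40 (pH - 7.40) - 0.06 (log10 pCO2 - log10 40)],
  multiplying a measured pO2 onto the standard-state (T = 37 degC,
  pH = 7.40, pCO2 = 40 mmHg) dissociation curve.  The exponent separates
  into a temperature-only term f_T, computable from the measured body
  temperature, and a residual f_pH_pCO2 covering the two quantities that
  cannot be measured noninvasively in the retina.
* Hill model sO2 = pO2^n / (pO2^n + p50^n) with C57BL/6 mouse defaults
  n = 2.59, p50 = 40.2 mmHg.
* A one-parameter least-squares fit of f_pH_pCO2 against an oxygen-challenge
  series of (systemic sO2, temperature-corrected arterial pO2) pairs.
* Arteriovenous difference metrics (pO2, sO2, oxygen content) and oxygen
  extraction fractions, plus the probe blood-concentration dose estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "KelmanEnvironment",
    "HillModel",
    "ChallengeRecord",
    "OxygenContentParams",
    "AVMetrics",
    "kelman_f",
    "kelman_f_temperature",
    "hill_so2",
    "hill_po2",
    "fit_f_ph_pco2",
    "av_metrics",
    "blood_concentration",
]

STANDARD_ENVIRONMENT = (37.0, 7.40, 40.0)


@dataclass(frozen=True)
class KelmanEnvironment:
    """Blood environment for the dissociation correction."""

    temperature: float = 37.0    # degC
    pH: float = 7.40
    pCO2: float = 40.0           # mmHg

    def __post_init__(self) -> None:
        if self.pCO2 <= 0:
            raise ValueError("pCO2 must be positive")


@dataclass(frozen=True)
class HillModel:
    """Hill dissociation curve; defaults for C57BL/6 mouse hemoglobin."""

    n: float = 2.59
    p50: float = 40.2            # mmHg

    def __post_init__(self) -> None:
        if self.n <= 0 or self.p50 <= 0:
            raise ValueError("Hill parameters must be positive")


@dataclass(frozen=True)
class ChallengeRecord:
    """One oxygen-challenge state for a subject.

    ``systemic_so2`` is the pulse-oximeter arterial saturation (fraction);
    the pO2 fields are vessel-class averages from the lifetime maps.
    """

    systemic_so2: float
    arterial_po2: float          # mmHg
    venous_po2: float | None = None
    capillary_po2: float | None = None
    temperature: float = 36.7    # degC
    subject: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.systemic_so2 <= 1.0:
            raise ValueError("systemic_so2 must lie in (0, 1]")
        if self.arterial_po2 <= 0:
            raise ValueError("arterial_po2 must be positive")


@dataclass(frozen=True)
class OxygenContentParams:
    """Coefficients of blood oxygen content.

    cO2 = binding_capacity * hb * sO2 + solubility * pO2, in mL O2 / dL.
    Defaults are standard physiology values (1.36 mL O2 per g Hb,
    0.0031 mL O2 / dL / mmHg dissolved, 15 g/dL hemoglobin); all three are
    configurable and recorded in output provenance.
    """

    hb_concentration: float = 15.0    # g/dL
    binding_capacity: float = 1.36    # mL O2 / g Hb
    solubility: float = 0.0031        # mL O2 / dL / mmHg

    def __post_init__(self) -> None:
        if min(self.hb_concentration, self.binding_capacity,
               self.solubility) <= 0:
            raise ValueError("all oxygen-content coefficients must be positive")

    def content(self, so2, po2):
        return (self.binding_capacity * self.hb_concentration * np.asarray(so2)
                + self.solubility * np.asarray(po2))


def kelman_f_temperature(temperature) -> float:
    """Temperature-only component f_T = 10^(-0.024 (T - 37))."""
    t = np.asarray(temperature, dtype=float)
    out = 10.0 ** (-0.024 * (t - 37.0))
    return out if out.ndim else float(out)


def kelman_f(env: KelmanEnvironment) -> tuple:
    """Kelman correction factor and its two components.

    Returns ``(f, f_T, f_pH_pCO2)`` with f = f_T * f_pH_pCO2 by exponent
    additivity; f_pH_pCO2 is exactly 1 at the standard pH and pCO2.
    """
    f_t = kelman_f_temperature(env.temperature)
    f_ph_pco2 = 10.0 ** (0.40 * (env.pH - 7.40)
                         - 0.06 * (np.log10(env.pCO2) - np.log10(40.0)))
    return f_t * f_ph_pco2, f_t, float(f_ph_pco2)


def hill_so2(po2, model: HillModel | None = None):
    """Hemoglobin saturation (fraction) at a given pO2 (mmHg)."""
    model = model or HillModel()
    p = np.asarray(po2, dtype=float)
    if np.any(p < 0):
        raise ValueError("po2 must be non-negative")
    x = p**model.n
    out = x / (x + model.p50**model.n)
    return out if out.ndim else float(out)


def hill_po2(so2, model: HillModel | None = None):
    """pO2 (mmHg) at a given saturation (fraction); inverse Hill curve."""
    model = model or HillModel()
    s = np.asarray(so2, dtype=float)
    if np.any((s < 0) | (s >= 1)):
        raise ValueError("so2 must lie in [0, 1)")
    out = model.p50 * (s / (1.0 - s)) ** (1.0 / model.n)
    return out if out.ndim else float(out)


def fit_f_ph_pco2(records: Sequence[ChallengeRecord],
                  model: HillModel | None = None,
                  bounds: tuple = (0.5, 2.0)) -> float:
    """Fit the unmeasurable pH/pCO2 correction from an oxygen challenge.

    Minimizes sum_i [sO2_i - Hill(f * f_T(T_i) * pO2_a,i)]^2 over the single
    scalar f = f_pH_pCO2, with each arterial pO2 first temperature-corrected
    by its own measured f_T.  Bounded scalar search; the physiological
    bracket (0.5, 2.0) comfortably contains plausible pH/pCO2 deviations.
    """
    model = model or HillModel()
    if len(records) < 2:
        raise ValueError("need at least 2 challenge records")
    so2 = np.array([r.systemic_so2 for r in records])
    if np.ptp(so2) == 0:
        raise ValueError("degenerate challenge: all sO2 identical")
    po2_tcorr = np.array([kelman_f_temperature(r.temperature) * r.arterial_po2
                          for r in records])

    def loss(f):
        return float(((so2 - hill_so2(f * po2_tcorr, model)) ** 2).sum())

    res = minimize_scalar(loss, bounds=bounds, method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x)


@dataclass(frozen=True)
class AVMetrics:
    """Arteriovenous oxygen differences and extraction fractions."""

    d_po2: float        # corrected arterial - venous pO2, mmHg
    so2_a: float
    so2_v: float
    d_so2: float
    co2_a: float        # mL O2 / dL
    co2_v: float
    d_co2: float
    oef_so2: float      # (sO2_a - sO2_v) / sO2_a
    oef_co2: float


def av_metrics(record: ChallengeRecord, model: HillModel | None = None,
               content: OxygenContentParams | None = None,
               f_total: float = 1.0) -> AVMetrics:
    """Arteriovenous difference metrics for one challenge state.

    The same combined correction factor ``f_total`` (= f_T * f_pH_pCO2)
    multiplies the arterial and the venous pO2 before any Hill or content
    evaluation, mirroring how the venous values are corrected with the
    arteriole-derived factor.
    """
    model = model or HillModel()
    content = content or OxygenContentParams()
    if record.venous_po2 is None:
        raise ValueError("record has no venous pO2")
    a = f_total * record.arterial_po2
    v = f_total * record.venous_po2
    if a <= 0:
        raise ValueError("non-positive corrected arterial pO2")
    so2_a = hill_so2(a, model)
    so2_v = hill_so2(v, model)
    co2_a = float(content.content(so2_a, a))
    co2_v = float(content.content(so2_v, v))
    return AVMetrics(
        d_po2=a - v,
        so2_a=so2_a, so2_v=so2_v, d_so2=so2_a - so2_v,
        co2_a=co2_a, co2_v=co2_v, d_co2=co2_a - co2_v,
        oef_so2=(so2_a - so2_v) / so2_a,
        oef_co2=(co2_a - co2_v) / co2_a,
    )


def blood_concentration(dose_volume: float, dose_concentration: float,
                        body_mass: float, blood_per_mass: float) -> float:
    """Probe concentration in blood after an intravascular bolus (uM).

    C = V_dose * C_dose / (m_body * v_blood + V_dose): the dose dilutes
    into the estimated total blood volume plus the injected volume itself.

    Parameters
    ----------
    dose_volume : mL
    dose_concentration : uM
    body_mass : g
    blood_per_mass : mL blood per g body weight
    """
    if min(dose_volume, dose_concentration, body_mass, blood_per_mass) < 0:
        raise ValueError("all dose parameters must be non-negative")
    return (dose_volume * dose_concentration
            / (body_mass * blood_per_mass + dose_volume))
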