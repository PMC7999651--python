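"""One-compartment first-order absorption model with closed-form oracles.

Concentrations follow

    C(t) = D·ka / (V_F·(ka − ke)) · (exp(−ke·t) − exp(−ka·t)),   ke = CL_F/V_F

with dose D in mg (converted to ng), apparent volume V_F in L and
concentrations in ng/mL.  The closed forms for t_max, C_max and AUC make the
model its own oracle for the non-compartmental engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

MG_TO_NG = 1.0e6
L_TO_ML = 1.0e3


@dataclass(frozen=True)
class PkParams:
    """Subject-level apparent PK parameters."""

    cl_f_l_h: float
    v_f_l: float
    ka_per_h: float

    @property
    def ke_per_h(self) -> float:
        return self.cl_f_l_h / self.v_f_l

    def validate(self) -> None:
        if min(self.cl_f_l_h, self.v_f_l, self.ka_per_h) <= 0:
            raise ValueError("PK parameters must be positive")
        if math.isclose(self.ka_per_h, self.ke_per_h, rel_tol=1e-9):
            raise ValueError("ka equals ke: flip-flop degenerate model rejected")


def concentration(t, dose_mg: float, params: PkParams) -> np.ndarray:
    """Noise-free plasma concentration (ng/mL) at times ``t`` (h)."""
    params.validate()
    if dose_mg <= 0:
        raise ValueError("dose must be positive")
    t = np.asarray(t, dtype=float)
    ke = params.ke_per_h
    ka = params.ka_per_h
    pref = dose_mg * MG_TO_NG * ka / (params.v_f_l * L_TO_ML * (ka - ke))
    return pref * (np.exp(-ke * t) - np.exp(-ka * t))


def analytic_tmax(params: PkParams) -> float:
    ke, ka = params.ke_per_h, params.ka_per_h
    return math.log(ka / ke) / (ka - ke)


def analytic_cmax(dose_mg: float, params: PkParams) -> float:
    tmax = analytic_tmax(params)
    return float(concentration(tmax, dose_mg, params))


def analytic_auc_inf(dose_mg: float, params: PkParams) -> float:
    """AUC from zero to infinity, ng·h/mL (= D / CL_F unit-consistently)."""
    return dose_mg * MG_TO_NG / (params.cl_f_l_h * L_TO_ML)


def analytic_auc_t(t: float, dose_mg: float, params: PkParams) -> float:
    """AUC from zero to ``t`` by the antiderivative of the closed form."""
    ke, ka = params.ke_per_h, params.ka_per_h
    pref = dose_mg * MG_TO_NG * ka / (params.v_f_l * L_TO_ML * (ka - ke))
    return pref * ((1 - math.exp(-ke * t)) / ke - (1 - math.exp(-ka * t)) / ka)
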