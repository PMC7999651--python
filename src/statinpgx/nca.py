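"""Non-compartmental pharmacokinetic analysis of concentration–time profiles.

Implements the standard single-dose NCA parameter set: trapezoidal AUC to
the last quantifiable point, terminal rate constant from log-linear
regression over an automatically selected terminal window, extrapolated
AUC to infinity, C_max / t_max, half-life, and weight-normalised apparent
clearance and volume of distribution.

Conventions (deterministic throughout):

* below-LLOQ values before t_max are treated as 0; after t_max they are
  dropped and the profile ends at the last quantifiable point;
* λz windows are all suffixes of ≥ ``min_points`` positive concentrations
  starting strictly after t_max; the window with maximal adjusted R² wins,
  ties broken toward more points;
* t_max ties go to the earliest time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MG_TO_NG = 1.0e6

#: fraction of AUC∞ obtained by extrapolation above which a flag is raised
EXTRAP_FLAG_THRESHOLD = 0.2


@dataclass(frozen=True)
class ConcTimeProfile:
    """One subject's concentration–time curve.

    ``concentrations`` holds NaN for below-LLOQ (BQL) samples.  Times are in
    hours, concentrations in ng/mL.
    """

    subject_id: str
    schedule_id: str
    times: np.ndarray
    concentrations: np.ndarray
    lloq: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.shape != c.shape:
            raise ValueError("times and concentrations differ in length")
        if t.size and (np.diff(t) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if t.size and t[0] != 0.0:
            raise ValueError("first sample must be pre-dose (t = 0)")
        with np.errstate(invalid="ignore"):
            if np.nanmin(c, initial=0.0) < 0:
                raise ValueError("negative concentration")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)


@dataclass(frozen=True)
class LambdaZFit:
    ke: float                   # 1/h
    n_points: int
    r_squared_adj: float
    t_first: float
    t_last: float


@dataclass
class NcaResult:
    subject_id: str
    auc_t: float
    auc_inf: float
    extrap_frac: float
    cmax: float
    tmax: float
    ke: float
    t_half: float
    cl_f_w: float               # mL/(h·kg)
    vd_f_w: float               # mL/kg
    dose_mg: float
    weight_kg: float
    lambda_z: LambdaZFit | None = None
    flags: list[str] = field(default_factory=list)


class NcaError(ValueError):
    """Profile cannot support the requested NCA computation."""


def _retained(profile: ConcTimeProfile) -> tuple[np.ndarray, np.ndarray]:
    """Apply BQL policy; returns (times, concentrations) actually analysed."""
    t, c = profile.times, profile.concentrations.copy()
    quantifiable = ~np.isnan(c)
    if not quantifiable.any():
        raise NcaError("no quantifiable concentrations")
    imax = int(np.nanargmax(c))
    pre = np.arange(t.size) <= imax
    c[pre & ~quantifiable] = 0.0
    keep = pre | quantifiable
    last_q = np.max(np.nonzero(quantifiable))
    keep &= np.arange(t.size) <= last_q
    return t[keep], c[keep]


def auc_trapezoid(times: np.ndarray, concentrations: np.ndarray,
                  log_down: bool = False) -> float:
    """AUC by the trapezoidal rule over the supplied points.

    With ``log_down`` the log-linear rule is used on strictly decreasing
    positive segments (linear-up / log-down); the default is the plain
    linear trapezoid everywhere.
    """
    t = np.asarray(times, float)
    c = np.asarray(concentrations, float)
    if t.size < 2:
        raise NcaError("need at least two points for an AUC")
    if not log_down:
        return float(np.trapezoid(c, t))
    total = 0.0
    for i in range(t.size - 1):
        dt = t[i + 1] - t[i]
        c0, c1 = c[i], c[i + 1]
        if c1 < c0 and c1 > 0 and c0 > 0:
            total += dt * (c0 - c1) / math.log(c0 / c1)
        else:
            total += dt * (c0 + c1) / 2.0
    return float(total)


def fit_lambda_z(times: np.ndarray, concentrations: np.ndarray,
                 min_points: int = 3) -> LambdaZFit:
    """Terminal slope by OLS of ln C on t over the best terminal window.

    Candidate windows end at the last positive concentration and start
    strictly after t_max; the window maximising adjusted R² is selected,
    ties resolved toward more points.
    """
    t = np.asarray(times, float)
    c = np.asarray(concentrations, float)
    imax = int(np.argmax(c))
    pos = c > 0
    candidates = [i for i in range(imax + 1, t.size) if pos[i]]
    if len(candidates) < min_points:
        raise NcaError("fewer than min_points positive concentrations after tmax")
    best: LambdaZFit | None = None
    for start_pos in range(0, len(candidates) - min_points + 1):
        idx = candidates[start_pos:]
        x, y = t[idx], np.log(c[idx])
        n = len(idx)
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
        fit = LambdaZFit(ke=-float(slope), n_points=n, r_squared_adj=r2_adj,
                         t_first=float(x[0]), t_last=float(x[-1]))
        if best is None or r2_adj > best.r_squared_adj + 1e-12:
            best = fit
    assert best is not None
    if best.ke <= 0:
        raise NcaError("no terminal decline (non-negative slope)")
    return best


def extrapolate_auc(auc_t: float, c_last: float, ke: float) -> tuple[float, float]:
    """AUC∞ = AUC_t + C_last/ke and the extrapolated fraction."""
    if ke <= 0:
        raise NcaError("ke must be positive for extrapolation")
    if c_last < 0:
        raise NcaError("negative last concentration")
    tail = c_last / ke
    auc_inf = auc_t + tail
    return auc_inf, (tail / auc_inf if auc_inf > 0 else 0.0)


def derive_parameters(auc_inf: float, ke: float, dose_mg: float,
                      weight_kg: float) -> tuple[float, float, float]:
    """(Cl/F per kg in mL/(h·kg), Vd/F per kg in mL/kg, t½ in h)."""
    if min(auc_inf, ke, dose_mg, weight_kg) <= 0:
        raise NcaError("all inputs must be positive")
    cl_f_w = dose_mg * MG_TO_NG / (auc_inf * weight_kg)
    vd_f_w = cl_f_w / ke
    t_half = math.log(2) / ke
    return cl_f_w, vd_f_w, t_half


def run_nca(profile: ConcTimeProfile, dose_mg: float, weight_kg: float,
            min_points: int = 3, log_down: bool = False) -> NcaResult:
    """Full NCA for one profile."""
    t, c = _retained(profile)
    if t.size < 2:
        raise NcaError("fewer than two retained points")
    flags: list[str] = []
    imax = int(np.argmax(c))
    cmax = float(c[imax])
    tmax = float(t[imax])
    auc_t = auc_trapezoid(t, c, log_down=log_down)

    try:
        lam = fit_lambda_z(t, c, min_points=min_points)
    except NcaError as exc:
        flags.append(f"lambda_z_failed: {exc}")
        return NcaResult(profile.subject_id, auc_t=auc_t, auc_inf=math.nan,
                         extrap_frac=math.nan, cmax=cmax, tmax=tmax,
                         ke=math.nan, t_half=math.nan, cl_f_w=math.nan,
                         vd_f_w=math.nan, dose_mg=dose_mg,
                         weight_kg=weight_kg, flags=flags)

    c_last = float(c[c > 0][-1])
    auc_inf, extrap_frac = extrapolate_auc(auc_t, c_last, lam.ke)
    if extrap_frac > EXTRAP_FLAG_THRESHOLD:
        flags.append("extrapolation_above_20pct")
    cl_f_w, vd_f_w, t_half = derive_parameters(auc_inf, lam.ke, dose_mg, weight_kg)
    return NcaResult(profile.subject_id, auc_t=auc_t, auc_inf=auc_inf,
                     extrap_frac=extrap_frac, cmax=cmax, tmax=tmax,
                     ke=lam.ke, t_half=t_half, cl_f_w=cl_f_w, vd_f_w=vd_f_w,
                     dose_mg=dose_mg, weight_kg=weight_kg, lambda_z=lam,
                     flags=flags)


def nca_table(profiles: list[ConcTimeProfile], doses: dict, weights: dict,
              min_points: int = 3, log_down: bool = False) -> pd.DataFrame:
    """NCA for a cohort; one row per subject with diagnostics."""
    rows = []
    for p in profiles:
        r = run_nca(p, doses[p.subject_id], weights[p.subject_id],
                    min_points=min_points, log_down=log_down)
        rows.append({
            "subject_id": r.subject_id, "auc_t": r.auc_t, "auc_inf": r.auc_inf,
            "extrap_frac": r.extrap_frac, "cmax": r.cmax, "tmax": r.tmax,
            "ke": r.ke, "t_half": r.t_half, "cl_f_w": r.cl_f_w,
            "vd_f_w": r.vd_f_w, "dose_mg": r.dose_mg, "weight_kg": r.weight_kg,
            "n_lambda_z": r.lambda_z.n_points if r.lambda_z else 0,
            "r2_adj": r.lambda_z.r_squared_adj if r.lambda_z else math.nan,
            "flags": ";".join(r.flags),
        })
    return pd.DataFrame(rows)
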