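"""Non-compartmental analysis of concentration-time profiles.

Estimates the standard model-free parameters — Cmax, AUC0-t, AUC0-inf,
AUMC, the terminal rate constant λz and half-life, mean residence time,
clearance and steady-state volume of distribution — from a (mean) plasma
profile. Defaults follow standard NCA practice: linear-up/log-down
trapezoids, λz by log-linear regression over the terminal points with the
window chosen by adjusted-R² maximisation, MRT corrected by TI/2 for
infusions, Vss = CL x MRT.

Censored (BQL) points are set to zero before Cmax and dropped after it,
mirroring the synthetic study generator's convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .parameters import DoseRegimen, ParameterError
from .profiles import ConcentrationTimeProfile

EXTRAPOLATION_WARNING_FRACTION = 0.2


class NCAError(ValueError):
    """The profile does not support the requested estimate."""


@dataclass(frozen=True)
class LambdaZFit:
    lambda_z: float          # 1/h
    t_half: float            # h
    n_points: int
    adjusted_r_squared: float
    time_window: tuple[float, float]


@dataclass(frozen=True)
class NCAResult:
    c_max: float             # mg/L
    t_max: float             # h
    t_half: float            # h
    lambda_z: float          # 1/h
    auc_0_t: float           # mg*h/L
    auc_0_inf: float         # mg*h/L
    aumc_0_inf: float        # mg*h^2/L
    mrt: float               # h
    cl: float                # L/h
    vss: float               # L
    extrapolated_fraction: float
    extrapolation_flagged: bool
    lambda_z_fit: LambdaZFit

    def to_frame(self) -> pd.DataFrame:
        d = asdict(self)
        d.pop("lambda_z_fit")
        d["lambda_z_n_points"] = self.lambda_z_fit.n_points
        d["lambda_z_adj_r2"] = self.lambda_z_fit.adjusted_r_squared
        return pd.DataFrame([d])


#: concentrations below Cmax x this are numerically indistinguishable from
#: zero (e.g. ODE-solver tolerance floor on dense simulated profiles) and are
#: treated as unquantifiable, like assay values below the LLOQ
NUMERICAL_FLOOR = 1e-9


def _prepare(profile: ConcentrationTimeProfile):
    t = profile.time
    c = profile.concentration.copy()
    if c.max() > 0:
        c[c < c.max() * NUMERICAL_FLOOR] = 0.0
    if profile.bql is not None and profile.bql.any():
        i_max = int(np.argmax(np.where(profile.bql, -np.inf, c)))
        pre = profile.bql & (np.arange(t.size) < i_max)
        post = profile.bql & (np.arange(t.size) > i_max)
        c[pre] = 0.0
        keep = ~post
        t, c = t[keep], c[keep]
    if t.size < 2:
        raise NCAError("fewer than 2 usable points after censoring")
    return t, c


def _segment_areas(t1, t2, c1, c2, method: str):
    """AUC and AUMC over one interval."""
    dt = t2 - t1
    log_down = (
        method == "linear_up_log_down" and c1 > 0 and c2 > 0 and c2 < c1
    )
    if log_down:
        k = np.log(c1 / c2) / dt
        auc = (c1 - c2) / k
        aumc = (t1 * c1 - t2 * c2) / k + (c1 - c2) / k**2
    else:
        auc = 0.5 * (c1 + c2) * dt
        aumc = 0.5 * (t1 * c1 + t2 * c2) * dt
    return auc, aumc


def auc_trapezoid(
    profile: ConcentrationTimeProfile,
    method: str = "linear_up_log_down",
    return_aumc: bool = False,
):
    """Piecewise trapezoidal AUC0-t (and optionally AUMC0-t).

    ``linear`` uses linear trapezoids throughout; ``linear_up_log_down``
    switches to the log trapezoid wherever both bracketing concentrations
    are positive and declining.
    """
    if method not in ("linear", "linear_up_log_down"):
        raise NCAError(f"unknown integration method {method!r}")
    t, c = _prepare(profile)
    if not np.any(c > 0):
        warnings.warn("all-zero profile; AUC = 0", stacklevel=2)
        return (0.0, 0.0) if return_aumc else 0.0
    auc = aumc = 0.0
    for i in range(t.size - 1):
        a, m = _segment_areas(t[i], t[i + 1], c[i], c[i + 1], method)
        auc += a
        aumc += m
    return (auc, aumc) if return_aumc else auc


def lambda_z(profile: ConcentrationTimeProfile, min_points: int = 3) -> LambdaZFit:
    """Terminal elimination rate constant by log-linear regression.

    Candidate windows are the last m >= ``min_points`` positive points,
    excluding the Cmax point; the window maximising the adjusted R² wins,
    with ties broken toward more points.
    """
    t, c = _prepare(profile)
    pos = c > 0
    i_cmax = int(np.argmax(c))
    usable = np.nonzero(pos & (np.arange(t.size) > i_cmax))[0]
    if usable.size < min_points:
        raise NCAError(
            f"need >= {min_points} positive terminal points after Cmax, "
            f"got {usable.size}"
        )
    if usable.size <= 50:
        candidates = range(min_points, usable.size + 1)
    else:
        # dense grids: geometric subsample of window sizes keeps the search
        # O(N) while still spanning short and long terminal windows
        candidates = sorted(
            set(
                np.geomspace(min_points, usable.size, 60).round().astype(int)
            )
        )
    best = None
    for m in candidates:
        sel = usable[-m:]
        x, y = t[sel], np.log(c[sel])
        slope, intercept = np.polyfit(x, y, 1)
        # a window must show a genuine decline, not round-off flatness
        if slope >= 0 or (y[0] - y[-1]) <= 1e-10:
            continue
        resid = y - (slope * x + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        adj = 1.0 - (1.0 - r2) * (m - 1) / (m - 2) if m > 2 else r2
        # >= : ties go to the larger window (m increases through the loop)
        if best is None or adj >= best.adjusted_r_squared - 1e-12:
            lz = -slope
            best = LambdaZFit(
                lambda_z=lz,
                t_half=np.log(2.0) / lz,
                n_points=m,
                adjusted_r_squared=adj,
                time_window=(float(x[0]), float(x[-1])),
            )
    if best is None:
        raise NCAError("terminal phase is not declining; cannot fit lambda_z")
    return best


def _back_extrapolate_c0(t: np.ndarray, c: np.ndarray):
    """IV-bolus C0 at t = 0 by log-linear back-extrapolation from the first
    two positive, declining concentrations (first value reused otherwise)."""
    pos = np.nonzero(c > 0)[0]
    if pos.size >= 2 and c[pos[1]] < c[pos[0]]:
        t1, t2 = t[pos[0]], t[pos[1]]
        lam = np.log(c[pos[0]] / c[pos[1]]) / (t2 - t1)
        return float(c[pos[0]] * np.exp(lam * t1))
    return float(c[pos[0]]) if pos.size else 0.0


def nca_summary(
    profile: ConcentrationTimeProfile,
    dose: float | None = None,
    regimen: DoseRegimen | None = None,
    method: str = "linear_up_log_down",
) -> NCAResult:
    """Full NCA parameter set for one profile.

    ``dose`` defaults to the profile's dose metadata; ``regimen`` supplies
    the infusion duration for the MRT correction and triggers standard
    IV-bolus C0 back-extrapolation when the profile starts after t = 0.
    """
    if dose is None:
        dose = profile.dose
    if dose is None or dose <= 0:
        raise NCAError("a positive dose is required")
    t, c = _prepare(profile)
    if regimen is not None and regimen.route == "iv_bolus" and t[0] > 0:
        c0 = _back_extrapolate_c0(t, c)
        t = np.concatenate([[0.0], t])
        c = np.concatenate([[c0], c])
    auc_t = aumc_t = 0.0
    for i in range(t.size - 1):
        a, mseg = _segment_areas(t[i], t[i + 1], c[i], c[i + 1], method)
        auc_t += a
        aumc_t += mseg
    if auc_t <= 0:
        raise NCAError("profile integrates to zero")
    fit = lambda_z(profile)
    i_last = int(np.nonzero(c > 0)[0][-1])
    c_last, t_last = c[i_last], t[i_last]
    auc_inf = auc_t + c_last / fit.lambda_z
    aumc_inf = (
        aumc_t
        + c_last * t_last / fit.lambda_z
        + c_last / fit.lambda_z**2
    )
    ti_half = 0.0
    if regimen is not None and regimen.route == "iv_infusion":
        ti_half = regimen.infusion_duration / 2.0
    mrt = aumc_inf / auc_inf - ti_half
    cl = dose / auc_inf
    extrap = 1.0 - auc_t / auc_inf
    return NCAResult(
        c_max=float(c.max()),
        t_max=float(t[int(np.argmax(c))]),
        t_half=fit.t_half,
        lambda_z=fit.lambda_z,
        auc_0_t=auc_t,
        auc_0_inf=auc_inf,
        aumc_0_inf=aumc_inf,
        mrt=mrt,
        cl=cl,
        vss=cl * mrt,
        extrapolated_fraction=extrap,
        extrapolation_flagged=extrap > EXTRAPOLATION_WARNING_FRACTION,
        lambda_z_fit=fit,
    )
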