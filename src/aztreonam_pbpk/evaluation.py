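"""Model-evaluation statistics and acceptance verdicts.

Per-point concentration fidelity is judged by the fold error
FE = predicted/observed, its geometric mean AFE (bias direction) and the
geometric mean of |log FE|, the AAFE (absolute magnitude); scalar PK
parameters by the relative prediction error RPE = (pred - obs)/obs x 100%
and its absolute value ARE. The acceptance rules encoded in
:func:`build_report`: a concentration fit is acceptable iff R² >= 0.8,
every FE lies within [0.3, 3] (inclusive) and AFE and AAFE are both < 2;
parameter predictions are reliable iff every ARE < 30%. Points with
FE outside [1/3, 3] can additionally be flagged as outliers and, when
explicitly enabled, excluded (every exclusion is logged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .parameters import ParameterError

FE_ACCEPT_LOW = 0.3
FE_ACCEPT_HIGH = 3.0
AFE_LIMIT = 2.0
AAFE_LIMIT = 2.0
R2_LIMIT = 0.8
ARE_LIMIT_PCT = 30.0
OUTLIER_FOLD_THRESHOLD = 3.0


def fold_error(predicted: float, observed: float) -> float:
    """FE = predicted / observed; both must be positive (exclude BQL upstream)."""
    if predicted <= 0 or observed <= 0:
        raise ParameterError("fold error needs positive predicted and observed")
    return predicted / observed


def _ratios(pairs) -> np.ndarray:
    arr = np.asarray(pairs, dtype=float)
    if arr.size == 0:
        raise ParameterError("at least one (predicted, observed) pair required")
    arr = arr.reshape(-1, 2)
    if np.any(arr <= 0):
        raise ParameterError("pairs must be positive")
    return arr[:, 0] / arr[:, 1]


def afe(pairs: Sequence[tuple[float, float]]) -> float:
    """Average fold error: 10^(mean log10(pred/obs)); 1 means no net bias."""
    return float(10.0 ** np.mean(np.log10(_ratios(pairs))))


def aafe(pairs: Sequence[tuple[float, float]]) -> float:
    """Average absolute fold error: 10^(mean |log10(pred/obs)|), always >= 1."""
    return float(10.0 ** np.mean(np.abs(np.log10(_ratios(pairs)))))


def rpe(observed: float, predicted: float) -> float:
    """Relative prediction error in percent (signed)."""
    if observed == 0:
        raise ParameterError("observed value must be nonzero")
    return (predicted - observed) / observed * 100.0


def are(observed: float, predicted: float) -> float:
    """Absolute relative error in percent: |RPE|."""
    return abs(rpe(observed, predicted))


def r_squared(
    observed: Sequence[float],
    predicted: Sequence[float],
    against_identity: bool = False,
) -> float:
    """Coefficient of determination of the regression of predicted on observed.

    By default this is the OLS R² (any perfect linear relation scores 1);
    ``against_identity=True`` scores residuals around the y = x line instead.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size != pred.size or obs.size < 3:
        raise ParameterError("need >= 3 paired values")
    if np.var(obs) == 0:
        raise ParameterError("observed series has zero variance")
    if against_identity:
        ss_res = float(((pred - obs) ** 2).sum())
        ss_tot = float(((pred - pred.mean()) ** 2).sum())
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    slope, intercept = np.polyfit(obs, pred, 1)
    resid = pred - (slope * obs + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((pred - pred.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def flag_outliers(
    points: pd.DataFrame,
    threshold: float = OUTLIER_FOLD_THRESHOLD,
    exclude: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag (and optionally drop) points with FE outside [1/threshold, threshold].

    ``points`` must carry an ``fe`` column. Returns (table, exclusion_log);
    rows are only removed when ``exclude=True``, and every removal is logged.
    """
    if points.empty:
        return points.assign(outlier=pd.Series(dtype=bool)), points.head(0)
    out = points.copy()
    out["outlier"] = (out["fe"] > threshold) | (out["fe"] < 1.0 / threshold)
    log = out[out["outlier"]].copy()
    if exclude:
        out = out[~out["outlier"]].copy()
    return out, log


@dataclass
class ValidationReport:
    """Per-point and per-parameter fidelity tables with verdicts."""

    points: pd.DataFrame          # time, observed, predicted, fe, flags
    parameters: pd.DataFrame      # name, observed, predicted, rpe, are, flag
    afe: float | None
    aafe: float | None
    r_squared: float | None
    exclusion_log: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def fe_within_bounds(self) -> bool:
        if self.points.empty:
            return True
        return bool(
            ((self.points["fe"] >= FE_ACCEPT_LOW)
             & (self.points["fe"] <= FE_ACCEPT_HIGH)).all()
        )

    @property
    def concentrations_acceptable(self) -> bool:
        if self.points.empty:
            return True
        return (
            self.fe_within_bounds
            and self.afe < AFE_LIMIT
            and self.aafe < AAFE_LIMIT
            and (self.r_squared is None or self.r_squared >= R2_LIMIT)
        )

    @property
    def parameters_reliable(self) -> bool:
        if self.parameters.empty:
            return True
        return bool((self.parameters["are_pct"] < ARE_LIMIT_PCT).all())

    def summary(self) -> str:
        lines = ["Validation report"]
        if not self.points.empty:
            lines += [
                f"  points: n = {len(self.points)}, "
                f"AFE = {self.afe:.3f}, AAFE = {self.aafe:.3f}"
                + (f", R2 = {self.r_squared:.3f}" if self.r_squared is not None else ""),
                f"  all FE in [{FE_ACCEPT_LOW}, {FE_ACCEPT_HIGH}]: "
                f"{self.fe_within_bounds}",
                f"  concentrations acceptable: {self.concentrations_acceptable}",
            ]
        if not self.parameters.empty:
            worst = self.parameters["are_pct"].max()
            lines += [
                f"  parameters: n = {len(self.parameters)}, "
                f"max ARE = {worst:.1f}%",
                f"  parameters reliable (all ARE < {ARE_LIMIT_PCT:g}%): "
                f"{self.parameters_reliable}",
            ]
        if len(self.exclusion_log):
            lines.append(f"  excluded outliers: {len(self.exclusion_log)}")
        return "\n".join(lines)


def build_report(
    observed: Sequence[float] | None = None,
    predicted: Sequence[float] | None = None,
    times: Sequence[float] | None = None,
    parameter_pairs: pd.DataFrame | None = None,
    exclude_outliers: bool = False,
) -> ValidationReport:
    """Assemble a :class:`ValidationReport`.

    ``observed``/``predicted`` are matched concentration series (positive,
    BQL excluded upstream); ``parameter_pairs`` is a frame with columns
    ``parameter``, ``observed``, ``predicted``.
    """
    exclusions = pd.DataFrame()
    if observed is not None:
        obs = np.asarray(observed, dtype=float)
        pred = np.asarray(predicted, dtype=float)
        pts = pd.DataFrame(
            {
                "time_h": times if times is not None else np.arange(obs.size),
                "observed": obs,
                "predicted": pred,
            }
        )
        pts["fe"] = pts["predicted"] / pts["observed"]
        pts["within_0.3_3"] = (pts["fe"] >= FE_ACCEPT_LOW) & (
            pts["fe"] <= FE_ACCEPT_HIGH
        )
        pts, exclusions = flag_outliers(pts, exclude=exclude_outliers)
        pairs = list(zip(pts["predicted"], pts["observed"]))
        afe_v, aafe_v = afe(pairs), aafe(pairs)
        if len(pts) >= 3 and np.var(pts["observed"]) > 0:
            r2 = r_squared(pts["observed"], pts["predicted"])
        else:
            r2 = None  # undefined for degenerate observed series
    else:
        pts = pd.DataFrame(columns=["time_h", "observed", "predicted", "fe"])
        afe_v = aafe_v = r2 = None

    if parameter_pairs is not None and len(parameter_pairs):
        par = parameter_pairs.copy()
        par["rpe_pct"] = [
            rpe(o, p) for o, p in zip(par["observed"], par["predicted"])
        ]
        par["are_pct"] = par["rpe_pct"].abs()
        par["within_30"] = par["are_pct"] < ARE_LIMIT_PCT
    else:
        par = pd.DataFrame(
            columns=["parameter", "observed", "predicted", "rpe_pct", "are_pct"]
        )

    return ValidationReport(
        points=pts,
        parameters=par,
        afe=afe_v,
        aafe=aafe_v,
        r_squared=r2,
        exclusion_log=exclusions,
    )
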