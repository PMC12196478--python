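"""Local parameter sensitivity of systemic exposure (AUC0-inf).

Five parameters are scanned, one at a time, as multiplicative perturbations
of the baseline model: the blood:plasma ratio ``r_bp``, the plasma free
fraction ``f_up``, lipophilicity ``log_d``, hepatic clearance ``cl_hep``
(with its tied biliary fraction) and renal clearance ``cl_renal``. Each
grid point re-simulates the whole model; the headline statistic is the
normalised sensitivity coefficient d ln AUC / d ln p at baseline
(central difference).

Two propagation conventions for ``f_up`` are offered: renal-only (the free
fraction drives filtration clearance; default) or additionally rescaling
every Kp through the protein-binding translation rule
(``fup_rescales_kp=True``). The lipophilicity perturbation feeds the
partition-prediction pathway only; with a fixed reference Kp table its
effect is structurally zero, which is exactly what a fixed-Kp model should
report.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .clearance import ClearanceSpec
from .engine import PBPKModel, SimulationError, build_model, simulate
from .parameters import ParameterError, PartitionSet
from .partition import predict_partition

PARAMETERS = ("r_bp", "f_up", "log_d", "cl_hep", "cl_renal")

DEFAULT_GRID = tuple(np.logspace(-1, 1, 21))  # 0.1x .. 10x


@dataclass
class SensitivityResult:
    parameter: str
    multipliers: np.ndarray
    auc_0_inf: np.ndarray            # mg*h/L; NaN where a run failed
    normalized_coefficient: float    # d ln AUC / d ln p at baseline
    baseline_auc: float
    failures: list = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.parameter,
                "multiplier": self.multipliers,
                "auc_0_inf": self.auc_0_inf,
            }
        )


def _perturbed_model(
    model: PBPKModel, parameter: str, m: float, fup_rescales_kp: bool
) -> PBPKModel:
    if m <= 0:
        raise ParameterError("multipliers must be > 0")
    sp = model.species
    if parameter == "r_bp":
        compound = replace(model.compound, r_bp={**model.compound.r_bp, sp: model.r_bp * m})
        return build_model(
            model.physiology, compound, model.partition, model.clearances,
            model.regimen,
        )
    if parameter == "f_up":
        new_fup = min(1.0, model.f_up * m)
        eff = new_fup / model.f_up
        compound = replace(
            model.compound, f_up={**model.compound.f_up, sp: new_fup}
        )
        cl = model.clearances
        clearances = ClearanceSpec(
            cl_renal=cl.cl_renal * eff,  # filtration scales with free fraction
            cl_hep=cl.cl_hep,
            cl_bil=cl.cl_bil,
            biliary_fraction=cl.biliary_fraction,
            provenance=cl.provenance,
        )
        partition = model.partition
        if fup_rescales_kp:
            partition = PartitionSet(
                species=sp,
                kp={t: v * eff for t, v in model.partition.kp.items()},
                source="scaled",
                adjustments_applied=model.partition.adjustments_applied,
            )
        return build_model(
            model.physiology, compound, partition, clearances, model.regimen
        )
    if parameter == "log_d":
        # lipophilicity feeds only the de-novo partition pathway
        if model.partition.source != "rodgers_rowland":
            return model
        partition = predict_partition(
            model.compound, sp, log_p=model.compound.log_p + np.log10(m)
        )
        return build_model(
            model.physiology, model.compound, partition, model.clearances,
            model.regimen,
        )
    if parameter == "cl_hep":
        cl = model.clearances
        clearances = ClearanceSpec(
            cl_renal=cl.cl_renal,
            cl_hep=cl.cl_hep * m,
            cl_bil=cl.cl_bil * m,  # biliary stays a fixed fraction of hepatic
            biliary_fraction=cl.biliary_fraction,
            provenance=cl.provenance,
        )
        return build_model(
            model.physiology, model.compound, model.partition, clearances,
            model.regimen,
        )
    if parameter == "cl_renal":
        cl = model.clearances
        clearances = ClearanceSpec(
            cl_renal=cl.cl_renal * m,
            cl_hep=cl.cl_hep,
            cl_bil=cl.cl_bil,
            biliary_fraction=cl.biliary_fraction,
            provenance=cl.provenance,
        )
        return build_model(
            model.physiology, model.compound, model.partition, clearances,
            model.regimen,
        )
    raise ParameterError(
        f"unknown sensitivity parameter {parameter!r}; choose from {PARAMETERS}"
    )


def _auc(model: PBPKModel, t_end: float, resolution: float) -> float:
    return simulate(model, t_end, output_resolution=resolution).auc_0_inf()


def sensitivity_scan(
    model: PBPKModel,
    parameter: str,
    grid=DEFAULT_GRID,
    t_end: float = 48.0,
    output_resolution: float = 0.05,
    fup_rescales_kp: bool = False,
    delta: float = 0.05,
) -> SensitivityResult:
    """Scan one parameter over multiplier ``grid`` and re-simulate each point.

    The normalised coefficient is a central difference at baseline using
    multipliers (1+delta) and 1/(1+delta). Failed grid-point simulations
    are recorded and reported as NaN, not fatal.
    """
    if parameter not in PARAMETERS:
        raise ParameterError(
            f"unknown sensitivity parameter {parameter!r}; choose from {PARAMETERS}"
        )
    grid = np.asarray(sorted(set(list(grid) + [1.0])), dtype=float)
    if np.any(grid <= 0):
        raise ParameterError("multipliers must be > 0")
    aucs = np.full(grid.shape, np.nan)
    failures = []
    for i, m in enumerate(grid):
        try:
            aucs[i] = _auc(
                _perturbed_model(model, parameter, m, fup_rescales_kp),
                t_end,
                output_resolution,
            )
        except (SimulationError, ParameterError) as exc:  # recorded, not fatal
            failures.append((float(m), str(exc)))
    baseline = aucs[np.isclose(grid, 1.0)][0]
    up = _auc(
        _perturbed_model(model, parameter, 1.0 + delta, fup_rescales_kp),
        t_end,
        output_resolution,
    )
    down = _auc(
        _perturbed_model(model, parameter, 1.0 / (1.0 + delta), fup_rescales_kp),
        t_end,
        output_resolution,
    )
    coeff = (np.log(up) - np.log(down)) / (2.0 * np.log(1.0 + delta))
    return SensitivityResult(
        parameter=parameter,
        multipliers=grid,
        auc_0_inf=aucs,
        normalized_coefficient=float(coeff),
        baseline_auc=float(baseline),
        failures=failures,
    )


def coefficient_table(
    model: PBPKModel,
    parameters=PARAMETERS,
    t_end: float = 48.0,
    output_resolution: float = 0.05,
    fup_rescales_kp: bool = False,
    delta: float = 0.05,
) -> pd.DataFrame:
    """Normalised coefficients for several parameters (tornado-style table)."""
    rows = []
    for p in parameters:
        res = sensitivity_scan(
            model,
            p,
            grid=(1.0,),
            t_end=t_end,
            output_resolution=output_resolution,
            fup_rescales_kp=fup_rescales_kp,
            delta=delta,
        )
        rows.append(
            {
                "parameter": p,
                "normalized_coefficient": res.normalized_coefficient,
                "baseline_auc": res.baseline_auc,
            }
        )
    return pd.DataFrame(rows)
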