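"""Perfusion-limited whole-body PBPK model and ODE simulator.

Model structure
---------------
Blood leaves the venous pool, passes through the lung (in series), fills the
arterial pool and perfuses every systemic tissue in parallel. Gut and spleen
drain into the portal vein, which joins the hepatic artery at the liver; the
gut has zero volume and acts as a pure flow conduit. Each tissue is
flow-limited: the blood leaving tissue *t* is in equilibrium with the tissue
at concentration ``(A_t / V_t) * R_bp / Kp_t`` (whole-blood scale), so

    dA_t/dt = Q_t * (C_in_blood - (A_t / V_t) * R_bp / Kp_t).

Elimination is organ-assigned and plasma-referenced: the kidney removes drug
at ``CL_renal * C_plasma`` and the liver at ``(CL_hep + CL_bil) * C_plasma``,
where ``C_plasma`` is the arterial plasma concentration entering the organ —
the well-stirred convention for a low-extraction drug, for which inflowing
and equilibrated outflowing plasma are nearly identical. The removal is
taken from the organ's venous-return stream, not from the tissue mass
balance, which makes three linear-PK identities hold simultaneously:
AUC0-inf = Dose/CL_total is exact, every tissue's steady-state
tissue:plasma ratio equals its Kp under constant infusion, and the
moment-based Vss = CL x MRT agrees closely with the volume-weighted
sum of Kp values.

Any residual between cardiac output and the summed venous-return flows
(the tabulated physiologies close to within 0.2%) is carried by a direct
arterial-to-venous shunt so that flow is conserved at every node.

Input routes: IV bolus (initial condition in the venous pool), zero-order IV
infusion, and a first-order depot (IM/SC, F = 1) absorbing into venous blood.
Reported plasma concentration is venous blood concentration divided by R_bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .clearance import ClearanceSpec, default_clearance
from .parameters import (
    PERFUSED_TISSUES,
    CompoundProperties,
    DoseRegimen,
    ParameterError,
    PartitionSet,
    SpeciesPhysiology,
    load_compound,
    load_physiology,
    resolve_dose,
)
from .partition import default_partition

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10  # mg
MASS_BALANCE_LIMIT = 1e-3


class SimulationError(RuntimeError):
    """The ODE integrator failed or produced an invalid state."""


@dataclass(frozen=True)
class PBPKModel:
    """Assembled whole-body model for one species and regimen."""

    physiology: SpeciesPhysiology
    compound: CompoundProperties
    partition: PartitionSet
    clearances: ClearanceSpec
    regimen: DoseRegimen
    #: species-resolved plasma binding
    f_up: float = field(init=False)
    r_bp: float = field(init=False)

    def __post_init__(self):
        sp = self.physiology.species
        object.__setattr__(self, "f_up", self.compound.f_up_for(sp))
        object.__setattr__(self, "r_bp", self.compound.r_bp_for(sp))

    @property
    def species(self) -> str:
        return self.physiology.species

    @classmethod
    def for_species(
        cls,
        species: str,
        regimen: DoseRegimen | None = None,
        dose_mg: float | None = None,
        dose_mg_per_kg: float | None = None,
        route: str = "iv_bolus",
        infusion_duration_h: float | None = None,
        ka_per_h: float | None = None,
        clearance: str = "calibrated",
        kp_source: str = "reference",
        compound_overrides: Mapping | None = None,
        physiology_overrides: Mapping | None = None,
    ) -> "PBPKModel":
        """Build a species model entirely from the embedded defaults."""
        physiology = load_physiology(species, physiology_overrides)
        compound = load_compound(compound_overrides)
        partition = default_partition(species, compound, kp_source)
        clearances = default_clearance(physiology, compound, clearance)
        if regimen is None:
            regimen = resolve_dose(
                route=route,
                physiology=physiology,
                dose_mg=dose_mg,
                dose_mg_per_kg=dose_mg_per_kg,
                infusion_duration_h=infusion_duration_h,
                ka_per_h=ka_per_h,
            )
        return build_model(physiology, compound, partition, clearances, regimen)

    def with_changes(self, **kwargs) -> "PBPKModel":
        """Rebuild the model with some components replaced (revalidates)."""
        parts = {
            "physiology": self.physiology,
            "compound": self.compound,
            "partition": self.partition,
            "clearances": self.clearances,
            "regimen": self.regimen,
        }
        parts.update(kwargs)
        allow = kwargs.pop("_allow_species_mismatch", False)
        return build_model(**parts, allow_species_mismatch=allow)

    def snapshot(self) -> dict:
        """Every resolved parameter, serializable for reproducibility."""
        return {
            "species": self.species,
            "f_up": self.f_up,
            "r_bp": self.r_bp,
            "physiology": self.physiology.to_dict(),
            "compound": self.compound.to_dict(),
            "partition": self.partition.to_dict(),
            "clearances": self.clearances.to_dict(),
            "regimen": self.regimen.to_dict(),
        }


def build_model(
    physiology: SpeciesPhysiology,
    compound: CompoundProperties,
    partition: PartitionSet,
    clearances: ClearanceSpec,
    regimen: DoseRegimen,
    allow_species_mismatch: bool = False,
) -> PBPKModel:
    """Validate and assemble a :class:`PBPKModel`.

    Checks species consistency, completeness of the Kp set for every
    perfused tissue, non-negative clearances, and that each organ clearance
    is deliverable by its blood flow (CL <= R_bp x Q_organ).
    """
    if partition.species != physiology.species and not allow_species_mismatch:
        raise ParameterError(
            f"species mismatch: physiology is {physiology.species!r} but the "
            f"partition set is {partition.species!r} (pass "
            "allow_species_mismatch=True to override)"
        )
    partition.require(PERFUSED_TISSUES)
    r_bp = compound.r_bp_for(physiology.species)
    q_kid = physiology.compartments["kidney"].blood_flow
    q_liv = physiology.compartments["liver"].blood_flow
    if clearances.cl_renal > r_bp * q_kid:
        raise ParameterError(
            "renal clearance exceeds deliverable kidney blood flow "
            f"({clearances.cl_renal:g} > {r_bp * q_kid:g} L/h)"
        )
    if clearances.cl_hep + clearances.cl_bil > r_bp * q_liv:
        raise ParameterError(
            "hepatic + biliary clearance exceeds deliverable liver blood flow"
        )
    return PBPKModel(
        physiology=physiology,
        compound=compound,
        partition=partition,
        clearances=clearances,
        regimen=regimen,
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Concentration-time surfaces and elimination bookkeeping.

    Concentrations are mg/L (ug/mL); ``plasma`` is venous plasma. ``auc``
    is the running integral of the venous plasma concentration computed by
    the solver itself (a quadrature state, not a post-hoc trapezoid).
    """

    model: PBPKModel
    time: np.ndarray                      # h
    plasma: np.ndarray                    # mg/L
    tissue_concentrations: dict[str, np.ndarray]  # mg/L, per tissue
    amounts: dict[str, np.ndarray]        # mg, every state incl. blood pools
    eliminated: dict[str, np.ndarray]     # mg, cumulative by route
    auc: np.ndarray                       # mg*h/L, running AUC of plasma
    mass_balance_error: float             # max |body + eliminated - given|/dose

    @property
    def dose(self) -> float:
        return self.model.regimen.dose

    def administered(self, t: np.ndarray) -> np.ndarray:
        """Cumulative amount delivered to the body (depot counts as in-body)."""
        reg = self.model.regimen
        if reg.route == "iv_infusion":
            return reg.dose * np.minimum(t / reg.infusion_duration, 1.0)
        return np.full_like(np.asarray(t, dtype=float), reg.dose)

    def amount_in_body(self) -> np.ndarray:
        return sum(self.amounts.values())

    def auc_0_inf(self) -> float:
        """Quadrature AUC to t_end plus a log-linear tail from the last decade."""
        c = self.plasma
        t = self.time
        pos = c > 0
        if not pos.any() or c[pos][-1] <= 0:
            return float(self.auc[-1])
        # terminal slope from the last stretch where the profile declines
        idx = np.nonzero(pos)[0]
        tail = idx[-min(10, len(idx)):]
        slope = np.polyfit(t[tail], np.log(c[tail]), 1)[0]
        if slope >= 0:
            return float(self.auc[-1])
        return float(self.auc[-1] + c[idx[-1]] / (-slope))

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: time, compartment, concentration."""
        frames = [
            pd.DataFrame(
                {
                    "time_h": self.time,
                    "compartment": "plasma",
                    "concentration_mg_per_L": self.plasma,
                }
            )
        ]
        for tissue, conc in self.tissue_concentrations.items():
            frames.append(
                pd.DataFrame(
                    {
                        "time_h": self.time,
                        "compartment": tissue,
                        "concentration_mg_per_L": conc,
                    }
                )
            )
        out = pd.concat(frames, ignore_index=True)
        out["dose_mg"] = self.dose
        out["species"] = self.model.species
        return out

    def to_wide(self) -> pd.DataFrame:
        data = {"time_h": self.time, "plasma": self.plasma}
        data.update(self.tissue_concentrations)
        return pd.DataFrame(data)

    def plot(self, compartments=("plasma",), ax=None, logy=True):
        """Quick static concentration-time figure (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name in compartments:
            y = (
                self.plasma
                if name == "plasma"
                else self.tissue_concentrations[name]
            )
            ax.plot(self.time, y, label=name)
        if logy:
            ax.set_yscale("log")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("concentration (mg/L)")
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = [
            f"PBPK simulation - {self.model.species}, "
            f"{self.model.regimen.route}, dose {self.dose:g} mg",
            f"  time span: 0-{self.time[-1]:g} h "
            f"({len(self.time)} output points)",
            f"  Cmax (plasma): {self.plasma.max():.4g} mg/L",
            f"  AUC0-{self.time[-1]:g}h: {self.auc[-1]:.4g} mg*h/L",
            f"  AUC0-inf (log tail): {self.auc_0_inf():.4g} mg*h/L",
            f"  eliminated: renal {self.eliminated['renal'][-1]:.4g} mg, "
            f"hepatic {self.eliminated['hepatic'][-1]:.4g} mg, "
            f"biliary {self.eliminated['biliary'][-1]:.4g} mg",
            f"  mass-balance error: {self.mass_balance_error:.2e} of dose",
        ]
        return "\n".join(lines)


def _network(model: PBPKModel):
    """Precompute flow/partition arrays for the RHS."""
    comps = model.physiology.compartments
    tissues = list(PERFUSED_TISSUES)
    n = len(tissues)
    idx = {t: i for i, t in enumerate(tissues)}
    v = np.array([comps[t].volume for t in tissues])
    q = np.array([comps[t].blood_flow for t in tissues])
    kp = np.array([model.partition.kp[t] for t in tissues])
    r_bp = model.r_bp
    co = model.physiology.cardiac_output
    q[idx["lung"]] = co
    q_gut = comps["acat_gut"].blood_flow
    q_spl = comps["spleen"].blood_flow
    q_liv = comps["liver"].blood_flow
    q_ha = q_liv - q_gut - q_spl
    shunt = co - model.physiology.venous_return_flow
    # venous collectors: all systemic tissues except spleen (drains portally);
    # lung feeds the arterial pool instead
    ven_mask = np.ones(n)
    ven_mask[idx["lung"]] = 0.0
    ven_mask[idx["spleen"]] = 0.0
    out_coef = q * r_bp / np.where(v > 0, kp * v, np.inf)  # c_out = coef*A/q
    return {
        "tissues": tissues,
        "idx": idx,
        "v": v,
        "q": q,
        "kp": kp,
        "r_bp": r_bp,
        "co": co,
        "q_gut": q_gut,
        "q_spl": q_spl,
        "q_liv": q_liv,
        "q_ha": q_ha,
        "shunt": shunt,
        "ven_mask": ven_mask,
        "v_art": comps["arterial"].volume,
        "v_ven": comps["venous"].volume,
    }


def simulate(
    model: PBPKModel,
    t_end: float | None = None,
    output_resolution: float = 0.01,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
    output_times=None,
) -> SimulationResult:
    """Integrate the model and return concentration-time profiles.

    ``output_resolution`` sets the reporting grid only; the solver chooses
    its own internal steps under ``rtol``/``atol``. ``output_times``
    overrides the uniform grid with explicit reporting times (t = 0 is
    always included). Raises :class:`SimulationError` on integrator failure
    or a state more negative than the solver tolerance allows.
    """
    if output_times is not None:
        output_times = np.unique(
            np.concatenate([[0.0], np.asarray(output_times, dtype=float)])
        )
        if output_times[0] < 0:
            raise ParameterError("output times must be >= 0")
        t_end = float(output_times[-1])
    if t_end is None or t_end <= 0:
        raise ParameterError("t_end must be > 0")
    net = _network(model)
    tissues = net["tissues"]
    idx = net["idx"]
    n = len(tissues)
    i_lung, i_liv = idx["lung"], idx["liver"]
    i_spl, i_kid = idx["spleen"], idx["kidney"]
    v, q = net["v"], net["q"]
    kp, r_bp = net["kp"], net["r_bp"]
    co, shunt = net["co"], net["shunt"]
    q_ha, q_gut, q_spl, q_liv = (
        net["q_ha"], net["q_gut"], net["q_spl"], net["q_liv"],
    )
    ven_q = net["ven_mask"] * q
    v_art, v_ven = net["v_art"], net["v_ven"]
    inv_kpv = np.where(v > 0, 1.0 / (kp * v), 0.0)

    cl = model.clearances
    cl_ren, cl_hep, cl_bil = cl.cl_renal, cl.cl_hep, cl.cl_bil

    reg = model.regimen
    # state: [tissues..., A_art, A_ven, A_depot, E_ren, E_hep, E_bil, AUC]
    i_art, i_ven, i_dep = n, n + 1, n + 2
    i_eren, i_ehep, i_ebil, i_auc = n + 3, n + 4, n + 5, n + 6
    n_state = n + 7
    y0 = np.zeros(n_state)
    infusion_rate = 0.0
    t_switch = None
    if reg.route == "iv_bolus":
        y0[i_ven] = reg.dose
    elif reg.route == "iv_infusion":
        infusion_rate = reg.dose / reg.infusion_duration
        t_switch = min(reg.infusion_duration, t_end)
    elif reg.route == "depot":
        y0[i_dep] = reg.dose

    ka = reg.ka or 0.0

    def rhs(t, y, rate_in):
        a_t = y[:n]
        c_art = y[i_art] / v_art
        c_ven = y[i_ven] / v_ven
        c_out = a_t * inv_kpv * r_bp  # equilibrated effluent blood conc
        c_in = np.full(n, c_art)
        c_in[i_lung] = c_ven
        da = q * (c_in - c_out)
        da[i_liv] = (
            (q_ha + q_gut) * c_art
            + q_spl * c_out[i_spl]
            - q_liv * c_out[i_liv]
        )
        # elimination at the organ, driven by the arterial plasma entering it
        c_art_plasma = c_art / r_bp
        r_ren = cl_ren * c_art_plasma
        r_hep = cl_hep * c_art_plasma
        r_bil = cl_bil * c_art_plasma
        absorbed = ka * y[i_dep]
        dy = np.empty(n_state)
        dy[:n] = da
        dy[i_art] = co * c_out[i_lung] - co * c_art
        dy[i_ven] = (
            ven_q @ c_out
            + shunt * c_art
            - r_ren - r_hep - r_bil
            - co * c_ven
            + rate_in
            + absorbed
        )
        dy[i_dep] = -absorbed
        dy[i_eren] = r_ren
        dy[i_ehep] = r_hep
        dy[i_ebil] = r_bil
        dy[i_auc] = c_ven / r_bp
        return dy

    if output_times is not None:
        t_eval = output_times
    else:
        n_out = max(2, int(round(t_end / output_resolution)) + 1)
        t_eval = np.linspace(0.0, t_end, n_out)
    if t_switch is not None and t_switch not in t_eval:
        t_eval = np.sort(np.append(t_eval, t_switch))

    segments = (
        [(0.0, t_switch, infusion_rate), (t_switch, t_end, 0.0)]
        if t_switch is not None and t_switch < t_end
        else [(0.0, t_end, infusion_rate)]
    )
    ts, ys = [], []
    y = y0
    for t0, t1, rate in segments:
        mask = (t_eval >= t0) & (t_eval <= t1)
        sol = solve_ivp(
            rhs,
            (t0, t1),
            y,
            t_eval=t_eval[mask],
            method=method,
            rtol=rtol,
            atol=atol,
            args=(rate,),
        )
        if not sol.success:
            raise SimulationError(
                f"integrator failed in [{t0}, {t1}] h: {sol.message}"
            )
        keep = slice(1, None) if ts and sol.t.size and sol.t[0] == ts[-1][-1] else slice(None)
        ts.append(sol.t[keep])
        ys.append(sol.y[:, keep])
        y = sol.y[:, -1]

    t = np.concatenate(ts)
    ymat = np.concatenate(ys, axis=1)

    floor = -max(atol * 1e3, rtol * max(reg.dose, 1.0))
    if ymat[: n + 3].min() < floor:
        raise SimulationError(
            f"negative state beyond solver tolerance: min = {ymat[: n + 3].min():g} mg"
        )
    ymat[: n + 3] = np.clip(ymat[: n + 3], 0.0, None)

    tissue_conc = {
        tis: ymat[idx[tis]] / v[idx[tis]] if v[idx[tis]] > 0 else np.zeros_like(t)
        for tis in tissues
    }
    plasma = ymat[i_ven] / v_ven / r_bp
    amounts = {tis: ymat[idx[tis]] for tis in tissues}
    amounts["arterial"] = ymat[i_art]
    amounts["venous"] = ymat[i_ven]
    amounts["depot"] = ymat[i_dep]
    eliminated = {
        "renal": ymat[i_eren],
        "hepatic": ymat[i_ehep],
        "biliary": ymat[i_ebil],
    }
    result = SimulationResult(
        model=model,
        time=t,
        plasma=plasma,
        tissue_concentrations=tissue_conc,
        amounts=amounts,
        eliminated=eliminated,
        auc=ymat[i_auc],
        mass_balance_error=0.0,
    )
    result.mass_balance_error = mass_balance_audit(result)
    return result


def mass_balance_audit(result: SimulationResult, dose: float | None = None) -> float:
    """Max over time of |in body + eliminated - administered so far| / dose.

    Raises if the result's compartment bookkeeping is incomplete.
    """
    expected = set(PERFUSED_TISSUES) | {"arterial", "venous", "depot"}
    missing = expected - set(result.amounts)
    if missing:
        raise SimulationError(
            f"mass-balance audit: missing compartment amounts {sorted(missing)}"
        )
    if dose is None:
        dose = result.dose
    if dose == 0:
        return 0.0
    in_body = result.amount_in_body()
    elim = sum(result.eliminated.values())
    given = result.administered(result.time)
    return float(np.max(np.abs(in_body + elim - given)) / dose)


def simulate_to_steady_state(
    model: PBPKModel,
    infusion_rate_mg_per_h: float,
    t_end: float = 500.0,
    **kwargs,
) -> SimulationResult:
    """Constant-rate infusion run used as the steady-state partition oracle."""
    reg = DoseRegimen(
        route="iv_infusion",
        dose=infusion_rate_mg_per_h * t_end,
        infusion_duration=t_end,
    )
    ss_model = replace(model, regimen=reg)
    kwargs.setdefault("output_resolution", t_end / 500)
    return simulate(ss_model, t_end, **kwargs)
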