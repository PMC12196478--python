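"""Whole-body simulator: conservation, linearity, network contracts."""

import json
from dataclasses import replace

import numpy as np
import pytest

import aztreonam_pbpk as az
from aztreonam_pbpk.engine import (
    SimulationError,
    build_model,
    mass_balance_audit,
    simulate,
    simulate_to_steady_state,
)
from aztreonam_pbpk.clearance import ClearanceSpec
from aztreonam_pbpk.parameters import ParameterError


class TestModelAssembly:
    def test_missing_kidney_kp_names_tissue(self, rat_model):
        kp = {t: v for t, v in rat_model.partition.kp.items() if t != "kidney"}
        part = az.PartitionSet(species="rat", kp=kp)
        with pytest.raises(ParameterError, match="kidney"):
            build_model(
                rat_model.physiology, rat_model.compound, part,
                rat_model.clearances, rat_model.regimen,
            )

    def test_species_mismatch_requires_override(self, rat_model):
        human_kp = az.load_partition_table("human")
        with pytest.raises(ParameterError, match="mismatch"):
            build_model(
                rat_model.physiology, rat_model.compound, human_kp,
                rat_model.clearances, rat_model.regimen,
            )
        model = build_model(
            rat_model.physiology, rat_model.compound, human_kp,
            rat_model.clearances, rat_model.regimen,
            allow_species_mismatch=True,
        )
        assert model.partition.species == "human"

    def test_clearance_beyond_organ_flow_rejected(self, rat_model):
        big = ClearanceSpec(cl_renal=10.0, cl_hep=0.0, cl_bil=0.0)
        with pytest.raises(ParameterError, match="renal"):
            build_model(
                rat_model.physiology, rat_model.compound, rat_model.partition,
                big, rat_model.regimen,
            )

    def test_snapshot_is_json_serializable(self, rat_model):
        text = json.dumps(rat_model.snapshot())
        snap = json.loads(text)
        assert snap["species"] == "rat"
        assert snap["clearances"]["total"] == pytest.approx(0.216)


class TestConservation:
    def test_zero_dose_stays_identically_zero(self, rat_model):
        model = replace(
            rat_model, regimen=az.DoseRegimen(route="iv_bolus", dose=0.0)
        )
        res = simulate(model, 4.0, 0.05)
        assert np.all(res.plasma == 0.0)
        assert all(np.all(c == 0.0) for c in res.tissue_concentrations.values())

    def test_clearance_free_bolus_conserves_dose(self, rat_model):
        model = rat_model.with_changes(
            clearances=ClearanceSpec(cl_renal=0.0, cl_hep=0.0, cl_bil=0.0)
        )
        res = simulate(model, 24.0, 0.05, rtol=1e-10, atol=1e-12)
        total = res.amount_in_body()
        assert np.max(np.abs(total - model.regimen.dose)) / model.regimen.dose < 1e-6

    def test_mass_balance_within_contract(self, rat_sim, human_sim):
        assert rat_sim.mass_balance_error <= 1e-3
        assert human_sim.mass_balance_error <= 1e-3

    def test_audit_fails_loudly_on_truncated_result(self, rat_sim):
        crippled = replace(
            rat_sim,
            amounts={k: v for k, v in rat_sim.amounts.items() if k != "muscle"},
        )
        with pytest.raises(SimulationError, match="muscle"):
            mass_balance_audit(crippled)

    def test_terminal_amount_monotone_after_input_ends(self, human_sim):
        total = human_sim.amount_in_body()
        after = total[human_sim.time > 0.05]  # infusion ends at 2 min
        assert np.all(np.diff(after) <= 1e-9 * human_sim.dose)


class TestLinearity:
    def test_dose_proportionality_to_1e6(self, rat_model):
        tight = dict(rtol=1e-10, atol=1e-12)
        res1 = simulate(rat_model, 12.0, 0.05, **tight)
        doubled = replace(
            rat_model,
            regimen=az.DoseRegimen(route="iv_bolus", dose=2 * rat_model.regimen.dose),
        )
        res2 = simulate(doubled, 12.0, 0.05, **tight)
        mask = res1.plasma > res1.plasma.max() * 1e-6
        ratio = res2.plasma[mask] / res1.plasma[mask]
        assert np.max(np.abs(ratio - 2.0)) < 1e-6
        # tissue curves carry a little extra solver step-control noise
        for t in ("muscle", "kidney", "liver"):
            c1 = res1.tissue_concentrations[t]
            c2 = res2.tissue_concentrations[t]
            m = c1 > c1.max() * 1e-6
            assert np.max(np.abs(c2[m] / c1[m] - 2.0)) < 5e-6

    @pytest.mark.parametrize(
        "species,kwargs,t_end",
        [
            ("rat", dict(dose_mg_per_kg=50), 24.0),
            ("mouse", dict(dose_mg_per_kg=20, route="depot", ka_per_h=6.0), 24.0),
            (
                "human",
                dict(dose_mg=500, route="iv_infusion", infusion_duration_h=2 / 60),
                48.0,
            ),
            ("dog", dict(dose_mg_per_kg=25), 48.0),
            ("monkey", dict(dose_mg_per_kg=20), 24.0),
        ],
    )
    def test_auc_equals_dose_over_clearance(self, species, kwargs, t_end):
        model = az.PBPKModel.for_species(species, **kwargs)
        res = simulate(model, t_end, 0.01)
        expected = model.regimen.dose / model.clearances.total
        assert res.auc_0_inf() == pytest.approx(expected, rel=0.01)


class TestSteadyState:
    def test_infusion_reproduces_every_kp(self, rat_model):
        ss = simulate_to_steady_state(rat_model, 1.0, t_end=300.0)
        c_plasma = ss.plasma[-1]
        for tissue, kp in rat_model.partition.kp.items():
            ratio = ss.tissue_concentrations[tissue][-1] / c_plasma
            assert ratio == pytest.approx(kp, rel=0.01), tissue


class TestContracts:
    def test_nonpositive_t_end_rejected(self, rat_model):
        with pytest.raises(ParameterError):
            simulate(rat_model, 0.0)

    def test_human_worked_scenario_auc(self, human_sim):
        """500 mg / 2-min infusion with total CL 6.56 L/h."""
        assert human_sim.auc_0_inf() == pytest.approx(500 / 6.56, rel=0.01)

    def test_tidy_frame_shape(self, rat_sim):
        df = rat_sim.to_frame()
        assert set(df.columns) >= {
            "time_h", "compartment", "concentration_mg_per_L", "dose_mg", "species",
        }
        assert (df["concentration_mg_per_L"] >= 0).all()

    def test_output_times_override(self, rat_model):
        res = simulate(rat_model, output_times=[0.25, 0.5, 1.0, 2.0])
        assert res.time[0] == 0.0 and res.time[-1] == 2.0
        assert np.all(np.isin([0.25, 0.5, 1.0, 2.0], res.time))
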