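"""Typed model inputs: compound constants, species physiology, partition
tables and dose regimens, with embedded defaults and unit normalization.

All defaults are shipped as data files under :mod:`aztreonam_pbpk.data` and
validated on load. Physiology files are stored in their tabulated units
(mL, mL/s) and converted to canonical units (L, L/h) exactly once.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .units import (
    CANONICAL_UNITS,
    ML_PER_S_TO_L_PER_H,
    ML_TO_L,
    TABLE_UNITS,
)

SPECIES = ("rat", "mouse", "human", "dog", "monkey")

#: every compartment of the whole-body network
TISSUES = (
    "lung", "arterial", "venous", "adipose", "muscle", "liver", "acat_gut",
    "spleen", "heart", "brain", "kidney", "skin", "reproductive",
    "red_marrow", "yellow_marrow", "rest_of_body",
)

#: tissues that require a partition coefficient (everything perfused except
#: the blood pools and the zero-volume gut conduit)
PERFUSED_TISSUES = tuple(
    t for t in TISSUES if t not in ("arterial", "venous", "acat_gut")
)

#: perfused tissues other than the lung (which sits in series, not parallel)
SYSTEMIC_TISSUES = tuple(t for t in PERFUSED_TISSUES if t != "lung")

#: tissues draining into the portal vein rather than directly to the venous pool
PORTAL_TISSUES = ("acat_gut", "spleen")

FLOW_IMBALANCE_TOLERANCE = 0.02


class ParameterError(ValueError):
    """Invalid or inconsistent model input."""


def _data_file(name: str):
    return resources.files("aztreonam_pbpk.data").joinpath(name)


def _load_yaml(name: str) -> dict:
    with _data_file(name).open("r") as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# compound
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PKaEntry:
    value: float
    kind: str  # "acid" or "base"

    def __post_init__(self):
        if self.kind not in ("acid", "base"):
            raise ParameterError(
                f"pKa entry needs an acid/base annotation, got {self.kind!r}"
            )


@dataclass(frozen=True)
class CompoundProperties:
    """Physicochemical and plasma-binding constants of the drug.

    ``f_up`` and ``r_bp`` are per-species maps: the fraction unbound in
    plasma and the blood:plasma concentration ratio.
    """

    name: str
    molecular_weight: float
    log_p: float
    log_d_74: float
    solubility_74: float
    pka_values: tuple[PKaEntry, ...]
    f_up: Mapping[str, float]
    r_bp: Mapping[str, float]

    def __post_init__(self):
        if self.molecular_weight <= 0:
            raise ParameterError("molecular_weight must be > 0")
        for sp, f in self.f_up.items():
            if not (0 < f <= 1):
                raise ParameterError(f"f_up[{sp}] = {f} outside (0, 1]")
        for sp, r in self.r_bp.items():
            if r <= 0:
                raise ParameterError(f"r_bp[{sp}] = {r} must be > 0")

    def f_up_for(self, species: str) -> float:
        try:
            return self.f_up[species]
        except KeyError:
            raise ParameterError(f"no f_up for species {species!r}") from None

    def r_bp_for(self, species: str) -> float:
        try:
            return self.r_bp[species]
        except KeyError:
            raise ParameterError(f"no r_bp for species {species!r}") from None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pka_values"] = [asdict(p) for p in self.pka_values]
        d["f_up"] = dict(self.f_up)
        d["r_bp"] = dict(self.r_bp)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CompoundProperties":
        d = dict(d)
        d["pka_values"] = tuple(PKaEntry(**p) for p in d["pka_values"])
        return cls(**d)


def load_compound(overrides: Mapping | None = None) -> CompoundProperties:
    """Load the embedded aztreonam constants, optionally overriding fields."""
    raw = _load_yaml("compound_aztreonam.yaml")
    raw["pka_values"] = [
        {"value": p["value"], "kind": p["kind"]} for p in raw["pka_values"]
    ]
    if overrides:
        for key, val in overrides.items():
            if isinstance(val, Mapping) and isinstance(raw.get(key), dict):
                raw[key] = {**raw[key], **val}
            else:
                raw[key] = val
    return CompoundProperties.from_dict(raw)


# ---------------------------------------------------------------------------
# physiology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueCompartment:
    """One organ: volume and the blood flow perfusing it."""

    name: str
    volume: float
    blood_flow: float

    def __post_init__(self):
        if self.name not in TISSUES:
            raise ParameterError(f"unknown compartment {self.name!r}")
        if self.blood_flow < 0:
            raise ParameterError(f"{self.name}: negative blood flow")
        if self.volume < 0:
            raise ParameterError(f"{self.name}: negative volume")
        if self.volume == 0 and self.name != "acat_gut":
            raise ParameterError(f"{self.name}: volume must be > 0")


@dataclass(frozen=True)
class SpeciesPhysiology:
    """Whole-body compartment set for one species.

    ``units`` tags whether volumes/flows are in the tabulated units
    (mL, mL/s) or canonical units (L, L/h); :meth:`normalized` converts and
    refuses to convert twice.
    """

    species: str
    body_weight: float  # kg
    compartments: Mapping[str, TissueCompartment]
    gfr: float          # L/h
    hematocrit: float
    units: str = TABLE_UNITS

    def __post_init__(self):
        if self.body_weight <= 0:
            raise ParameterError("body_weight must be > 0")
        if not (0 < self.hematocrit < 1):
            raise ParameterError("hematocrit must be in (0, 1)")
        if self.gfr < 0:
            raise ParameterError("gfr must be >= 0")
        missing = set(TISSUES) - set(self.compartments)
        if missing:
            raise ParameterError(f"missing compartments: {sorted(missing)}")
        liver = self.compartments["liver"].blood_flow
        portal = sum(self.compartments[t].blood_flow for t in PORTAL_TISSUES)
        if liver < portal:
            raise ParameterError(
                "liver total flow smaller than portal inflow (gut + spleen)"
            )
        self._check_flow_conservation()

    # -- network bookkeeping -------------------------------------------------

    @property
    def cardiac_output(self) -> float:
        return self.compartments["lung"].blood_flow

    @property
    def venous_return_flow(self) -> float:
        """Sum of flows draining to the venous pool: systemic tissues with the
        liver at its total flow; gut and spleen drain portally and are not
        double-counted."""
        return sum(
            self.compartments[t].blood_flow
            for t in SYSTEMIC_TISSUES
            if t not in PORTAL_TISSUES
        )

    @property
    def hepatic_artery_flow(self) -> float:
        return self.compartments["liver"].blood_flow - sum(
            self.compartments[t].blood_flow for t in PORTAL_TISSUES
        )

    def _check_flow_conservation(self):
        co = self.cardiac_output
        ret = self.venous_return_flow
        if co <= 0:
            raise ParameterError("lung (cardiac output) flow must be > 0")
        imbalance = abs(co - ret) / co
        if imbalance > FLOW_IMBALANCE_TOLERANCE:
            raise ParameterError(
                f"flow imbalance {imbalance:.1%} in compartment 'lung': "
                f"cardiac output {co:g} vs venous return {ret:g}"
            )

    # -- units ---------------------------------------------------------------

    def normalized(self) -> "SpeciesPhysiology":
        """Convert tabulated units (mL, mL/s) to canonical (L, L/h)."""
        if self.units == CANONICAL_UNITS:
            raise ParameterError(
                "physiology already in canonical units; refusing to convert twice"
            )
        comps = {
            name: TissueCompartment(
                name=name,
                volume=c.volume * ML_TO_L,
                blood_flow=c.blood_flow * ML_PER_S_TO_L_PER_H,
            )
            for name, c in self.compartments.items()
        }
        return SpeciesPhysiology(
            species=self.species,
            body_weight=self.body_weight,
            compartments=comps,
            gfr=self.gfr,
            hematocrit=self.hematocrit,
            units=CANONICAL_UNITS,
        )

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "body_weight": self.body_weight,
            "gfr": self.gfr,
            "hematocrit": self.hematocrit,
            "units": self.units,
            "compartments": {
                name: {"volume": c.volume, "blood_flow": c.blood_flow}
                for name, c in self.compartments.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SpeciesPhysiology":
        comps = {
            name: TissueCompartment(name=name, **vals)
            for name, vals in d["compartments"].items()
        }
        return cls(
            species=d["species"],
            body_weight=d["body_weight"],
            compartments=comps,
            gfr=d["gfr"],
            hematocrit=d["hematocrit"],
            units=d.get("units", CANONICAL_UNITS),
        )

    def to_frame(self) -> pd.DataFrame:
        unit_v = "L" if self.units == CANONICAL_UNITS else "mL"
        unit_q = "L/h" if self.units == CANONICAL_UNITS else "mL/s"
        rows = [
            {
                "tissue": name,
                f"volume_{unit_v}": c.volume,
                f"blood_flow_{unit_q}": c.blood_flow,
            }
            for name, c in self.compartments.items()
        ]
        return pd.DataFrame(rows)


def load_physiology(
    species: str, overrides: Mapping | None = None
) -> SpeciesPhysiology:
    """Load a species physiology in canonical units (L, L/h).

    ``overrides`` may replace scalars (``body_weight_kg``, ``gfr_L_per_h``,
    ``hematocrit``) or per-compartment values, expressed in the tabulated
    units (mL, mL/s); they are applied before unit conversion.
    """
    if species not in SPECIES:
        if not overrides or "compartments" not in overrides:
            raise ParameterError(
                f"unknown species {species!r}; provide a complete compartment "
                f"set via overrides, or use one of {SPECIES}"
            )
        raw = {"species": species, "units": {"volume": "mL", "flow": "mL/s"}}
    else:
        raw = _load_yaml(f"physiology_{species}.yaml")
    if overrides:
        raw = copy.deepcopy(raw)
        for key, val in overrides.items():
            if key == "compartments":
                raw.setdefault("compartments", {})
                for cname, cvals in val.items():
                    raw["compartments"].setdefault(cname, {}).update(cvals)
            else:
                raw[key] = val
    comps = {
        name: TissueCompartment(
            name=name, volume=vals["volume"], blood_flow=vals["flow"]
        )
        for name, vals in raw["compartments"].items()
    }
    phys = SpeciesPhysiology(
        species=raw["species"],
        body_weight=raw["body_weight_kg"],
        compartments=comps,
        gfr=raw["gfr_L_per_h"],
        hematocrit=raw["hematocrit"],
        units=TABLE_UNITS,
    )
    return phys.normalized()


# ---------------------------------------------------------------------------
# dosing
# ---------------------------------------------------------------------------

ROUTES = ("iv_bolus", "iv_infusion", "depot")


@dataclass(frozen=True)
class DoseRegimen:
    """Administration: route, absolute dose and route-specific kinetics.

    The depot route models IM/SC administration as first-order absorption
    into venous blood with complete bioavailability (F = 1).
    """

    route: str
    dose: float                       # mg, absolute
    infusion_duration: float | None = None  # h, iv_infusion only
    ka: float | None = None           # 1/h, depot only

    def __post_init__(self):
        if self.route not in ROUTES:
            raise ParameterError(f"unknown route {self.route!r}")
        # zero dose is permitted so null-input simulations are expressible;
        # resolve_dose() rejects non-positive study doses
        if self.dose < 0:
            raise ParameterError("dose must be >= 0")
        if self.route == "iv_infusion":
            if not self.infusion_duration or self.infusion_duration <= 0:
                raise ParameterError("iv_infusion needs infusion_duration > 0")
        if self.route == "depot":
            if not self.ka or self.ka <= 0:
                raise ParameterError("depot route needs ka > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "DoseRegimen":
        return cls(**d)


def resolve_dose(
    route: str,
    physiology: SpeciesPhysiology | None = None,
    dose_mg: float | None = None,
    dose_mg_per_kg: float | None = None,
    infusion_duration_h: float | None = None,
    ka_per_h: float | None = None,
) -> DoseRegimen:
    """Build a :class:`DoseRegimen`, resolving per-kg doses against body weight."""
    if (dose_mg is None) == (dose_mg_per_kg is None):
        raise ParameterError("give exactly one of dose_mg or dose_mg_per_kg")
    if dose_mg_per_kg is not None:
        if dose_mg_per_kg <= 0:
            raise ParameterError("per-kg dose must be > 0")
        if physiology is None:
            raise ParameterError("per-kg dose needs a physiology (body weight)")
        dose_mg = dose_mg_per_kg * physiology.body_weight
    if dose_mg <= 0:
        raise ParameterError("dose must be > 0")
    return DoseRegimen(
        route=route,
        dose=dose_mg,
        infusion_duration=infusion_duration_h,
        ka=ka_per_h,
    )


# ---------------------------------------------------------------------------
# partition tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartitionSet:
    """Tissue -> Kp map (steady-state tissue:plasma concentration ratios)."""

    species: str
    kp: Mapping[str, float]
    source: str = "reference"
    #: guards the one-shot dog muscle adjustment against double application
    adjustments_applied: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        for tissue, value in self.kp.items():
            if value <= 0:
                raise ParameterError(f"Kp[{tissue}] = {value} must be > 0")

    def require(self, tissues: Iterable[str]) -> None:
        missing = [t for t in tissues if t not in self.kp]
        if missing:
            raise ParameterError(f"missing Kp for tissue(s): {missing}")

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "kp": dict(self.kp),
            "source": self.source,
            "adjustments_applied": list(self.adjustments_applied),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PartitionSet":
        return cls(
            species=d["species"],
            kp=dict(d["kp"]),
            source=d.get("source", "reference"),
            adjustments_applied=tuple(d.get("adjustments_applied", ())),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tissue": list(self.kp), "kp": list(self.kp.values())}
        ).assign(source=self.source)


def load_partition_table(species: str) -> PartitionSet:
    """Load an embedded reference Kp table (available for rat and human)."""
    if species not in ("rat", "human"):
        raise ParameterError(
            f"no embedded Kp table for {species!r}; build one via "
            "aztreonam_pbpk.partition.default_partition"
        )
    raw = _load_yaml(f"kp_{species}.yaml")
    return PartitionSet(
        species=raw["species"], kp=raw["kp"], source=raw["source"]
    )


# ---------------------------------------------------------------------------
# clearance defaults (data access; the model lives in .clearance)
# ---------------------------------------------------------------------------

def load_clearance_defaults() -> dict:
    return _load_yaml("clearance_defaults.yaml")


def load_reference_pk_parameters() -> pd.DataFrame:
    """Observed/predicted PK parameter pairs with printed error percentages."""
    with _data_file("reference_pk_parameters.csv").open("r") as fh:
        return pd.read_csv(fh, comment="#")


def roundtrip_json(obj) -> dict:
    """Serialize a parameter object to JSON text and back (lossless for floats)."""
    return json.loads(json.dumps(obj.to_dict()))
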