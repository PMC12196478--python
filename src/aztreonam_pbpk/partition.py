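"""Tissue:plasma partition coefficients.

Three pathways produce a :class:`~aztreonam_pbpk.parameters.PartitionSet`:

1. the embedded calibrated reference tables (rat, human) — the default;
2. de-novo prediction with the Rodgers-Rowland single-parameter method from
   log P, the pKa set and plasma binding;
3. interspecies translation of an existing table through the plasma
   protein-binding scaling rule
   ``Kp_target = (f_up_target / f_up_source) * (R_bp_source / R_bp_target) * Kp_source``.

A species-specific adjustment (+30% on dog muscle, reflecting the higher
muscle mass fraction of dogs) is applied once, guarded by an idempotence
flag. ``vss_from_kp`` synthesises the steady-state volume of distribution
from a Kp table and organ volumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd

from .parameters import (
    PERFUSED_TISSUES,
    CompoundProperties,
    ParameterError,
    PartitionSet,
    SpeciesPhysiology,
    load_partition_table,
)

PH_PLASMA = 7.4
PH_INTRACELLULAR = 7.0

DOG_MUSCLE_KP_FACTOR = 1.30
_DOG_MUSCLE_ADJUSTMENT = "dog_muscle_+30%"


# ---------------------------------------------------------------------------
# ionization
# ---------------------------------------------------------------------------

def ionized_fractions(pka_values, ph: float) -> dict:
    """Henderson-Hasselbalch speciation at the given pH.

    Returns ``{"neutral": f, "ionized": 1 - f}`` where ``f`` is the fraction
    of molecules with every ionisable group in its neutral state. Acids
    ionise above their pKa, bases below; groups are treated as independent.
    """
    if not (0 <= ph <= 14):
        raise ParameterError(f"pH {ph} outside [0, 14]")
    f_neutral = 1.0
    for entry in pka_values:
        kind = getattr(entry, "kind", None)
        if kind is None and isinstance(entry, Mapping):
            kind = entry.get("kind")
        value = getattr(entry, "value", None)
        if value is None and isinstance(entry, Mapping):
            value = entry.get("value")
        if kind == "acid":
            f_neutral *= 1.0 / (1.0 + 10.0 ** (ph - value))
        elif kind == "base":
            f_neutral *= 1.0 / (1.0 + 10.0 ** (value - ph))
        else:
            raise ParameterError(
                f"pKa entry {entry!r} lacks an acid/base annotation"
            )
    return {"neutral": f_neutral, "ionized": 1.0 - f_neutral}


# ---------------------------------------------------------------------------
# tissue composition + Rodgers-Rowland
# ---------------------------------------------------------------------------

#: plasma neutral-lipid / neutral-phospholipid volume fractions (rat)
PLASMA_F_NL = 0.0023
PLASMA_F_NP = 0.0013


@dataclass(frozen=True)
class TissueComposition:
    """Fractional composition of one tissue for partition prediction."""

    tissue: str
    f_ew: float            # extracellular water
    f_iw: float            # intracellular water
    f_nl: float            # neutral lipids
    f_np: float            # neutral phospholipids
    albumin_ratio: float   # tissue:plasma albumin concentration ratio

    def __post_init__(self):
        for name in ("f_ew", "f_iw", "f_nl", "f_np", "albumin_ratio"):
            v = getattr(self, name)
            if v < 0:
                raise ParameterError(f"{self.tissue}: {name} < 0")
        # rounded literature fractions can overshoot unity by well under 1%
        # (adipose sums to 1.0066); anything beyond that is a data error
        if self.f_ew + self.f_iw + self.f_nl + self.f_np > 1.01:
            raise ParameterError(
                f"{self.tissue}: water + lipid fractions exceed 1"
            )


def load_tissue_composition() -> dict[str, TissueComposition]:
    """Embedded rat tissue composition table, keyed by tissue name."""
    path = resources.files("aztreonam_pbpk.data").joinpath(
        "tissue_composition_rat.csv"
    )
    with path.open("r") as fh:
        df = pd.read_csv(fh, comment="#")
    return {
        row.tissue: TissueComposition(
            tissue=row.tissue,
            f_ew=row.f_ew,
            f_iw=row.f_iw,
            f_nl=row.f_nl,
            f_np=row.f_np,
            albumin_ratio=row.albumin_ratio,
        )
        for row in df.itertuples()
    }


def rodgers_rowland_kp(
    compound: CompoundProperties,
    composition: TissueComposition,
    species: str = "rat",
    log_p: float | None = None,
) -> float:
    """Single-parameter Rodgers-Rowland tissue:plasma partition coefficient.

    Applicable to acids, neutrals and weak bases: partitioning into tissue
    water (with Henderson-Hasselbalch ionisation at intracellular pH 7.0 vs
    plasma pH 7.4), dissolution of the neutral species into neutral lipids
    and phospholipids, and extracellular binding to albumin scaled by the
    tissue:plasma albumin ratio. Returns Kp on the tissue:plasma scale.

    ``log_p`` overrides the compound's octanol-water log P (used by the
    lipophilicity sensitivity scan).
    """
    f_up = compound.f_up_for(species)
    if log_p is None:
        log_p = compound.log_p
    p = 10.0 ** log_p
    fn_p = ionized_fractions(compound.pka_values, PH_PLASMA)["neutral"]
    fn_iw = ionized_fractions(compound.pka_values, PH_INTRACELLULAR)["neutral"]
    # fraction-of-total scalings: 1/Y = fn_p ; X/Y = fn_p / fn_iw
    lipid = p * composition.f_nl + (0.3 * p + 0.7) * composition.f_np
    lipid_plasma = p * PLASMA_F_NL + (0.3 * p + 0.7) * PLASMA_F_NP
    iw_term = (fn_p / fn_iw) * composition.f_iw if fn_iw > 0 else 0.0
    protein_assoc = max(0.0, 1.0 / f_up - 1.0 - lipid_plasma * fn_p)
    kpu = (
        composition.f_ew
        + iw_term
        + fn_p * lipid
        + composition.albumin_ratio * protein_assoc
    )
    kp = kpu * f_up
    if kp <= 0:
        raise ParameterError(f"{composition.tissue}: non-positive predicted Kp")
    return kp


def predict_partition(
    compound: CompoundProperties,
    species: str = "rat",
    log_p: float | None = None,
) -> PartitionSet:
    """De-novo Kp table for every perfused tissue via Rodgers-Rowland."""
    comps = load_tissue_composition()
    missing = [t for t in PERFUSED_TISSUES if t not in comps]
    if missing:
        raise ParameterError(f"composition missing for tissue(s): {missing}")
    kp = {
        t: rodgers_rowland_kp(compound, comps[t], species, log_p)
        for t in PERFUSED_TISSUES
    }
    return PartitionSet(species=species, kp=kp, source="rodgers_rowland")


# ---------------------------------------------------------------------------
# interspecies translation and adjustments
# ---------------------------------------------------------------------------

def scale_kp_cross_species(
    kp_source: float,
    f_up_source: float,
    f_up_target: float,
    r_bp_source: float,
    r_bp_target: float,
) -> float:
    """Translate one Kp across species for plasma protein-binding differences."""
    for name, v in (
        ("kp_source", kp_source),
        ("f_up_source", f_up_source),
        ("f_up_target", f_up_target),
        ("r_bp_source", r_bp_source),
        ("r_bp_target", r_bp_target),
    ):
        if v <= 0:
            raise ParameterError(f"{name} must be > 0, got {v}")
    return (f_up_target / f_up_source) * (r_bp_source / r_bp_target) * kp_source


def scale_partition_cross_species(
    partition: PartitionSet,
    compound: CompoundProperties,
    target_species: str,
) -> PartitionSet:
    """Translate a whole Kp table from its species to ``target_species``."""
    src = partition.species
    kp = {
        t: scale_kp_cross_species(
            v,
            compound.f_up_for(src),
            compound.f_up_for(target_species),
            compound.r_bp_for(src),
            compound.r_bp_for(target_species),
        )
        for t, v in partition.kp.items()
    }
    return PartitionSet(species=target_species, kp=kp, source="scaled")


def apply_species_adjustments(partition: PartitionSet) -> PartitionSet:
    """Apply per-species Kp corrections (dog muscle +30%), at most once."""
    if partition.species != "dog":
        return partition
    if _DOG_MUSCLE_ADJUSTMENT in partition.adjustments_applied:
        return partition
    kp = dict(partition.kp)
    if "muscle" not in kp:
        raise ParameterError("dog partition set lacks a muscle Kp")
    kp["muscle"] = kp["muscle"] * DOG_MUSCLE_KP_FACTOR
    return PartitionSet(
        species="dog",
        kp=kp,
        source="adjusted",
        adjustments_applied=partition.adjustments_applied
        + (_DOG_MUSCLE_ADJUSTMENT,),
    )


def default_partition(
    species: str,
    compound: CompoundProperties,
    kp_source: str = "reference",
) -> PartitionSet:
    """Species default Kp table.

    ``reference`` uses the embedded calibrated table where one exists (rat,
    human) and otherwise falls back to rat scaled across species;
    ``scaled_from_rat`` always translates the rat table;
    ``rodgers_rowland`` predicts de novo. Dog tables then receive the
    muscle adjustment.
    """
    if kp_source == "rodgers_rowland":
        part = predict_partition(compound, species)
    elif kp_source == "scaled_from_rat" or (
        kp_source == "reference" and species not in ("rat", "human")
    ):
        part = scale_partition_cross_species(
            load_partition_table("rat"), compound, species
        )
    elif kp_source == "reference":
        part = load_partition_table(species)
    else:
        raise ParameterError(f"unknown kp_source {kp_source!r}")
    return apply_species_adjustments(part)


# ---------------------------------------------------------------------------
# Vss synthesis
# ---------------------------------------------------------------------------

def vss_from_kp(
    partition: PartitionSet,
    physiology: SpeciesPhysiology,
    r_bp: float,
) -> float:
    """Plasma-referenced steady-state volume of distribution (L).

    Vss = R_bp x (V_arterial + V_venous) + sum_t Kp_t x V_t over perfused
    tissues: at steady state the amount in a blood pool is
    C_plasma x R_bp x V_blood, so its plasma-equivalent volume is
    R_bp x V_blood; each tissue contributes Kp x V.
    """
    if r_bp <= 0:
        raise ParameterError("r_bp must be > 0")
    comps = physiology.compartments
    partition.require(
        [t for t in PERFUSED_TISSUES if comps[t].volume > 0]
    )
    blood = r_bp * (comps["arterial"].volume + comps["venous"].volume)
    tissue = sum(
        partition.kp[t] * comps[t].volume
        for t in PERFUSED_TISSUES
        if comps[t].volume > 0
    )
    return blood + tissue
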