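"""Clearance model: mechanistic renal filtration, calibration of the
renal/hepatic/biliary split to a target total, and allometric interspecies
scaling.

Aztreonam is eliminated predominantly unchanged in urine; renal clearance is
modelled as passive filtration of unbound drug (f_up x GFR). Hepatic
clearance absorbs the remainder of the calibrated total, with a fixed
fraction (default 10%) of the hepatic route assigned to biliary excretion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Mapping

from .parameters import (
    CompoundProperties,
    ParameterError,
    SpeciesPhysiology,
    load_clearance_defaults,
)

DEFAULT_BILIARY_FRACTION = 0.10
DEFAULT_ALLOMETRIC_EXPONENT = 0.75
ALLOMETRIC_EXPONENT_BAND = (0.6, 0.8)


@dataclass(frozen=True)
class ClearanceSpec:
    """Plasma-referenced clearances (L/h) by elimination route."""

    cl_renal: float
    cl_hep: float
    cl_bil: float
    biliary_fraction: float = DEFAULT_BILIARY_FRACTION
    provenance: str = "calibrated"

    def __post_init__(self):
        for name in ("cl_renal", "cl_hep", "cl_bil"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    @property
    def total(self) -> float:
        return self.cl_renal + self.cl_hep + self.cl_bil

    def to_dict(self) -> dict:
        d = asdict(self)
        d["total"] = self.total
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClearanceSpec":
        d = {k: v for k, v in d.items() if k != "total"}
        return cls(**d)


def renal_clearance(f_up: float, gfr: float) -> float:
    """Renal filtration clearance of unbound drug: f_up x GFR (L/h)."""
    if not (0 <= f_up <= 1):
        raise ParameterError(f"f_up = {f_up} outside [0, 1]")
    if gfr < 0:
        raise ParameterError("gfr must be >= 0")
    return f_up * gfr


def calibrate_to_total(
    target_cl_total: float,
    f_up: float,
    gfr: float,
    biliary_fraction: float = DEFAULT_BILIARY_FRACTION,
) -> ClearanceSpec:
    """Split a target total plasma clearance into renal/hepatic/biliary.

    The renal component keeps its mechanistic value (f_up x GFR, capped at
    the target); the remainder is hepatic, of which ``biliary_fraction``
    is excreted in bile. The components sum to the target exactly.
    """
    if target_cl_total <= 0:
        raise ParameterError("target_cl_total must be > 0")
    if not (0 <= biliary_fraction < 1):
        raise ParameterError("biliary_fraction must be in [0, 1)")
    cl_renal = min(renal_clearance(f_up, gfr), target_cl_total)
    remainder = target_cl_total - cl_renal
    cl_hep = remainder / (1.0 + biliary_fraction)
    cl_bil = remainder - cl_hep  # == biliary_fraction * cl_hep, sums exactly
    return ClearanceSpec(
        cl_renal=cl_renal,
        cl_hep=cl_hep,
        cl_bil=cl_bil,
        biliary_fraction=biliary_fraction,
        provenance="calibrated",
    )


def mechanistic_clearance(
    physiology: SpeciesPhysiology,
    compound: CompoundProperties,
    cl_hep: float = 0.0,
    biliary_fraction: float = DEFAULT_BILIARY_FRACTION,
) -> ClearanceSpec:
    """Purely mechanistic spec: renal = f_up x GFR, hepatic as given."""
    cl_renal = renal_clearance(
        compound.f_up_for(physiology.species), physiology.gfr
    )
    return ClearanceSpec(
        cl_renal=cl_renal,
        cl_hep=cl_hep,
        cl_bil=biliary_fraction * cl_hep,
        biliary_fraction=biliary_fraction,
        provenance="mechanistic",
    )


def allometric_scale(
    cl_ref: float,
    weight_ref: float,
    weight_target: float,
    exponent: float = DEFAULT_ALLOMETRIC_EXPONENT,
) -> float:
    """Power-law interspecies clearance scaling: CL x (W_t / W_ref)^b.

    Exponents outside the conventional 0.6-0.8 band are allowed with a
    warning (b = 1 recovers direct proportionality to body weight).
    """
    if weight_ref <= 0 or weight_target <= 0:
        raise ParameterError("body weights must be > 0")
    lo, hi = ALLOMETRIC_EXPONENT_BAND
    if not (lo <= exponent <= hi):
        warnings.warn(
            f"allometric exponent {exponent} outside the conventional "
            f"[{lo}, {hi}] band",
            stacklevel=2,
        )
    return cl_ref * (weight_target / weight_ref) ** exponent


def default_clearance(
    physiology: SpeciesPhysiology,
    compound: CompoundProperties,
    provenance: str = "calibrated",
    allometric_reference: tuple[float, float] | None = None,
    exponent: float | None = None,
) -> ClearanceSpec:
    """Build the species clearance spec by provenance.

    - ``calibrated``: renal/hepatic/biliary split constrained to the
      species' calibrated total (the embedded default).
    - ``mechanistic``: renal = f_up x GFR only, no hepatic route.
    - ``allometric``: total scaled from a reference ``(cl_ref, weight_ref)``
      pair (default: the calibrated rat total at 0.25 kg), then split as in
      the calibrated case.
    """
    defaults = load_clearance_defaults()
    species = physiology.species
    f_up = compound.f_up_for(species)
    bf = defaults.get("biliary_fraction", DEFAULT_BILIARY_FRACTION)
    if provenance == "mechanistic":
        return mechanistic_clearance(physiology, compound, 0.0, bf)
    if provenance == "calibrated":
        try:
            target = defaults["cl_total_L_per_h"][species]
        except KeyError:
            raise ParameterError(
                f"no calibrated total clearance for species {species!r}"
            ) from None
        return calibrate_to_total(target, f_up, physiology.gfr, bf)
    if provenance == "allometric":
        if allometric_reference is None:
            allometric_reference = (defaults["cl_total_L_per_h"]["rat"], 0.25)
        cl_ref, w_ref = allometric_reference
        if exponent is None:
            exponent = defaults.get(
                "allometric_exponent", DEFAULT_ALLOMETRIC_EXPONENT
            )
        total = allometric_scale(cl_ref, w_ref, physiology.body_weight, exponent)
        spec = calibrate_to_total(total, f_up, physiology.gfr, bf)
        return ClearanceSpec(
            cl_renal=spec.cl_renal,
            cl_hep=spec.cl_hep,
            cl_bil=spec.cl_bil,
            biliary_fraction=bf,
            provenance="allometric",
        )
    raise ParameterError(f"unknown clearance provenance {provenance!r}")
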