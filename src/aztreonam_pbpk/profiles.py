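"""Concentration-time profiles: the tidy in-memory/CSV interchange object
shared by the simulator, the NCA, the evaluation metrics and the synthetic
study generator."""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import ParameterError


@dataclass
class ConcentrationTimeProfile:
    """Time-stamped concentrations with censoring flags and dose metadata.

    Concentrations are mg/L (ug/mL); ``bql`` flags points below the assay's
    lower limit of quantification (their stored value is the uncensored one
    when known, or 0).
    """

    time: np.ndarray            # h
    concentration: np.ndarray   # mg/L
    bql: np.ndarray | None = None
    dose: float | None = None   # mg
    species: str | None = None
    compartment: str = "plasma"
    lloq: float | None = None   # mg/L
    subject: str | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.time.shape != self.concentration.shape:
            raise ParameterError("time and concentration lengths differ")
        if self.time.size < 2:
            raise ParameterError("a profile needs at least 2 points")
        if np.any(np.diff(self.time) <= 0):
            raise ParameterError("times must be strictly increasing")
        if np.any(self.concentration < 0):
            raise ParameterError("negative concentrations")
        if self.bql is None:
            self.bql = np.zeros(self.time.shape, dtype=bool)
        else:
            self.bql = np.asarray(self.bql, dtype=bool)
            if self.bql.shape != self.time.shape:
                raise ParameterError("bql flag length differs from times")

    def quantifiable(self) -> "ConcentrationTimeProfile":
        """Drop BQL points (keeps metadata); needs >= 2 surviving points."""
        keep = ~self.bql
        if keep.sum() < 2:
            raise ParameterError("fewer than 2 quantifiable points")
        return ConcentrationTimeProfile(
            time=self.time[keep],
            concentration=self.concentration[keep],
            dose=self.dose,
            species=self.species,
            compartment=self.compartment,
            lloq=self.lloq,
            subject=self.subject,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_h": self.time,
                "compartment": self.compartment,
                "concentration_mg_per_L": self.concentration,
                "bql": self.bql,
            }
        )
        if self.dose is not None:
            df["dose_mg"] = self.dose
        if self.species is not None:
            df["species"] = self.species
        if self.subject is not None:
            df["subject"] = self.subject
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConcentrationTimeProfile":
        return cls(
            time=df["time_h"].to_numpy(),
            concentration=df["concentration_mg_per_L"].to_numpy(),
            bql=df["bql"].to_numpy() if "bql" in df else None,
            dose=float(df["dose_mg"].iloc[0]) if "dose_mg" in df else None,
            species=str(df["species"].iloc[0]) if "species" in df else None,
            compartment=(
                str(df["compartment"].iloc[0]) if "compartment" in df else "plasma"
            ),
            subject=str(df["subject"].iloc[0]) if "subject" in df else None,
        )

    @classmethod
    def from_csv(cls, path) -> "ConcentrationTimeProfile":
        return cls.from_frame(pd.read_csv(path))
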