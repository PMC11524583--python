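"""Validated domain records for the Transwell permeability pipeline.

All concentrations are stored in µmol/L, volumes in mL (≡ cm³), membrane
areas in cm², times in seconds and permeabilities in cm/s.  Records are
immutable pydantic models so that a value validated once cannot drift as
it moves through the pipeline.
"""

from __future__ import annotations

import enum
import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


class QcFlag(str, enum.Enum):
    """Quality-control annotations attached to derived results."""

    NON_SINK = "NON_SINK"
    OVER_EQUILIBRIUM = "OVER_EQUILIBRIUM"
    LOW_N = "LOW_N"
    LOW_BARRIER = "LOW_BARRIER"
    NEGATIVE_TEER = "NEGATIVE_TEER"
    OUT_OF_BAND = "OUT_OF_BAND"


class TransportRecord(BaseModel):
    """One receiver-side measurement from a single Transwell insert.

    A single apical→basolateral transport experiment: the donor chamber
    starts at ``c0_donor``, and after ``t_sample`` seconds the receiver
    chamber concentration ``c_receiver`` is measured.
    """

    model_config = ConfigDict(frozen=True)

    drug_id: str
    model_id: str
    replicate: int = Field(ge=1)
    t_sample: float = Field(gt=0, description="sampling time, s")
    c0_donor: float = Field(gt=0, description="initial donor concentration, µmol/L")
    c_receiver: float = Field(ge=0, description="receiver concentration at t_sample, µmol/L")
    v_receiver: float = Field(gt=0, description="receiver volume, mL")
    v_donor: float = Field(gt=0, description="donor volume, mL")
    membrane_area: float = Field(gt=0, description="insert membrane area, cm²")

    @property
    def equilibrium_bound(self) -> float:
        """Receiver concentration at passive equilibrium, µmol/L."""
        return self.c0_donor * self.v_donor / (self.v_donor + self.v_receiver)

    @property
    def over_equilibrium(self) -> bool:
        """True when the measurement exceeds the passive-equilibrium bound.

        Flagged rather than rejected: assay noise can push a near-equilibrated
        measurement past the bound without invalidating the record.
        """
        return self.c_receiver > self.equilibrium_bound

    @property
    def fraction_transported(self) -> float:
        """Fraction of the dosed amount found in the receiver chamber."""
        return (self.c_receiver * self.v_receiver) / (self.c0_donor * self.v_donor)


class DrugRecord(BaseModel):
    """Literature-side data for one drug: brain unbound fraction and
    the observed in vivo permeability-surface-area product."""

    model_config = ConfigDict(frozen=True)

    drug_id: str
    fu_brain: float = Field(gt=0, le=1, description="unbound fraction in brain")
    ps_obs: float = Field(gt=0, description="observed in vivo PS, µL/min/g brain")
    ps_obs_source: str = ""


class TeerRecord(BaseModel):
    """Raw chopstick-electrode resistance reading from one insert on one day."""

    model_config = ConfigDict(frozen=True)

    insert_id: str
    model_id: str
    day: int = Field(ge=0)
    resistance_raw: float = Field(gt=0, description="raw resistance, Ω")
    is_blank: bool = False
    membrane_area: float = Field(gt=0, description="insert membrane area, cm²")


class TeerValue(BaseModel):
    """Per-model, per-day summary of blank-corrected TEER (Ω·cm²)."""

    model_config = ConfigDict(frozen=True)

    model_id: str
    day: int
    teer_mean: float
    teer_sem: float = Field(ge=0)
    n: int = Field(ge=1)
    raw_mean: Optional[float] = None
    flags: frozenset[QcFlag] = frozenset()

    @model_validator(mode="after")
    def _sem_zero_for_singleton(self) -> "TeerValue":
        if self.n == 1 and self.teer_sem != 0:
            raise ValueError("SEM must be 0 when n = 1")
        return self


class PappResult(BaseModel):
    """Per-drug, per-model apparent permeability with replicate statistics."""

    model_config = ConfigDict(frozen=True)

    drug_id: str
    model_id: str
    papp_mean: float = Field(ge=0, description="mean apparent permeability, cm/s")
    papp_sem: float = Field(ge=0, description="SEM of replicate Papp values, cm/s")
    n: int = Field(ge=1)
    fraction_transported: float = Field(ge=0)
    qc_flags: frozenset[QcFlag] = frozenset()


class IvivcResult(BaseModel):
    """One drug's predicted-vs-observed PS comparison."""

    model_config = ConfigDict(frozen=True)

    drug_id: str
    model_id: str
    ps_pre: float = Field(description="predicted PS, µL/min/g")
    ps_obs: float = Field(gt=0, description="observed PS, µL/min/g")
    fold_ratio: float
    within_2fold: bool


class IvivcSummary(BaseModel):
    """Per-model prediction accuracy: success count plus geometric fold errors.

    ``afe`` is the average fold error 10^mean(log10 ratio) and ``aafe`` the
    absolute average fold error 10^mean(|log10 ratio|); AAFE ≥ 1 always.
    """

    model_config = ConfigDict(frozen=True)

    model_id: str
    n_total: int = Field(ge=0)
    n_success: int = Field(ge=0)
    afe: float = Field(gt=0)
    aafe: float = Field(ge=1)

    @model_validator(mode="after")
    def _success_within_total(self) -> "IvivcSummary":
        if self.n_success > self.n_total:
            raise ValueError("n_success cannot exceed n_total")
        return self


class CtRecord(BaseModel):
    """One qPCR cycle-threshold measurement."""

    model_config = ConfigDict(frozen=True)

    sample_id: str
    gene_id: str
    ct: float = Field(gt=0)
    reference_gene: str = ""
    calibrator_sample: str = ""

    @field_validator("ct")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ValueError("Ct must be finite")
        return v


class RegressionFit(BaseModel):
    """Ordinary least-squares fit between two experimental variables."""

    model_config = ConfigDict(frozen=True)

    slope: float
    intercept: float
    r_squared: float = Field(ge=0, le=1)
    p_value: float = Field(gt=0, le=1)
    n: int = Field(ge=3)


class SimSpec(BaseModel):
    """Parameterization of one synthetic Transwell transport experiment.

    Defaults reflect a 24-well format insert (0.33 cm² membrane, 0.1 mL
    apical donor, 0.6 mL basolateral receiver) dosed at 10 µmol/L and
    sampled on a 30-minute grid.
    """

    model_config = ConfigDict(frozen=True)

    true_papp: float = Field(gt=0, description="true membrane permeability, cm/s")
    membrane_area: float = Field(default=0.33, gt=0)
    v_donor: float = Field(default=0.1, gt=0, description="mL")
    v_receiver: float = Field(default=0.6, gt=0, description="mL")
    c0: float = Field(default=10.0, gt=0, description="µmol/L")
    t_grid: tuple[float, ...] = (1800.0,)
    noise_cv: float = Field(default=0.05, ge=0)
    seed: int = 0

    @field_validator("t_grid")
    @classmethod
    def _strictly_increasing(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        arr = np.asarray(v, dtype=float)
        if arr.size == 0 or arr[0] < 0 or np.any(np.diff(arr) <= 0):
            raise ValueError("t_grid must be non-empty, start ≥ 0 and strictly increase")
        return v


class CohortSpec(BaseModel):
    """Parameterization of a synthetic drug cohort for end-to-end testing.

    Dispersion defaults emulate the spread seen across a small CNS drug
    panel: Papp roughly 3–40 ×10⁻⁶ cm/s and fu_brain 0.004–0.8.
    ``ivivc_fold_sd`` is the SD of the log10 prediction error linking true
    predicted PS to the noisy "observed" in vivo PS.
    """

    model_config = ConfigDict(frozen=True)

    n_drugs: int = Field(default=18, ge=1)
    log10_papp_mean: float = -4.92
    log10_papp_sd: float = Field(default=0.28, ge=0)
    log10_fu_mean: float = -1.2
    log10_fu_sd: float = Field(default=0.6, ge=0)
    ivivc_fold_sd: float = Field(default=0.25, ge=0)
    n_replicates: int = Field(default=4, ge=1)
    noise_cv: float = Field(default=0.05, ge=0)
    t_sample: float = Field(default=1800.0, gt=0)
    membrane_area: float = Field(default=0.33, gt=0)
    v_donor: float = Field(default=0.1, gt=0)
    v_receiver: float = Field(default=0.6, gt=0)
    c0: float = Field(default=10.0, gt=0)
    vsa: float = Field(default=150.0, gt=0)
    seed: int = 0
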