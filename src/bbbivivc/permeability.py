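"""Apparent permeability coefficients from single-timepoint Transwell assays.

The estimator is the standard sink-condition formula

    Papp = (Q / t) / (S · C0)        [cm/s]

with Q = C_receiver · V_receiver the amount found in the receiver chamber
at the sampling time t (conventionally 1800 s), S the insert membrane area
and C0 the nominal initial donor concentration.  With concentrations in
µmol/L, volumes in mL (= cm³) and area in cm² the units cancel to cm/s
directly.  The estimator assumes sink conditions; the QC flags below mark
where that assumption is strained.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .records import PappResult, QcFlag, TransportRecord

__all__ = [
    "compute_papp_single",
    "aggregate_papp",
    "recovery_check",
    "DEFAULT_SINK_THRESHOLD",
    "DEFAULT_RECOVERY_BAND",
]

DEFAULT_SINK_THRESHOLD = 0.10
DEFAULT_RECOVERY_BAND = (0.8, 1.2)


def compute_papp_single(record: TransportRecord) -> float:
    """Apparent permeability (cm/s) from one receiver-side measurement."""
    if record.c0_donor == 0:
        raise ZeroDivisionError("C0 = 0: permeability undefined")
    q = record.c_receiver * record.v_receiver  # amount ∝ concentration × volume
    return q / (record.t_sample * record.membrane_area * record.c0_donor)


def aggregate_papp(
    records: Sequence[TransportRecord],
    sink_threshold: float = DEFAULT_SINK_THRESHOLD,
    low_n: int = 3,
) -> PappResult:
    """Replicate mean ± SEM of Papp for one drug/model group.

    Each replicate's Papp is computed first and the statistics taken over
    those per-replicate values (SEM = sample SD / √n).  QC flags:

    - ``NON_SINK`` — mean fraction transported exceeds ``sink_threshold``
      (default 0.10), so the constant-flux approximation is doubtful;
    - ``OVER_EQUILIBRIUM`` — any replicate exceeds the passive equilibrium
      concentration bound;
    - ``LOW_N`` — fewer than ``low_n`` replicates.
    """
    if not records:
        raise ValueError("no transport records to aggregate")
    first = records[0]
    for rec in records[1:]:
        if rec.drug_id != first.drug_id or rec.model_id != first.model_id:
            raise ValueError("records mix drugs or models")
        if (
            rec.membrane_area != first.membrane_area
            or rec.v_receiver != first.v_receiver
            or rec.v_donor != first.v_donor
            or rec.t_sample != first.t_sample
        ):
            raise ValueError("records mix insert geometries or sampling times")

    papps = np.array([compute_papp_single(r) for r in records], dtype=float)
    fractions = np.array([r.fraction_transported for r in records], dtype=float)
    n = papps.size
    sem = float(np.std(papps, ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    flags = set()
    if fractions.mean() > sink_threshold:
        flags.add(QcFlag.NON_SINK)
    if any(r.over_equilibrium for r in records):
        flags.add(QcFlag.OVER_EQUILIBRIUM)
    if n < low_n:
        flags.add(QcFlag.LOW_N)

    return PappResult(
        drug_id=first.drug_id,
        model_id=first.model_id,
        papp_mean=float(papps.mean()),
        papp_sem=sem,
        n=int(n),
        fraction_transported=float(fractions.mean()),
        qc_flags=frozenset(flags),
    )


def recovery_check(
    record: TransportRecord,
    c_donor_final: float,
    band: tuple[float, float] = DEFAULT_RECOVERY_BAND,
) -> tuple[float, frozenset]:
    """Mass-balance recovery and an out-of-band flag.

    recovery = (C_donor,final·V_donor + C_receiver·V_receiver) / (C0·V_donor);
    values outside ``band`` (default 0.8–1.2) flag adsorption, metabolism or
    dosing error.  QC only — never raises on poor recovery.
    """
    if c_donor_final < 0:
        raise ValueError("final donor concentration cannot be negative")
    recovered = c_donor_final * record.v_donor + record.c_receiver * record.v_receiver
    recovery = recovered / (record.c0_donor * record.v_donor)
    lo, hi = band
    flags = frozenset() if lo <= recovery <= hi else frozenset({QcFlag.OUT_OF_BAND})
    return recovery, flags
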