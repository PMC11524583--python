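"""In vitro → in vivo extrapolation of blood–brain barrier permeability.

An in vitro apparent permeability Papp (cm/s) is scaled to a predicted
in vivo permeability-surface-area product per gram of brain:

    PS_pre = Papp · 60 · VSA · 1000 / fu_brain      [µL/min/g]

where VSA is the luminal vascular surface area of brain tissue (150 cm²/g
by convention) and fu_brain the unbound fraction in brain; the factor 60
converts cm/s to cm/min and the factor 1000 mL to µL.  A prediction is
judged successful when it falls within 0.5–2-fold of the observed in situ
brain-perfusion PS (bounds inclusive).
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np

from .records import DrugRecord, IvivcResult, IvivcSummary

__all__ = [
    "DEFAULT_VSA",
    "FOLD_BOUNDS",
    "predict_ps",
    "unify_ps_obs",
    "classify_fold",
    "evaluate_model",
    "summarize_model",
    "failure_set",
    "brain_plasma_ratio",
]

DEFAULT_VSA = 150.0  # cm²/g, luminal vascular surface area of brain
FOLD_BOUNDS = (0.5, 2.0)


def predict_ps(papp: float, fu_brain: float, vsa: float = DEFAULT_VSA) -> float:
    """Predicted in vivo PS (µL/min/g) from in vitro Papp (cm/s)."""
    if fu_brain <= 0:
        raise ValueError("fu_brain must be positive")
    if papp < 0:
        raise ValueError("Papp cannot be negative")
    if vsa <= 0:
        raise ValueError("VSA must be positive")
    return papp * 60.0 * vsa * 1000.0 / fu_brain


def unify_ps_obs(published_permeability: float, vsa: float = DEFAULT_VSA) -> float:
    """Unify a published per-area in vivo permeability to PS (µL/min/g)
    by multiplying with the brain vascular surface area."""
    if published_permeability <= 0:
        raise ValueError("published permeability must be positive")
    return published_permeability * vsa


def classify_fold(
    ps_pre: float,
    ps_obs: float,
    lower: float = FOLD_BOUNDS[0],
    upper: float = FOLD_BOUNDS[1],
) -> tuple[float, bool]:
    """Fold ratio predicted/observed and whether it lies in [lower, upper]."""
    if ps_obs <= 0:
        raise ValueError("observed PS must be positive")
    if not 0 < lower < upper:
        raise ValueError("bounds must satisfy 0 < lower < upper")
    ratio = ps_pre / ps_obs
    return ratio, lower <= ratio <= upper


def evaluate_model(
    drugs: Sequence[DrugRecord],
    papp_by_drug: Mapping[str, float],
    model_id: str,
    vsa: float = DEFAULT_VSA,
    bounds: tuple[float, float] = FOLD_BOUNDS,
) -> list[IvivcResult]:
    """Predict and classify PS for every drug with a Papp in ``papp_by_drug``.

    ``papp_by_drug`` maps drug_id to the replicate-mean Papp in cm/s; the
    mean (not per-replicate values) feeds the scaling, giving one prediction
    per drug and model.
    """
    results = []
    for drug in drugs:
        if drug.drug_id not in papp_by_drug:
            continue
        ps_pre = predict_ps(papp_by_drug[drug.drug_id], drug.fu_brain, vsa)
        ratio, within = classify_fold(ps_pre, drug.ps_obs, *bounds)
        results.append(
            IvivcResult(
                drug_id=drug.drug_id,
                model_id=model_id,
                ps_pre=ps_pre,
                ps_obs=drug.ps_obs,
                fold_ratio=ratio,
                within_2fold=within,
            )
        )
    return results


def summarize_model(results: Sequence[IvivcResult]) -> IvivcSummary:
    """Success count plus geometric fold-error summaries for one model.

    AFE = 10^mean(log10 ratio) measures systematic bias; AAFE =
    10^mean(|log10 ratio|) measures spread and is ≥ 1 by construction.
    """
    if not results:
        raise ValueError("no results to summarize")
    model_ids = {r.model_id for r in results}
    if len(model_ids) > 1:
        raise ValueError(f"results span multiple models: {sorted(model_ids)}")
    logs = np.log10([r.fold_ratio for r in results])
    return IvivcSummary(
        model_id=results[0].model_id,
        n_total=len(results),
        n_success=sum(r.within_2fold for r in results),
        afe=float(10 ** logs.mean()),
        aafe=float(10 ** np.abs(logs).mean()),
    )


def failure_set(results: Sequence[IvivcResult]) -> list[str]:
    """Drugs whose prediction missed the fold window, worst first
    (descending |log10 fold ratio|)."""
    failures = [r for r in results if not r.within_2fold]
    failures.sort(key=lambda r: -abs(math.log10(r.fold_ratio)))
    return [r.drug_id for r in failures]


def brain_plasma_ratio(c_brain, c_plasma):
    """Elementwise brain-to-plasma concentration ratio (Kp).

    Accepts scalars or equal-length array-likes; plasma concentrations must
    be strictly positive.
    """
    c_brain = np.asarray(c_brain, dtype=float)
    c_plasma = np.asarray(c_plasma, dtype=float)
    if c_brain.shape != c_plasma.shape:
        raise ValueError("brain and plasma inputs must have matching shapes")
    if np.any(c_plasma <= 0):
        raise ValueError("plasma concentration must be positive")
    ratio = c_brain / c_plasma
    return float(ratio) if ratio.ndim == 0 else ratio
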