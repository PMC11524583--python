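"""Expression-side computations: comparative-Ct qPCR normalization and
simple linear regression between permeability and protein expression."""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .records import CtRecord, RegressionFit

__all__ = ["ddct_fold_change", "average_technical_replicates", "linear_correlation"]


def ddct_fold_change(
    target_ct: float, ref_ct: float, calib_target_ct: float, calib_ref_ct: float
) -> float:
    """Relative expression by the comparative cycle-threshold (ΔΔCt) method.

    ΔΔCt = (target − reference) − (calibrator target − calibrator reference);
    relative expression is 2^(−ΔΔCt), assuming an amplification efficiency
    of exactly 2 per cycle.  Adding a constant to every Ct cancels out.
    """
    for ct in (target_ct, ref_ct, calib_target_ct, calib_ref_ct):
        if not np.isfinite(ct) or ct <= 0:
            raise ValueError("Ct values must be positive and finite")
    ddct = (target_ct - ref_ct) - (calib_target_ct - calib_ref_ct)
    return float(2.0 ** (-ddct))


def average_technical_replicates(records: Iterable[CtRecord]) -> dict[tuple[str, str], float]:
    """Mean Ct per (sample, gene); technical replicates are averaged on the
    Ct scale before any ΔΔCt arithmetic, the conventional order."""
    groups: dict[tuple[str, str], list[float]] = defaultdict(list)
    for rec in records:
        groups[(rec.sample_id, rec.gene_id)].append(rec.ct)
    return {key: float(np.mean(v)) for key, v in groups.items()}


def linear_correlation(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Ordinary least-squares fit of y on x with r² and a two-sided p-value
    for a nonzero slope.

    Requires at least 3 points and a non-constant predictor.  For a
    mathematically exact linear relationship the p-value degenerates to the
    numerical floor; it is clipped into (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 points for a regression p-value")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: regression is degenerate")
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=min(max(r2, 0.0), 1.0),
        p_value=min(max(float(fit.pvalue), np.finfo(float).tiny), 1.0),
        n=int(x.size),
    )
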