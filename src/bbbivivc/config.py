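"""Run configuration: assay geometry defaults, QC thresholds and scaling constants.

The defaults encode the study design this pipeline targets: 30-minute
(1800 s) single-timepoint sampling on 6.5 mm inserts (0.33 cm²), a brain
vascular surface area of 150 cm²/g for in vitro → in vivo scaling, and the
0.5–2-fold success criterion.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class RunConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    # assay geometry defaults (applied when an input table omits a column)
    t_sample_s: float = Field(default=1800.0, gt=0)
    membrane_area_cm2: float = Field(default=0.33, gt=0)
    v_donor_ml: float = Field(default=0.1, gt=0)
    v_receiver_ml: float = Field(default=0.6, gt=0)

    # QC thresholds
    sink_threshold: float = Field(default=0.10, gt=0, le=1)
    recovery_band: tuple[float, float] = (0.8, 1.2)

    # in vitro → in vivo scaling
    vsa_cm2_per_g: float = Field(default=150.0, gt=0)
    fold_lower: float = Field(default=0.5, gt=0)
    fold_upper: float = Field(default=2.0, gt=0)

    # I/O
    output_precision: int = Field(default=2, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _bounds_ordered(self) -> "RunConfig":
        if not self.fold_lower < self.fold_upper:
            raise ValueError("fold_lower must be < fold_upper")
        lo, hi = self.recovery_band
        if not 0 < lo < hi:
            raise ValueError("recovery_band must satisfy 0 < lower < upper")
        return self


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a :class:`RunConfig` from YAML, or return defaults when ``path`` is None."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "recovery_band" in data:
        data["recovery_band"] = tuple(data["recovery_band"])
    return RunConfig(**data)


def dump_config(config: RunConfig, path: str | Path) -> Path:
    """Serialize the effective configuration next to a run's outputs."""
    path = Path(path)
    data = config.model_dump()
    data["recovery_band"] = list(data["recovery_band"])
    path.write_text(yaml.safe_dump(data, sort_keys=True))
    return path
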