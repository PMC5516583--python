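"""Pipeline configuration: every processing default in one validated object."""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field


class PipelineConfig(BaseModel):
    """All tunable pipeline defaults; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    # preprocessing
    broadening_edited_hz: float = 3.0
    broadening_press_hz: float = 1.1
    zero_fill_factor: int = 2
    water_band_ppm: tuple[float, float] = (4.4, 5.0)

    # edited fitting
    fit_window_ppm: tuple[float, float] = (2.6, 3.3)
    cr_window_ppm: tuple[float, float] = (2.6, 3.3)
    gauss_centers_ppm: tuple[float, ...] = (2.82, 2.95, 3.01, 3.10, 3.26)
    center_bound_ppm: float = 0.03
    editing_efficiency: float = Field(0.74, gt=0, le=1)
    gsh_model: str = "five"            # "five" or "single"
    detection_snr: float = 4.0
    fit_error_ceiling_pct: float = 150.0

    # PRESS QC
    qc_linewidth_max_ppm: float = 0.1
    qc_snr_min: float = 5.0
    qc_crlb_max_pct: float = 20.0

    # cohort / statistics
    impute_baselines: bool = True
    percent_change_convention: str = "ratio_of_means"
    n_blocks: int = 40
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.model_dump(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))
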