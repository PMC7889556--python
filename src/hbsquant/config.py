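"""Pipeline configuration with YAML round-trip and provenance hashing."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator


class PipelineConfig(BaseModel):
    """All tunable settings of the quantification pipeline.

    Defaults reflect standard clinical practice: the 150-350 s
    measurement window, pixel-pixel geometric mean for TL-F and
    ROI-ROI for TL-U, the two-point uptake estimator, inclusive
    low-is-positive cutoffs, and institution-default lab limits.
    """

    window_start_s: float = 150.0
    window_end_s: float = 350.0
    tl_f_gmean_mode: str = Field("pixel", pattern="^(pixel|roi)$")
    tl_u_gmean_mode: str = Field("roi", pattern="^(pixel|roi)$")
    tl_f_estimator: str = Field("two-point", pattern="^(two-point|slope)$")
    tl_u_definition: str = Field("endpoint", pattern="^(endpoint|window-mean)$")
    mirror_posterior: bool = True
    decay_correction: bool = False
    inr_upper_normal: float = 1.2
    bilirubin_upper_normal_umol: float = 20.5
    low_is_positive: bool = True
    liver_density_g_ml: float = 1.00
    seed: int = 0
    report_decimals: int = 1

    @model_validator(mode="after")
    def _check_window(self) -> "PipelineConfig":
        if not 0 <= self.window_start_s < self.window_end_s:
            raise ValueError("need 0 <= window_start_s < window_end_s")
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))
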