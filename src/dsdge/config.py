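"""Run configuration, validation and provenance for the command line."""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

from pydantic import BaseModel, Field, field_validator

from . import __version__


class PulseTrainConfig(BaseModel):
    shape: str = "sinc_gauss"
    n_pulses: int = Field(10, ge=1)
    pulse_duration_s: float = Field(0.050, gt=0)
    b1_peak_uT: float = Field(0.5, ge=0)
    interpulse_delay_s: float = Field(0.0, ge=0)
    samples_per_pulse: int = Field(32, ge=8)
    gauss_sigma_fraction: float = Field(0.25, gt=0)
    sinc_tbw: float = Field(2.6, gt=0)


class ProtocolConfig(BaseModel):
    field_strength_T: float = Field(3.0, gt=0)
    TR_s: float = Field(1.2, gt=0)
    initial_state: str = "cycled_steady_state"
    saturation_model: str = "cw_steady_state"

    @field_validator("saturation_model")
    @classmethod
    def _model_known(cls, v: str) -> str:
        if v not in ("pulse_train", "cw_steady_state"):
            raise ValueError(f"unknown saturation model {v!r}")
        return v


class ToleranceConfig(BaseModel):
    """Pass/fail tolerances for the reference comparison table."""

    lw_relative: float = 0.10
    # absolute tolerance (percentage points) for small linewidth changes
    dlw_absolute_pp: float = 0.15
    # relative tolerance for the large-change tissues
    dlw_relative: float = 0.20
    dlw_relative_tissues: tuple[str, ...] = ("arterial", "TUMOR", "CSF")


class RunConfig(BaseModel):
    protocol: ProtocolConfig = ProtocolConfig()
    pulse_train: PulseTrainConfig = PulseTrainConfig()
    tissue_table_path: str | None = None
    noise_sigma_fraction: float = Field(0.02, ge=0)
    seed: int = 0
    output_dir: str = "dsdge_out"
    tolerances: ToleranceConfig = ToleranceConfig()

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def write_provenance(self, out_dir) -> Path:
        import numpy
        import scipy

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        record = {
            "timestamp_utc": datetime.now(timezone.utc).isoformat(),
            "dsdge_version": __version__,
            "config_hash": self.config_hash(),
            "config": self.model_dump(),
            "seed": self.seed,
            "python": platform.python_version(),
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
        }
        path = out / "provenance.json"
        path.write_text(json.dumps(record, indent=2))
        return path
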