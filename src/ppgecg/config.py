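"""Run configuration: every tunable of the pipeline with its default.

Unknown keys are rejected (pydantic ``extra="forbid"``), and the full config
is serialized into every artifact's sidecar so no run depends on hidden
defaults.
"""
from __future__ import annotations

import hashlib
import json

from pydantic import BaseModel, ConfigDict

from .siggen import SimConfig

__all__ = ["RunConfig"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FilterSection(_Section):
    low_hz: float = 0.5
    high_hz: float = 40.0


class RDetectSection(_Section):
    c: float = 0.4
    lam: float = 0.98
    refractory_s: float = 0.25
    keep_halfwidth_s: float = 0.03
    refine_halfwidth_s: float = 0.05
    warmup_s: float = 2.0


class CoupleSection(_Section):
    alpha: float = 0.5
    beta: float = 1.0
    amp_ratio: float = 2.0
    window_lo: float = 0.1
    window_hi: float = 0.9


class BaselineSection(_Section):
    min_peak_dist_s: float = 0.3
    amp_frac: float = 0.5
    roll_n: int = 10
    lookback_s: float = 0.5
    deriv_frac: float = 0.4
    deriv_window_s: float = 2.0
    refractory_s: float = 0.3
    onset_mode: str = "zero_cross"


class EvalSection(_Section):
    tol_s: float = 0.04
    alpha: float = 0.05


class ModelSection(_Section):
    window_s: float = 10.0
    step_s: float = 5.0
    trials: int = 50
    cv_folds: int = 5
    test_frac: float = 0.2
    tukey_k: float = 1.5
    bp_noise_sd: float = 3.0


class CohortSection(_Section):
    n_subjects: int = 20
    preset: str = "default"


class RunConfig(_Section):
    sim: SimConfig = SimConfig()
    filter: FilterSection = FilterSection()
    rdetect: RDetectSection = RDetectSection()
    couple: CoupleSection = CoupleSection()
    baseline: BaselineSection = BaselineSection()
    eval: EvalSection = EvalSection()
    model: ModelSection = ModelSection()
    cohort: CohortSection = CohortSection()
    seed: int = 0
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(self.model_dump(), indent=2, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))
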