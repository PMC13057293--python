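"""Pipeline configuration: nested, strictly validated, YAML round-trippable."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortSection(_Strict):
    n_dyslexic: int = 26
    n_control: int = 25
    duration_s: float = 340.0
    fs: float = 256.0
    band_amplitudes: dict[str, float] | None = None
    band_effect_d: dict[str, float] | None = None
    subject_cv: float = 0.05
    epoch_cv: float = 0.2
    pink_noise_scale: float = 5.0
    blink_rate: float = 8.0
    emg_rate: float = 4.0


class BandpassSection(_Strict):
    enabled: bool = True
    low: float = 0.1
    high: float = 70.0


class MovingAverageSection(_Strict):
    enabled: bool = True
    window: int = 9


class IcaSection(_Strict):
    enabled: bool = False
    ocular_corr_threshold: float = 0.7
    ocular_lowfreq_band: tuple[float, float] = (0.5, 4.0)
    emg_highfreq_band: tuple[float, float] = (30.0, 70.0)
    emg_power_ratio_threshold: float = 0.6
    max_components_removed: int = 4


class PreprocessSection(_Strict):
    bandpass: BandpassSection = BandpassSection()
    moving_average: MovingAverageSection = MovingAverageSection()
    ica: IcaSection = IcaSection()


class DecompositionSection(_Strict):
    wavelet: str = "db4"
    level: int = 6
    mapping_mode: str = "table3_literal"
    bands: str = "4band"
    epoch_length_s: float = 10.0


class FeaturesSection(_Strict):
    entropy_bins: int = 16


class SelectionSection(_Strict):
    method: str = "relieff"
    top_k: int = 20
    mi_bins: int = 10
    relieff_k_neighbors: int = 10


class EvaluationSection(_Strict):
    model: str = "dnn"
    n_folds: int = 10
    grouped: bool = False


class PipelineConfig(_Strict):
    seed: int = 0
    out_dir: str = "runs"
    cohort: CohortSection = CohortSection()
    preprocess: PreprocessSection = PreprocessSection()
    decomposition: DecompositionSection = DecompositionSection()
    features: FeaturesSection = FeaturesSection()
    selection: SelectionSection = SelectionSection()
    evaluation: EvaluationSection = EvaluationSection()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(self.model_dump_json()), fh,
                           sort_keys=False)

    def fingerprint(self) -> str:
        return hashlib.sha256(
            self.model_dump_json().encode()
        ).hexdigest()[:12]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed fanned out from the single global seed."""
    digest = hashlib.blake2s(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little")
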