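"""Run configuration and reproducibility plumbing.

A single RunConfig aggregates every tunable of the pipeline and
round-trips through YAML so the resolved configuration can be written
next to each run's outputs.  One master seed fans out deterministically to
per-stage seeds (CRC32 of the stage name mixed into a SeedSequence), so
stages can be re-run in isolation without touching each other's streams.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .entropy import EntropyConfig
from .exceptions import ConfigurationError
from .gait_features import SpectralConfig
from .signal_prep import ScreenConfig

__all__ = ["PredictionConfig", "RunConfig", "stage_seed"]


@dataclass
class PredictionConfig:
    n_reps: int = 500
    train_frac: float = 0.8
    max_components: int = 10
    cv_folds: int = 10
    n_boot: int = 1000


@dataclass
class RunConfig:
    """All pipeline parameters plus the master seed."""

    seed: int = 0
    epoch_duration_s: float = 30.0
    cycle_extremum: str = "minima"      # or "maxima" (see detect_step_cycles)
    detrend_cutoff_hz: float = 0.5
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    entropy: EntropyConfig = field(default_factory=EntropyConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    prediction: PredictionConfig = field(default_factory=PredictionConfig)
    include_lyapunov: bool = True

    def __post_init__(self):
        if self.cycle_extremum not in ("minima", "maxima"):
            raise ConfigurationError(
                "cycle_extremum must be 'minima' or 'maxima'"
            )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, np.ndarray):
                return [float(v) for v in obj]
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj
        return _clean(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sub = {
            "screen": ScreenConfig, "entropy": EntropyConfig,
            "spectral": SpectralConfig, "prediction": PredictionConfig,
        }
        kwargs = {}
        for key, val in d.items():
            if key in sub and isinstance(val, dict):
                val = dict(val)
                for tup_key in ("band", "scales", "phases", "dominant_band",
                                "slope_band", "power_band"):
                    if tup_key in val and isinstance(val[tup_key], list):
                        val[tup_key] = tuple(val[tup_key])
                kwargs[key] = sub[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        return cls.from_dict(d)

    def __eq__(self, other) -> bool:
        return isinstance(other, RunConfig) and self.to_dict() == other.to_dict()


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the master
    seed and the stage name (CRC32 mixed into a SeedSequence)."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))
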