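"""Run configuration: every knob of the pipeline in one serializable record."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Pipeline configuration with documented defaults.

    n_layers: soft-tissue layers between gingival margin and mucosal base.
    shape_vector_m: samples per normalized arch form.
    repeats: ND/NA experiment repetitions.
    rounds/threshold: anomaly-detection rounds and detection-count threshold
    (threshold defaults to rounds // 2 when left as None).
    epsilon: association-matrix cell bound for a mismatch (None: half a
    subject's worth of mass, 0.5 / n_reference).
    k: cluster count or "auto" (Elbow + CuSum over 1..k_max).
    """

    n_layers: int = 10
    shape_vector_m: int = 50
    repeats: int = 100
    rounds: int = 100
    threshold: int | None = None
    epsilon: float | None = None
    k: int | str = "auto"
    k_max: int = 10
    n_init: int = 10
    seed: int = 0
    knn_neighbors: int = 5
    svm_kernel: str = "rbf"
    ci_method: str = "normal"
    two_sided_outlier_rule: bool = True

    def __post_init__(self):
        if self.n_layers < 2:
            raise ConfigError("n_layers must be >= 2")
        if self.shape_vector_m < 7:
            raise ConfigError("shape_vector_m must be >= 7")
        if self.repeats < 1 or self.rounds < 1:
            raise ConfigError("repeats and rounds must be >= 1")
        if self.threshold is not None and not 0 <= self.threshold <= self.rounds:
            raise ConfigError("threshold must lie in [0, rounds]")
        if self.k != "auto" and int(self.k) < 1:
            raise ConfigError("k must be 'auto' or a positive integer")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in run manifests."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
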