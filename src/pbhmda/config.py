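"""Run configuration: the tunable parameters of the predictor.

Parameters
----------
L : int
    Maximum path length in edges for the depth-first enumeration (default 3).
alpha : float
    Decay coefficient of the path score ``(prod w)^(alpha * len)``
    (default 2.26); larger alpha penalises long / weak paths harder.
T : float
    Similarity-edge threshold in [0, 1] (default 0.0, i.e. keep every kernel
    edge); known-association edges are unaffected.
gamma_prime_m, gamma_prime_d : float
    The user-set GIP bandwidth parameters gamma' (default 1 each).

Precedence when assembling a config: explicit overrides > YAML file >
defaults.  The effective config is echoed into every output artifact.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Any, Mapping

import yaml

__all__ = ["RunConfig", "DEFAULT_CONFIG"]


@dataclasses.dataclass(frozen=True)
class RunConfig:
    L: int = 3
    alpha: float = 2.26
    T: float = 0.0
    gamma_prime_m: float = 1.0
    gamma_prime_d: float = 1.0

    def __post_init__(self) -> None:
        if int(self.L) != self.L or self.L < 1:
            raise ValueError(f"L must be an integer >= 1, got {self.L!r}")
        object.__setattr__(self, "L", int(self.L))
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha!r}")
        if not 0.0 <= self.T <= 1.0:
            raise ValueError(f"T must lie in [0, 1], got {self.T!r}")
        if self.gamma_prime_m < 0 or self.gamma_prime_d < 0:
            raise ValueError("gamma_prime values must be non-negative")
        for f in ("alpha", "T", "gamma_prime_m", "gamma_prime_d"):
            object.__setattr__(self, f, float(getattr(self, f)))

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_sources(
        cls,
        yaml_path: str | os.PathLike[str] | None = None,
        **overrides: Any,
    ) -> "RunConfig":
        """Merge defaults, an optional YAML file, and explicit overrides.

        Overrides equal to ``None`` are ignored (unset CLI flags).  Unknown
        keys in either source raise ``ValueError``.
        """
        fields = {f.name for f in dataclasses.fields(cls)}
        merged: dict[str, Any] = {}
        if yaml_path is not None:
            with open(yaml_path, "r", encoding="utf-8") as fh:
                data = yaml.safe_load(fh) or {}
            if not isinstance(data, Mapping):
                raise ValueError(f"{yaml_path}: config file must be a mapping")
            unknown = set(data) - fields
            if unknown:
                raise ValueError(f"{yaml_path}: unknown config keys {sorted(unknown)}")
            merged.update(data)
        for key, value in overrides.items():
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            if value is not None:
                merged[key] = value
        return cls(**merged)


DEFAULT_CONFIG = RunConfig()
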