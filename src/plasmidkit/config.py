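"""Run configuration: one source of truth for every stage threshold."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any, Mapping

import yaml


@dataclass
class RunConfig:
    """Per-stage parameter blocks plus the global seed.

    Unset keys fall back to the stage functions' documented defaults; the
    resolved config (including the seed) is serialized into every output
    directory so a run is reproducible from its artifacts alone.
    """

    seed: int = 0
    outdir: str = "plasmidkit_out"
    log_level: str = "INFO"
    synth: dict[str, Any] = field(default_factory=dict)
    discover: dict[str, Any] = field(
        default_factory=lambda: {
            "gc_window": 0.02,
            "cov_window": 0.15,
            "target_lineage": "Candidatus Methanoperedens",
            "min_dominant_fraction": 0.5,
        }
    )
    hostlink: dict[str, Any] = field(
        default_factory=lambda: {"ratio_band": [0.67, 1.5]}
    )
    circ: dict[str, Any] = field(
        default_factory=lambda: {
            "min_overlap": 20,
            "max_overlap": 5000,
            "max_mismatch": 0,
            "min_pairs": 3,
            "max_insert": 1000,
        }
    )
    skew: dict[str, Any] = field(
        default_factory=lambda: {"window": 1000, "step": 10}
    )
    express: dict[str, Any] = field(
        default_factory=lambda: {
            "min_identity": 0.99,
            "ambiguous_policy": "random",
            "min_frac_overlap": 0.1,
            "thresholds": [0.5, 10.0, 100.0],
        }
    )
    protfam: dict[str, Any] = field(
        default_factory=lambda: {
            "e_max": 1e-3,
            "cover_min": 0.5,
            "fdr": 0.05,
            "n_families": 12,
            "n_background": 60,
            "substitution_rate": 0.1,
        }
    )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "RunConfig":
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, dict) and isinstance(value, Mapping):
                current.update(value)
            else:
                setattr(cfg, key, value)
        return cfg

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
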