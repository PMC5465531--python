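"""Analysis configuration: every threshold of the pipeline in one object.

No zone, band or multiplier is hard-coded in the orchestration layer; the
defaults form the shipped ``mercado2017`` profile (15% four-quadrant zone,
0.5 L/min polar zone, ±30° band, ΔCO reference rule > 10%, operating
threshold > 8%, 1.96 LOA multiplier, k = 2 precision convention). The
config is serialised verbatim into every report for provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, fields
from pathlib import Path

from .exceptions import InvalidInputError


@dataclass(frozen=True)
class AnalysisConfig:
    fq_zone_pct: float = 15.0
    polar_zone_lmin: float = 0.5
    polar_band_deg: float = 30.0
    roc_positive_pct: float = 10.0
    operating_threshold_pct: float = 8.0
    loa_multiplier: float = 1.96
    precision_k: float = 2.0
    central_tendency: str = "mean"
    ci_method: str = "delong"
    pi_literal: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fq_zone_pct", "polar_zone_lmin", "polar_band_deg",
                     "roc_positive_pct", "operating_threshold_pct",
                     "loa_multiplier", "precision_k"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"config: {name} must be > 0")
        if self.central_tendency not in ("mean", "median"):
            raise InvalidInputError("config: central_tendency must be 'mean' or 'median'")
        if self.ci_method not in ("delong", "bootstrap"):
            raise InvalidInputError("config: ci_method must be 'delong' or 'bootstrap'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known - {"profile"}
        if unknown:
            raise InvalidInputError(f"config: unknown keys {sorted(unknown)}")
        base = {}
        if d.get("profile") is not None:
            if d["profile"] not in PROFILES_DICT:
                raise InvalidInputError(f"unknown profile {d['profile']!r}")
            base = dict(PROFILES_DICT[d["profile"]])
        base.update({k: v for k, v in d.items() if k != "profile"})
        return cls(**base)

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        """Load from JSON or YAML, keyed off the file suffix."""
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        if not isinstance(d, dict):
            raise InvalidInputError(f"config file {path}: expected a mapping")
        return cls.from_dict(d)


#: Named profiles; the defaults are the published-study settings.
PROFILES_DICT: dict[str, dict] = {"mercado2017": {}}


def get_profile(name: str = "mercado2017") -> AnalysisConfig:
    if name not in PROFILES_DICT:
        raise InvalidInputError(f"unknown profile {name!r}; available: {sorted(PROFILES_DICT)}")
    return AnalysisConfig(**PROFILES_DICT[name])
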