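"""Run configuration: defaults, YAML loading, and resolved-config echoing."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .fitting import FitConfig
from .synthetic import GeneratorConfig

__all__ = ["RunConfig", "load_run_config", "write_resolved_config"]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings with documented defaults.

    alpha_mode: how the proliferation rate is obtained -- ``fastest-progressor``
    (one cohort-wide rate from the fastest exponential fit),
    ``per-patient-pretreatment`` (each patient's pretreatment scan), or
    ``fixed`` (``alpha_fixed``, 1/day).
    """

    seed: int = 0
    alpha_mode: str = "fastest-progressor"
    alpha_fixed: float | None = None
    recist_convention: str = "volume-0.7"
    projection_horizon: float = 700.0
    truncation_windows: tuple[float, ...] = (30.0, 60.0, 120.0, 200.0)
    pdl1_cutoffs: tuple[float, ...] = (1.0, 5.0)
    fit: FitConfig = field(default_factory=FitConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["truncation_windows"] = list(self.truncation_windows)
        d["pdl1_cutoffs"] = list(self.pdl1_cutoffs)
        for key in ("fit", "generator"):
            d[key] = {
                k: (list(v) if isinstance(v, tuple) else v) for k, v in d[key].items()
            }
        return d


def _build(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    tuple_fields = {
        f.name for f in fields(cls) if "tuple" in str(f.type)
    }
    coerced = {
        k: (tuple(v) if k in tuple_fields and isinstance(v, list) else v)
        for k, v in data.items()
    }
    return cls(**coerced)


def load_run_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides."""
    data: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    fit = _build(FitConfig, data.pop("fit", {}) or {})
    gen = _build(GeneratorConfig, data.pop("generator", {}) or {})
    cfg = _build(RunConfig, {**data, "fit": fit, "generator": gen})
    if overrides:
        gen_over = overrides.pop("generator", None)
        if gen_over:
            cfg = replace(cfg, generator=replace(cfg.generator, **gen_over))
        fit_over = overrides.pop("fit", None)
        if fit_over:
            cfg = replace(cfg, fit=replace(cfg.fit, **fit_over))
        cfg = replace(cfg, **{k: v for k, v in overrides.items() if v is not None})
    return cfg


def write_resolved_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
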