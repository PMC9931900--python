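"""Run configuration: one structured YAML file with per-stage blocks.

All randomness flows from explicit seeds (no wall-clock seeding); every
stage can be toggled; MCMC settings are per stage with desk-scale defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

__all__ = ["McmcSettings", "RunConfig", "load_config"]


@dataclass
class McmcSettings:
    chains: int = 3
    iters: int = 4000
    burn_in: int = 2000
    thin: int = 1

    def kwargs(self) -> dict:
        return asdict(self)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "popimpact_run"
    stages: tuple[str, ...] = ("simulate", "growth", "absence", "demography", "project", "rank")
    thresholds_km: tuple[float, ...] = (2.0, 5.0, 10.0, 15.0, 20.0, 30.0)
    absence_before_years: tuple[int, int] | None = None  # default: final two of each period
    absence_after_years: tuple[int, int] | None = None
    sim_overrides: dict = field(default_factory=dict)
    growth_mcmc: McmcSettings = field(default_factory=lambda: McmcSettings(iters=8000, burn_in=4000))
    absence_mcmc: McmcSettings = field(default_factory=McmcSettings)
    demography_mcmc: McmcSettings = field(default_factory=lambda: McmcSettings(iters=8000, burn_in=4000))
    buffers_km: tuple[float, ...] = (2.0, 5.0, 10.0)
    cluster_radius_km: float = 4.0
    decay_scale_m: float = 3000.0  # impact-covariate exponential-decay scale

    def validate(self) -> None:
        known = {"simulate", "growth", "absence", "demography", "project", "rank"}
        bad = set(self.stages) - known
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if self.seed is None:
            raise ValueError("an explicit seed is required")


def load_config(path) -> RunConfig:
    import yaml

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("growth_mcmc", "absence_mcmc", "demography_mcmc"):
        if key in raw:
            raw[key] = McmcSettings(**raw[key])
    for key in ("stages", "thresholds_km", "buffers_km",
                "absence_before_years", "absence_after_years"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def default_yaml() -> str:
    import yaml

    cfg = RunConfig()
    d = asdict(cfg)
    return yaml.safe_dump(d, sort_keys=False)
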