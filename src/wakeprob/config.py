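"""Run configuration: model priors, filter settings, and YAML round-trip.

Every randomized entry point takes an explicit seed and can echo its full
configuration, so any run is reproducible bit-exactly from the echo.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import DEFAULT_BETA

__all__ = ["PriorSpec", "ModelConfig", "FilterConfig", "RunConfig",
           "load_config", "save_config"]


@dataclass
class PriorSpec:
    """Independent Gaussian priors for initial states and coefficients.

    Positive-constrained coefficients (``mu1``, gains, noise sds) are given
    lognormal priors: the (mean, sd) pair applies to the log of the value.
    """

    state_mean: tuple[float, float, float] = (2.0, 2.0, -2.0)
    state_sd: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mu0: tuple[float, float] = (-1.5, 0.25)
    log_mu1: tuple[float, float] = (-0.6931471805599453, 0.15)     # median 0.5
    log_emg_noise_sd: tuple[float, float] = (-1.2039728043259361, 0.15)  # median 0.3
    alpha_offset: tuple[float, float] = (0.0, 0.5)
    log_alpha_gain: tuple[float, float] = (0.6931471805599453, 0.15)     # median 2.0
    log_alpha_noise_sd: tuple[float, float] = (-0.6931471805599453, 0.15)
    dt_offset: tuple[float, float] = (0.0, 0.5)
    log_dt_gain: tuple[float, float] = (0.6931471805599453, 0.15)
    log_dt_noise_sd: tuple[float, float] = (-0.6931471805599453, 0.15)

    def validate(self) -> None:
        # zero-variance (degenerate, point-mass) priors are legal
        for f in dataclasses.fields(self):
            if f.name.startswith("state_"):
                continue
            if getattr(self, f.name)[1] < 0:
                raise ValueError(f"prior sd for {f.name} must be >= 0")
        if any(s < 0 for s in self.state_sd):
            raise ValueError("state prior sds must be >= 0")


@dataclass
class ModelConfig:
    """Wake-model structure and walk scales."""

    beta: float = DEFAULT_BETA
    link: str = "logistic"
    #: Filter process noise per 0.25-s step. Set generously relative to the
    #: physiological drift rates so the filter can track transitions without
    #: lagging; simulation shows the 95% band stays near-nominal.
    state_walk_sds: tuple[float, float, float] = (0.08, 0.08, 0.08)
    param_walk_sd: float = 0.002
    #: Liu-West shrinkage factor for coefficient evolution inside the filter.
    #: The plain coefficient random walk inflates the parameter posterior a
    #: little every step; the Liu-West kernel (shrink by a toward the
    #: ensemble mean, add kernel noise of variance (1-a^2)*ensemble variance)
    #: is the standard variance-preserving correction. None selects the
    #: plain walk at param_walk_sd.
    param_shrinkage: float | None = 0.995
    priors: PriorSpec = field(default_factory=PriorSpec)

    def validate(self) -> None:
        if self.link != "logistic":
            raise ValueError("only the logistic link is implemented")
        if any(s < 0 for s in self.state_walk_sds) or self.param_walk_sd < 0:
            raise ValueError("walk sds must be >= 0")
        if self.param_shrinkage is not None and not 0 < self.param_shrinkage <= 1:
            raise ValueError("param_shrinkage must lie in (0, 1] or be None")
        self.priors.validate()


@dataclass
class FilterConfig:
    """Particle-filter settings: ensemble size, resampling trigger, outputs."""

    n_particles: int = 10_000
    ess_fraction: float = 0.5      # resample when ESS < ess_fraction * N
    n_predictive_samples: int = 200

    def validate(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if not 0 < self.ess_fraction <= 1:
            raise ValueError("ess_fraction must be in (0, 1]")


@dataclass
class RunConfig:
    """Top-level bundle covering all pipeline stages."""

    model: ModelConfig = field(default_factory=ModelConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    gof_n_mc: int = 10_000
    popspec_bin_width: float = 0.0025
    popspec_iterations: int = 10_000

    def validate(self) -> None:
        self.model.validate()
        self.filter.validate()


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def _from_plain(cls, data):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        if dataclasses.is_dataclass(f.type) or f.name in ("model", "filter", "priors"):
            sub = {"model": ModelConfig, "filter": FilterConfig,
                   "priors": PriorSpec}[f.name]
            kwargs[f.name] = _from_plain(sub, val)
        elif isinstance(val, list):
            kwargs[f.name] = tuple(val)
        else:
            kwargs[f.name] = val
    return cls(**kwargs)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    cfg = _from_plain(RunConfig, data)
    cfg.validate()
    return cfg
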