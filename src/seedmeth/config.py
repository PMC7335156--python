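"""Pipeline configuration: one YAML file holding every threshold.

Every numeric criterion of the analysis is a named parameter with the
published default: methylcytosine calling at p <= 1e-4 and depth >= 5;
DMR windows of 100 bp sliding by 50 bp with >= 3 cytosines, >= 25-point
level difference at q <= 0.01, merged within 50 bp; 2-kb flanks split
into 10 bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class Params:
    min_depth: int = 5
    alpha: float = 1e-4
    window: int = 100
    step: int = 50
    min_cytosines: int = 3
    min_diff: float = 25.0
    max_q: float = 0.01
    merge_gap: int = 50
    flank: int = 2000
    nbins: int = 10
    pi0: float | None = None          # None = estimate from data

    def validate(self) -> None:
        for name in ("min_depth", "window", "step", "min_cytosines",
                     "flank", "nbins"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ConfigError(f"alpha must be in (0, 1]: {self.alpha}")
        if not 0 < self.max_q <= 1:
            raise ConfigError(f"max_q must be in (0, 1]: {self.max_q}")
        if self.min_diff < 0 or self.min_diff > 100:
            raise ConfigError("min_diff must be in [0, 100]")
        if self.merge_gap < 0:
            raise ConfigError("merge_gap must be >= 0")
        if self.window < self.step:
            raise ConfigError("window must be >= step")
        if self.pi0 is not None and not 0 < self.pi0 <= 1:
            raise ConfigError("pi0 must be in (0, 1]")


@dataclass
class SimulateSection:
    n_chromosomes: int = 2
    chromosome_length: int = 1_000_000
    chloroplast_length: int = 125_000
    depth_mean: float = 20.0
    conversion_error: float = 0.006
    n_genes: int = 300
    n_tes: int = 200
    fraction_intragenic_tes: float = 0.25
    stages: list = field(default_factory=lambda: ["S1", "S2"])
    n_replicates: int = 2
    stage_te_chh_gain: dict = field(default_factory=dict)
    n_planted_dmrs: int = 20
    planted_dmr_width: int = 300
    planted_dmr_levels: list = field(default_factory=lambda: [0.2, 0.7])
    expression_coupling: float = 0.5
    n_up_degs: int = 50
    n_down_degs: int = 50
    fraction_hyper_tes: float = 0.25
    te_chh_dmr_levels: list = field(default_factory=lambda: [0.05, 0.55])
    smallrna_lambda_bg: float = 0.001
    smallrna_density_ratio: float = 5.0
    smallrna_frac_24nt: float = 0.8
    write_site_truth: bool = False


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "seedmeth_out"
    group_a: str = "S1"
    group_b: str = "S2"
    params: Params = field(default_factory=Params)
    simulate: SimulateSection = field(default_factory=SimulateSection)
    inputs: dict = field(default_factory=dict)
    gene_lists: dict = field(default_factory=dict)

    def validate(self) -> None:
        self.params.validate()
        if self.group_a == self.group_b:
            raise ConfigError("comparison groups must differ")


def _fill(cls, data: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown {where} keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    params = _fill(Params, raw.pop("params", {}) or {}, "params")
    sim = _fill(SimulateSection, raw.pop("simulate", {}) or {}, "simulate")
    cfg = _fill(PipelineConfig,
                {**raw, "params": params, "simulate": sim}, "config")
    cfg.validate()
    return cfg
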