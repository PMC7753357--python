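"""Run configuration: model parameters, cohort spec, regimens, targets.

A YAML file with keys mirroring the parameter dataclasses overrides the
study defaults; anything omitted keeps its default, so an empty config is
a valid full specification of the published analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import CovariateDistribution, CovariateSpec, EtaScheme
from .covariates import OmegaSet, SigmaSet, ThetaSet

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    theta: ThetaSet = field(default_factory=ThetaSet)
    omega: OmegaSet = field(default_factory=OmegaSet)
    sigma: SigmaSet = field(default_factory=SigmaSet)
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    eta_scheme: EtaScheme = field(default_factory=EtaScheme)
    n_subjects: int = 5000
    infusion_duration: float = 0.5  # h
    dose_grid_min: int = 4  # mg/kg
    dose_grid_max: int = 25
    loading_scan_max: int = 15  # mg/kg, q12h x3 scan upper end
    maintenance_scan_max: int = 20  # mg/kg/day scan upper end
    trough_targets: tuple = (10.0, 15.0)  # mg/L
    ratio_targets: tuple = (125.0, 345.0)  # AUC24/MIC
    cfr_min: float = 0.90
    mic_file: str | None = None  # None -> bundled synthetic example
    lloq: float = 2.5  # mg/L
    seed: int = 1
    outdir: str = "results"

    @property
    def dose_grid(self) -> tuple:
        return tuple(range(self.dose_grid_min, self.dose_grid_max + 1))


def _dist(entry: dict) -> CovariateDistribution:
    return CovariateDistribution(
        mean=entry["mean"], sd=entry["sd"], minimum=entry["min"], maximum=entry["max"]
    )


def load_config(path=None) -> RunConfig:
    """Load a YAML config; missing keys fall back to the study defaults."""
    cfg = RunConfig()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "theta" in raw:
        cfg.theta = ThetaSet(**raw["theta"])
    if "omega" in raw:
        cfg.omega = OmegaSet(**raw["omega"])
    if "sigma" in raw:
        cfg.sigma = SigmaSet(**raw["sigma"])
    if "covariates" in raw:
        cov = raw["covariates"]
        cfg.covariates = CovariateSpec(
            wt=_dist(cov["wt"]) if "wt" in cov else CovariateSpec().wt,
            scr=_dist(cov["scr"]) if "scr" in cov else CovariateSpec().scr,
            age=_dist(cov["age"]) if "age" in cov else CovariateSpec().age,
            male_fraction=cov.get("male_fraction", CovariateSpec().male_fraction),
        )
    if "eta_scheme" in raw:
        cfg.eta_scheme = EtaScheme(**raw["eta_scheme"])
    for key in (
        "n_subjects",
        "infusion_duration",
        "dose_grid_min",
        "dose_grid_max",
        "loading_scan_max",
        "maintenance_scan_max",
        "cfr_min",
        "mic_file",
        "lloq",
        "seed",
        "outdir",
    ):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "trough_targets" in raw:
        cfg.trough_targets = tuple(raw["trough_targets"])
    if "ratio_targets" in raw:
        cfg.ratio_targets = tuple(raw["ratio_targets"])
    if cfg.mic_file is not None and not Path(cfg.mic_file).exists():
        raise FileNotFoundError(f"config key 'mic_file' points to missing file: {cfg.mic_file}")
    return cfg
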