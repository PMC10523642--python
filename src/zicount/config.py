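"""Study configuration: a validated plain-text (YAML) key-value file."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .synthetic import CALIBRATION_TARGETS, OUTCOMES, MIN_SAMPLE_SIZE

__all__ = ["StudyConfig", "ConfigError", "ALLOWED_SAMPLE_SIZES"]

ALLOWED_SAMPLE_SIZES = (60, 80, 100, 200, 422, 600, 800)


class ConfigError(ValueError):
    pass


@dataclass
class StudyConfig:
    """Everything a full study run needs, reproducible from (config, seed).

    ``dd_family`` picks which generative truths to simulate from ("nb",
    "zinb", or "both"); ``analysis_families`` are the models fitted to every
    replicate.  ``sample_sizes`` come from the sensitivity grid; anything
    below 60 is rejected outright.
    """

    outcome: str = "serious_illness"
    dd_family: str = "both"
    analysis_families: tuple = ("nb", "zinb")
    reps: int = 500
    sample_sizes: tuple = (422,)
    master_seed: int = 2023
    calibration_targets: dict = field(default_factory=lambda: dict(CALIBRATION_TARGETS))
    logit_intercept: float = None  # None -> package default
    compute_ci: bool = True
    ci_level: float = 0.95
    lambda_grid_size: int = 50
    cv_folds: int = 10
    n_bootstrap: int = 200
    n_jobs: int = 1
    out_dir: str = "zicount_outputs"

    _KNOWN = None  # filled below

    def validate(self) -> "StudyConfig":
        errs = []
        if self.outcome not in OUTCOMES:
            errs.append(f"outcome must be one of {OUTCOMES}, got '{self.outcome}'")
        if self.dd_family not in ("nb", "zinb", "both"):
            errs.append("dd_family must be 'nb', 'zinb', or 'both'")
        for fam in self.analysis_families:
            if fam not in ("poisson", "nb", "zip", "zinb"):
                errs.append(f"unknown analysis family '{fam}'")
        if self.reps < 2:
            errs.append("reps must be >= 2")
        for n in self.sample_sizes:
            if n < MIN_SAMPLE_SIZE:
                errs.append(
                    f"sample size {n} < {MIN_SAMPLE_SIZE}: too few non-zero counts "
                    "for stable fitting; sizes below 60 are excluded by design"
                )
        if not (0.0 < self.ci_level < 1.0):
            errs.append("ci_level must be in (0, 1)")
        if self.cv_folds < 2:
            errs.append("cv_folds must be >= 2")
        if not (0 <= self.master_seed < 2**31):
            errs.append("master_seed must be a non-negative 31-bit integer")
        if errs:
            raise ConfigError("; ".join(errs))
        return self

    @property
    def dd_families(self) -> tuple:
        return ("nb", "zinb") if self.dd_family == "both" else (self.dd_family,)

    def as_dict(self) -> dict:
        d = asdict(self)
        d.pop("_KNOWN", None)
        d["analysis_families"] = list(self.analysis_families)
        d["sample_sizes"] = list(self.sample_sizes)
        d["calibration_targets"] = {k: list(v) for k, v in self.calibration_targets.items()}
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        known = {f for f in cls.__dataclass_fields__ if not f.startswith("_")}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.analysis_families = tuple(cfg.analysis_families)
        cfg.sample_sizes = tuple(cfg.sample_sizes)
        cfg.calibration_targets = {
            k: tuple(v) for k, v in cfg.calibration_targets.items()
        }
        return cfg.validate()
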