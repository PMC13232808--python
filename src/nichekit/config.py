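"""Run configuration: one YAML file drives the whole chain reproducibly."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .ensemble import MEMBER_TAGS
from .errors import ConfigError

_VALID_D_MODES = ("binary", "continuous")
_VALID_PERIOD_AVERAGES = ("continuous_mean", "binary_majority")


@dataclass
class RunConfig:
    """Paths, parameters and the master seed for a pipeline run.

    Parameter defaults are the standard protocol of the analysis: |r| 0.7
    collinearity cutoff, 1,000 pseudo-absences, a 500-record subsampling cap,
    70/30 calibration/evaluation splits over 3 replicates, an inclusive
    AUC >= 0.7 ensemble gate, and 95% confidence intervals.
    """

    baseline_dir: str = ""
    scenario_dirs: dict[str, str] = field(default_factory=dict)
    occurrences_csv: str = ""
    elevation: str | None = None
    zones: str | None = None
    output_dir: str = ""

    collinearity_threshold: float = 0.7
    n_pseudo_absences: int = 1000
    subsample_cap: int = 500
    calib_frac: float = 0.7
    reps: int = 3
    auc_gate: float = 0.7
    ci_alpha: float = 0.05
    d_mode: str = "binary"
    period_average: str = "continuous_mean"
    learners: list[str] = field(default_factory=lambda: list(MEMBER_TAGS))
    resample_cell_size: float | None = None

    master_seed: int = 0

    def validate(self) -> None:
        for key in ("baseline_dir", "occurrences_csv", "output_dir"):
            if not getattr(self, key):
                raise ConfigError(f"missing required path: paths.{key}")
        for key in ("collinearity_threshold", "auc_gate", "ci_alpha"):
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{key}={v} outside [0, 1]")
        if not 0.0 < self.calib_frac < 1.0:
            raise ConfigError(f"calib_frac={self.calib_frac} outside (0, 1)")
        if self.n_pseudo_absences < 1 or self.subsample_cap < 1 or self.reps < 1:
            raise ConfigError("counts must be >= 1")
        if self.d_mode not in _VALID_D_MODES:
            raise ConfigError(f"d_mode must be one of {_VALID_D_MODES}")
        if self.period_average not in _VALID_PERIOD_AVERAGES:
            raise ConfigError(f"period_average must be one of {_VALID_PERIOD_AVERAGES}")
        unknown = [t for t in self.learners if t not in MEMBER_TAGS]
        if unknown:
            raise ConfigError(f"unknown learners: {unknown} (choose from {MEMBER_TAGS})")
        if not self.learners:
            raise ConfigError("at least one learner is required")

    def to_dict(self) -> dict:
        d = asdict(self)
        return {
            "paths": {k: d.pop(k) for k in ("baseline_dir", "scenario_dirs",
                                            "occurrences_csv", "elevation",
                                            "zones", "output_dir")},
            "parameters": {k: v for k, v in d.items() if k != "master_seed"},
            "master_seed": d["master_seed"],
        }

    def echo(self, path: str | Path) -> None:
        """Write the fully resolved configuration next to the outputs."""
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


_PATH_KEYS = {"baseline_dir", "scenario_dirs", "occurrences_csv", "elevation",
              "zones", "output_dir"}
_PARAM_KEYS = {"collinearity_threshold", "n_pseudo_absences", "subsample_cap",
               "calib_frac", "reps", "auc_gate", "ci_alpha", "d_mode",
               "period_average", "learners", "resample_cell_size"}


def parse_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected by name; missing parameters fall back to the
    protocol defaults; out-of-range values raise :class:`ConfigError`.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = set(raw) - {"paths", "parameters", "master_seed"}
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    paths = raw.get("paths") or {}
    params = raw.get("parameters") or {}
    for section, allowed, got in (("paths", _PATH_KEYS, paths),
                                  ("parameters", _PARAM_KEYS, params)):
        if not isinstance(got, dict):
            raise ConfigError(f"'{section}' must be a mapping")
        bad = set(got) - allowed
        if bad:
            raise ConfigError(f"unknown keys in {section}: {sorted(bad)}")
    cfg = RunConfig(**paths, **params, master_seed=int(raw.get("master_seed", 0)))
    cfg.validate()
    return cfg
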