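"""Pipeline configuration: a serializable record of one reproducible run."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a simulate-to-report run.

    Defaults encode the reference study design: 20 participants, 120 trials
    over 4 complexity levels, 20-s maintenance at 3 fixations/s, fixation
    filters at 100 ms / 5 s, recurrence threshold of 2 deg (~104 px).
    """

    seed: int = 0
    output_dir: str = "runs/default"
    # design
    n_participants: int = 20
    trials_per_participant: int = 120
    dvn_factor: bool = False
    # mechanism
    mechanism: str = "mixture"
    anchor_sd_px: float = 45.0
    restriction_release: float = 1.35
    revisit_prob: float = 0.3
    fixation_rate_hz: float = 3.0
    maintenance_duration_s: float = 20.0
    heterogeneity: bool = True
    # accuracy model
    accuracy_intercept: float = 3.2
    accuracy_slope: float = -0.45
    # filters
    min_fixation_ms: float = 100.0
    max_fixation_ms: float = 5000.0
    min_rating: int = 3
    # rqa
    threshold_deg: float = 2.0
    threshold_px: float | None = None  # overrides threshold_deg when set
    min_line: int = 2
    # inference
    profile: str = "test"  # "test": 4x1000 draws; "full": 4x5000
    sampler: str = "laplace"
    include_spread_covariate: bool = False
    make_figures: bool = True

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.trials_per_participant <= 0:
            raise ValueError("trials_per_participant must be positive")
        if self.profile not in ("test", "full"):
            raise ValueError("profile must be 'test' or 'full'")
        if self.min_fixation_ms >= self.max_fixation_ms:
            raise ValueError("min_fixation_ms must be below max_fixation_ms")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path
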