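"""Run configuration: one YAML-serializable object wiring every stage.

Defaults mirror the full-scale study settings (1000 members per cohort at
NP ratio 20 with a 70/30 hold-out; 10,000 permutations for enrichment and
1,000 for module activity); the simulation block defaults to the
repository's desk-scale synthetic configuration.  Seeds are always
explicit — there are no wall-clock defaults anywhere.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import SimConfig, config_from_dict


@dataclass
class RunConfig:
    outdir: str = "puvote_run"
    seed: int = 17
    # data: either simulate (sim block) or point data_dir at files written
    # in the same layout
    data_dir: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    positive_set: str = "HALLMARK_SEED_PATHWAY"
    exclusion_prefix: str = "HALLMARK_"
    reference_set: str = "ONCOGENIC_C6_ANALOGUE"
    subtype_column: str = "tnbc"
    # ensemble
    members: int = 1000
    np_ratio: float = 20.0
    holdout_frac: float = 0.3
    svm_c: float = 1.0
    standardize: bool = True
    log_transform: bool = True
    # calibration
    calibration_ratios: tuple[float, ...] = (1, 10, 15, 20, 25, 30)
    members_per_ratio: int = 1000
    # permutations
    n_perm_enrich: int = 10000
    n_perm_activity: int = 1000
    # modules
    module_min_size: int = 3
    classifier_holdouts: int = 100
    # survival
    horizon_years: float = 5.0

    def validate(self) -> None:
        self.sim.validate()
        if self.members < 1:
            raise ValueError("members must be >= 1")
        if not 0 < self.holdout_frac < 1:
            raise ValueError("holdout_frac must be in (0, 1)")
        if self.data_dir is not None and not Path(self.data_dir).exists():
            raise ValueError(f"data_dir {self.data_dir!r} does not exist")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = dataclasses.asdict(self.sim)
        d["calibration_ratios"] = list(self.calibration_ratios)
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            sim = config_from_dict(sim)
        if "calibration_ratios" in d:
            d["calibration_ratios"] = tuple(d["calibration_ratios"])
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(sim=sim, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
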