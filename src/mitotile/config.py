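"""Pipeline configuration: every tunable threshold in one round-trippable object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class PipelineConfig:
    # probe design
    probe_length: int = 60
    step: int = 2
    min_dup_length: int = 10_000
    circular: bool = True
    # expression calling
    window_size: int = 60
    alpha: float = 1e-3
    assignment: str = "center"  # center | min_cover
    # TU detection
    min_run: int = 20
    gap_tolerance: int = 0
    containment_mode: str = "query_cover"
    min_overlap: float = 0.5
    # ORF analysis
    min_aa: int = 70
    orf_mode: str = "stop_to_stop"
    # simulation scenario (noise/effect conventions: the source data states
    # no noise distribution, so these are explicit, documented defaults)
    genome_length: int = 100_000
    n_housekeeping: int = 6
    n_iorf: int = 8
    n_te: int = 3
    duplication_lengths: list = field(default_factory=list)
    background_regions: int = 2
    tissue_profiles: list = field(
        default_factory=lambda: [["calli", 0.485, 3.0], ["seedling", 0.320, 3.0]]
    )
    nested: bool = True
    baseline_signal: float = 10.0
    noise_sd: float = 1.0
    typical_interval_bp: int = 12_000
    seed: int = 0
    # paths
    out_dir: str = "results/pipeline"

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        for name in ("probe_length", "step", "min_dup_length", "window_size",
                     "min_run", "min_aa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.assignment not in {"center", "min_cover"}:
            raise ValueError(f"bad assignment convention {self.assignment!r}")
        if self.orf_mode not in {"stop_to_stop", "start_to_stop"}:
            raise ValueError(f"bad ORF mode {self.orf_mode!r}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


__all__ = ["PipelineConfig"]
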