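"""The probes-by-channels intensity container.

Rows are probe start positions on the non-redundant sequence; columns
are (tissue, replicate) channels, where the sense and antisense probes
sharing a start are the two replicates.  The ``stage`` tag tracks the
normalization state and only ever advances raw -> quantile -> zscore.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STAGES = ("raw", "quantile", "zscore")


class StageError(ValueError):
    pass


@dataclass
class IntensityMatrix:
    positions: np.ndarray  # int64 probe starts (non-redundant coordinates)
    channels: list[tuple[str, str]]  # (tissue, replicate) per column
    values: np.ndarray  # positions x channels, float
    stage: str = "raw"
    probe_length: int = 60
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.positions), len(self.channels)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.positions)} positions x {len(self.channels)} channels"
            )
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}")
        if np.isnan(self.values).any():
            raise ValueError("missing values in intensity matrix")

    @property
    def tissues(self) -> list[str]:
        seen = []
        for t, _ in self.channels:
            if t not in seen:
                seen.append(t)
        return seen

    def columns_for(self, tissue: str) -> list[int]:
        return [i for i, (t, _) in enumerate(self.channels) if t == tissue]

    def advanced(self, values: np.ndarray, stage: str, **prov) -> "IntensityMatrix":
        if STAGES.index(stage) != STAGES.index(self.stage) + 1:
            raise StageError(f"illegal stage transition {self.stage} -> {stage}")
        return replace(
            self,
            values=values,
            stage=stage,
            provenance={**self.provenance, stage: prov},
        )

    def hstack(self, other: "IntensityMatrix") -> "IntensityMatrix":
        if not np.array_equal(self.positions, other.positions):
            raise ValueError("cannot stack matrices with different positions")
        if self.stage != other.stage:
            raise StageError("cannot stack matrices at different stages")
        return replace(
            self,
            channels=self.channels + other.channels,
            values=np.hstack([self.values, other.values]),
        )

    # -- TSV interchange ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"start": self.positions})
        for j, (tissue, rep) in enumerate(self.channels):
            df[f"{tissue}.{rep}"] = self.values[:, j]
        return df

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# stage={self.stage} probe_length={self.probe_length}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read_tsv(cls, path) -> "IntensityMatrix":
        with open(path) as fh:
            header = fh.readline().strip()
            meta = dict(
                item.split("=", 1) for item in header.lstrip("# ").split() if "=" in item
            )
            df = pd.read_csv(fh, sep="\t")
        channels = []
        for col in df.columns:
            if col == "start":
                continue
            tissue, _, rep = col.partition(".")
            channels.append((tissue, rep or "sense"))
        return cls(
            positions=df["start"].to_numpy(),
            channels=channels,
            values=df.drop(columns="start").to_numpy(),
            stage=meta.get("stage", "raw"),
            probe_length=int(meta.get("probe_length", 60)),
        )


__all__ = ["IntensityMatrix", "StageError", "STAGES"]
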