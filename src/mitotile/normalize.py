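"""Intensity normalization: quantile scaling then Z-scores.

Each tissue's channels (sense + antisense) are quantile-normalized
together, replacing every column by the rank-wise mean of the sorted
columns so the empirical distributions become identical; tied values
receive the mean of the reference values their ranks span.  Columns are
then standardized to Z-scores (sample standard deviation, n-1).  The
two strands' probes at a genomic start are finally merged into a
replicate set per position, which is what the window t-test consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import IntensityMatrix


class DegenerateVarianceError(ValueError):
    pass


def _quantile_normalize_block(X: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of X against their rank-mean reference."""
    n, m = X.shape
    order = np.argsort(X, axis=0, kind="stable")
    ref = np.take_along_axis(X, order, axis=0).mean(axis=1)
    out = np.empty_like(X, dtype=float)
    ranks = np.empty(n, dtype=np.int64)
    for j in range(m):
        ranks[order[:, j]] = np.arange(n)
        col_ref = ref[ranks]
        # ties take the mean of the reference values they span
        uniq, inv = np.unique(X[:, j], return_inverse=True)
        if len(uniq) < n:
            sums = np.bincount(inv, weights=col_ref)
            counts = np.bincount(inv)
            out[:, j] = (sums / counts)[inv]
        else:
            out[:, j] = col_ref
    return out


def quantile_normalize(matrix: IntensityMatrix, per_tissue: bool = True) -> IntensityMatrix:
    """Quantile-normalize channels, by default within each tissue.

    ``per_tissue=False`` normalizes all channels together (cross-tissue
    coupling; provided for sensitivity analysis).
    """
    if matrix.values.size == 0:
        raise ValueError("empty intensity matrix")
    out = np.empty_like(matrix.values, dtype=float)
    groups = (
        [matrix.columns_for(t) for t in matrix.tissues]
        if per_tissue
        else [list(range(len(matrix.channels)))]
    )
    for cols in groups:
        out[:, cols] = _quantile_normalize_block(matrix.values[:, cols])
    return matrix.advanced(out, "quantile", per_tissue=per_tissue)


def zscore(matrix: IntensityMatrix) -> IntensityMatrix:
    """Standardize each channel to mean 0, sample (n-1) standard deviation 1."""
    X = matrix.values
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [matrix.channels[j] for j in np.flatnonzero(sd == 0)]
        raise DegenerateVarianceError(f"constant channel(s): {bad}")
    return matrix.advanced((X - mu) / sd, "zscore")


@dataclass
class ReplicateTrack:
    """Per-position replicate sets of normalized values, one block per tissue.

    ``values[tissue]`` is a positions x replicates array; with both
    strands present each position carries two replicate values (sense,
    antisense).  Positions are sorted ascending.
    """

    positions: np.ndarray
    values: dict  # tissue -> (n_positions, n_replicates) float array
    probe_length: int = 60
    step: int = 2

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def tissues(self) -> list[str]:
        return list(self.values)

    def flat(self, tissue: str) -> np.ndarray:
        return self.values[tissue].ravel()

    def n_replicates(self, tissue: str) -> int:
        return self.values[tissue].shape[1]


def merge_replicates(matrix: IntensityMatrix) -> ReplicateTrack:
    """Fold each tissue's sense/antisense channels into per-position replicates.

    A tissue with a single channel yields singleton replicate sets; the
    count of replicate channels per tissue may differ (orphan strands are
    kept, not dropped).
    """
    order = np.argsort(matrix.positions, kind="stable")
    positions = matrix.positions[order]
    values = {}
    for tissue in matrix.tissues:
        cols = matrix.columns_for(tissue)
        values[tissue] = matrix.values[order][:, cols]
    return ReplicateTrack(
        positions=positions,
        values=values,
        probe_length=matrix.probe_length,
    )


def normalize_pipeline(matrix: IntensityMatrix, per_tissue: bool = True) -> ReplicateTrack:
    """raw -> quantile -> zscore -> replicate track, in one call."""
    return merge_replicates(zscore(quantile_normalize(matrix, per_tissue=per_tissue)))


__all__ = [
    "DegenerateVarianceError",
    "ReplicateTrack",
    "quantile_normalize",
    "zscore",
    "merge_replicates",
    "normalize_pipeline",
]
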