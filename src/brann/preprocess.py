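"""Rescaling, marker filtering, and missing-genotype imputation.

Inputs and targets are mapped into [-1, +1] before training (the min-max
convention of MATLAB's ``mapminmax``): for a variable x with observed range
[x_min, x_max] and target range [A_min, A_max],

    x_new = A_min + (x - x_min) / (x_max - x_min) * (A_max - A_min).

Scaling statistics are estimated per variable on the training partition and
the transform is applied unchanged to validation/test partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .relationships import MarkerMatrix, allele_frequencies

__all__ = [
    "ScaleRecord",
    "minmax_scale",
    "minmax_unscale",
    "scale_matrix",
    "apply_scale_matrix",
    "maf_filter",
    "impute_missing",
    "center_targets",
]


@dataclass
class ScaleRecord:
    """Min-max scaling parameters for one variable."""

    x_min: float
    x_max: float
    a_min: float = -1.0
    a_max: float = 1.0
    degenerate: bool = False  # constant input: everything maps to midpoint

    def scale(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.degenerate:
            return np.full_like(x, 0.5 * (self.a_min + self.a_max))
        return self.a_min + (x - self.x_min) / (self.x_max - self.x_min) * (
            self.a_max - self.a_min
        )

    def unscale(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self.degenerate:
            return np.full_like(y, self.x_min)
        return self.x_min + (y - self.a_min) / (self.a_max - self.a_min) * (
            self.x_max - self.x_min
        )

    @property
    def slope(self) -> float:
        """d(original)/d(scaled); used to map gradients back to trait units."""
        if self.degenerate:
            return 0.0
        return (self.x_max - self.x_min) / (self.a_max - self.a_min)


def minmax_scale(
    x: np.ndarray, a_min: float = -1.0, a_max: float = 1.0
) -> tuple[np.ndarray, ScaleRecord]:
    """Rescale a vector into [a_min, a_max]; constant vectors map to the midpoint."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot scale an empty vector")
    x_min, x_max = float(np.min(x)), float(np.max(x))
    rec = ScaleRecord(x_min, x_max, a_min, a_max, degenerate=(x_max == x_min))
    return rec.scale(x), rec


def minmax_unscale(y: np.ndarray, rec: ScaleRecord) -> np.ndarray:
    """Inverse of :func:`minmax_scale` (degenerate records return the constant)."""
    return rec.unscale(y)


def scale_matrix(
    x: np.ndarray, a_min: float = -1.0, a_max: float = 1.0
) -> tuple[np.ndarray, list[ScaleRecord]]:
    """Column-wise min-max scaling of an input matrix."""
    x = np.asarray(x, dtype=float)
    cols, recs = [], []
    for j in range(x.shape[1]):
        col, rec = minmax_scale(x[:, j], a_min, a_max)
        cols.append(col)
        recs.append(rec)
    return np.column_stack(cols) if cols else x.copy(), recs


def apply_scale_matrix(x: np.ndarray, recs: list[ScaleRecord]) -> np.ndarray:
    """Apply previously estimated column scalings to new rows."""
    x = np.asarray(x, dtype=float)
    if x.shape[1] != len(recs):
        raise ValueError("number of columns does not match scale records")
    return np.column_stack([recs[j].scale(x[:, j]) for j in range(x.shape[1])])


def maf_filter(
    m: MarkerMatrix, threshold: float = 0.05
) -> tuple[MarkerMatrix, list[str]]:
    """Drop markers whose minor allele frequency is strictly below threshold."""
    if not (0.0 <= threshold <= 0.5):
        raise ValueError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    mu = allele_frequencies(m).mu
    maf = np.minimum(mu, 1.0 - mu)
    keep = maf >= threshold
    kept_ids = [mid for mid, k in zip(m.marker_ids, keep) if k]
    filtered = MarkerMatrix(
        codes=m.codes[:, keep],
        ploidy=m.ploidy,
        missing_mask=m.missing_mask[:, keep],
        individual_ids=list(m.individual_ids),
        marker_ids=kept_ids,
    )
    return filtered, kept_ids


def impute_missing(m: MarkerMatrix, rng_seed: int) -> MarkerMatrix:
    """Fill missing calls with draws from the marginal genotype distribution.

    Each missing call at marker j is replaced by Binomial(ploidy, p̂_j)
    where p̂_j is the allele frequency estimated from the non-missing calls,
    so imputation is frequency-preserving in expectation.
    """
    if not m.missing_mask.any():
        return MarkerMatrix(
            codes=m.codes.copy(),
            ploidy=m.ploidy,
            missing_mask=m.missing_mask.copy(),
            individual_ids=list(m.individual_ids),
            marker_ids=list(m.marker_ids),
        )
    mu = allele_frequencies(m).mu
    rng = np.random.default_rng(rng_seed)
    codes = m.codes.copy()
    rows, cols = np.nonzero(m.missing_mask)
    codes[rows, cols] = rng.binomial(m.ploidy, mu[cols])
    return MarkerMatrix(
        codes=codes,
        ploidy=m.ploidy,
        missing_mask=np.zeros_like(m.missing_mask),
        individual_ids=list(m.individual_ids),
        marker_ids=list(m.marker_ids),
    )


def center_targets(t: np.ndarray) -> tuple[np.ndarray, float]:
    """Deviations from the mean; removes the outer bias from the network."""
    t = np.asarray(t, dtype=float)
    if t.size == 0:
        raise ValueError("cannot center an empty target vector")
    mean = float(np.mean(t))
    return t - mean, mean
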