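"""Pedigree- and marker-derived relationship matrices and network input features.

The additive infinitesimal model can be written as a single-neuron linear
network whose inputs are, equivalently, rows of the Cholesky factor C of the
numerator relationship matrix A (t = C u* + e), rows of A itself
(t = A u** + e), or rows of A⁻¹ (t = A⁻¹ u*** + e).  This module builds A
from a pedigree by the tabular method, the genomic relationship matrix G
from centered marker codes, and exposes the three feature representations
(plus centered marker codes themselves) as network input matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "UNKNOWN",
    "Pedigree",
    "MarkerMatrix",
    "RelationshipMatrix",
    "AlleleFrequencies",
    "PedigreeError",
    "numerator_relationship",
    "cholesky_lower",
    "allele_frequencies",
    "genomic_relationship",
    "feature_matrix",
]

#: sentinel for an unknown parent
UNKNOWN = "0"

# eigenvalues more negative than -PSD_RTOL * max eigenvalue are treated as
# genuinely indefinite; anything above is clipped to zero
PSD_RTOL = 1e-8


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, duplicate id, ...)."""


@dataclass
class Pedigree:
    """Ordered (individual, sire, dam) triples; ``"0"``/empty means unknown.

    After construction the records are topologically sorted so that parents
    always precede offspring; a cycle raises :class:`PedigreeError` naming an
    individual on the cycle.
    """

    records: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        recs = [
            (str(i), str(s) if s not in ("", None) else UNKNOWN,
             str(d) if d not in ("", None) else UNKNOWN)
            for i, s, d in self.records
        ]
        ids = [r[0] for r in recs]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise PedigreeError(f"duplicate individual id {dup!r}")
        self.records = self._toposort(recs)

    @staticmethod
    def _toposort(recs: list[tuple[str, str, str]]) -> list[tuple[str, str, str]]:
        by_id = {r[0]: r for r in recs}
        order: list[tuple[str, str, str]] = []
        state: dict[str, int] = {}  # 0 in progress, 1 done

        for start in by_id:
            if state.get(start) == 1:
                continue
            stack = [(start, False)]
            while stack:
                node, expanded = stack.pop()
                if expanded:
                    state[node] = 1
                    order.append(by_id[node])
                    continue
                if state.get(node) == 1:
                    continue
                if state.get(node) == 0:
                    raise PedigreeError(
                        f"cycle in pedigree involving individual {node!r}"
                    )
                state[node] = 0
                stack.append((node, True))
                _, sire, dam = by_id[node]
                for parent in (sire, dam):
                    if parent != UNKNOWN and parent in by_id:
                        if state.get(parent) == 0:
                            raise PedigreeError(
                                f"cycle in pedigree involving individual {parent!r}"
                            )
                        if state.get(parent) != 1:
                            stack.append((parent, False))
        return order

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class MarkerMatrix:
    """n × p genotype codes with a missing-value mask.

    ``codes`` holds 0/1/2 allele counts for biallelic SNPs (ploidy 2) or
    0/1 presence/absence scores for dominant markers (ploidy 1).  Entries
    under ``missing_mask`` are ignored by all downstream statistics.
    """

    codes: np.ndarray
    ploidy: int = 2
    missing_mask: np.ndarray | None = None
    individual_ids: list[str] = field(default_factory=list)
    marker_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("marker codes must be a 2-D array")
        if self.ploidy not in (1, 2):
            raise ValueError(f"ploidy must be 1 or 2, got {self.ploidy}")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.codes.shape, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.codes.shape:
                raise ValueError("missing_mask shape must match codes shape")
        observed = self.codes[~self.missing_mask]
        if observed.size and (
            (observed < 0).any() or (observed > self.ploidy).any()
        ):
            bad = np.argwhere(
                ~self.missing_mask
                & ((self.codes < 0) | (self.codes > self.ploidy))
            )[0]
            raise ValueError(
                f"genotype code out of range at row {bad[0]}, column {bad[1]} "
                f"(allowed 0..{self.ploidy})"
            )
        n, p = self.codes.shape
        if not self.individual_ids:
            self.individual_ids = [f"ind{i}" for i in range(n)]
        if not self.marker_ids:
            self.marker_ids = [f"m{j}" for j in range(p)]

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]


@dataclass
class RelationshipMatrix:
    """Symmetric n × n kinship-type matrix (A, G, a Cholesky factor, or A⁻¹)."""

    values: np.ndarray
    kind: Literal["numerator_A", "genomic_G", "cholesky_C", "inverse_Ainv"]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != m:
            raise ValueError("relationship matrix must be square")
        if self.kind in ("numerator_A", "genomic_G"):
            if np.abs(self.values - self.values.T).max() > 1e-10:
                raise ValueError(f"{self.kind} matrix is not symmetric")
        if not self.ids:
            self.ids = [f"ind{i}" for i in range(n)]

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class AlleleFrequencies:
    """Per-marker estimated frequency of the counted allele."""

    mu: np.ndarray
    counted_alleles: np.ndarray  # non-missing allele copies per marker

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        if ((self.mu < 0) | (self.mu > 1)).any():
            raise ValueError("allele frequencies must lie in [0, 1]")


def numerator_relationship(ped: Pedigree) -> RelationshipMatrix:
    """Expected additive relationships A = {a_ij} by the tabular method.

    Founders are assumed non-inbred and unrelated; unknown parents
    contribute zero.  The diagonal is 1 + F_i with F_i half the additive
    relationship between the parents of i.
    """
    ids = ped.ids
    index = {iid: k for k, iid in enumerate(ids)}
    n = len(ids)
    a = np.zeros((n, n))

    for i, (iid, sire, dam) in enumerate(ped.records):
        si = index.get(sire, -1) if sire != UNKNOWN else -1
        di = index.get(dam, -1) if dam != UNKNOWN else -1
        for j in range(i):
            val = 0.0
            if si >= 0:
                val += 0.5 * a[j, si]
            if di >= 0:
                val += 0.5 * a[j, di]
            a[i, j] = a[j, i] = val
        inb = 0.5 * a[si, di] if (si >= 0 and di >= 0) else 0.0
        a[i, i] = 1.0 + inb
    return RelationshipMatrix(a, kind="numerator_A", ids=ids)


def cholesky_lower(rel: RelationshipMatrix) -> RelationshipMatrix:
    """Lower-triangular factor C with CC' = rel.values.

    Finite-sample G matrices can be numerically semidefinite; eigenvalues
    down to -1e-8 times the largest are tolerated (clipped at zero via a
    tiny diagonal jitter).  A genuinely indefinite matrix raises, reporting
    its smallest eigenvalue.
    """
    mat = np.asarray(rel.values, dtype=float)
    try:
        c = np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        eig = scipy.linalg.eigvalsh(mat)
        if eig[0] < -PSD_RTOL * max(eig[-1], 1.0):
            raise np.linalg.LinAlgError(
                f"matrix is not positive semidefinite "
                f"(smallest eigenvalue {eig[0]:.3e})"
            ) from None
        jitter = 1e-10 * max(np.trace(mat) / mat.shape[0], 1.0) - min(eig[0], 0.0)
        c = np.linalg.cholesky(mat + jitter * np.eye(mat.shape[0]))
    return RelationshipMatrix(c, kind="cholesky_C", ids=list(rel.ids))


def allele_frequencies(m: MarkerMatrix) -> AlleleFrequencies:
    """Estimate per-marker allele frequencies, ignoring missing calls."""
    obs = ~m.missing_mask
    counts = obs.sum(axis=0)
    if (counts == 0).any():
        j = int(np.argmin(counts))
        raise ValueError(f"marker {m.marker_ids[j]!r} has no non-missing calls")
    totals = np.where(obs, m.codes, 0).sum(axis=0)
    mu = totals / (m.ploidy * counts)
    return AlleleFrequencies(mu=mu, counted_alleles=m.ploidy * counts)


def genomic_relationship(
    m: MarkerMatrix, freqs: AlleleFrequencies | None = None
) -> RelationshipMatrix:
    """Marker-derived relationship matrix G = ZZ' / (c·Σ μ(1−μ)).

    Z = M − E where E holds the genotype expectations ploidy·μ_j under
    Hardy–Weinberg equilibrium; the denominator constant c equals the
    ploidy (2 for SNP codes, 1 for dominant 0/1 markers).  Frequencies are
    estimated from the supplied matrix unless ``freqs`` (e.g. training-set
    frequencies) is given.
    """
    if m.missing_mask.any():
        raise ValueError("genomic_relationship requires a fully imputed matrix")
    if freqs is None:
        freqs = allele_frequencies(m)
    mu = freqs.mu
    denom = m.ploidy * float(np.sum(mu * (1.0 - mu)))
    if denom <= 0:
        raise ValueError(
            "all markers are monomorphic: genomic relationship undefined"
        )
    z = centered_codes(m, freqs)
    g = (z @ z.T) / denom
    g = 0.5 * (g + g.T)
    return RelationshipMatrix(g, kind="genomic_G", ids=list(m.individual_ids))


def centered_codes(
    m: MarkerMatrix, freqs: AlleleFrequencies | None = None
) -> np.ndarray:
    """Centered genotype codes Z = M − E (E = ploidy·μ per column)."""
    if freqs is None:
        freqs = allele_frequencies(m)
    return m.codes.astype(float) - m.ploidy * freqs.mu[None, :]


def feature_matrix(
    source: RelationshipMatrix | MarkerMatrix,
    mode: Literal["cholesky", "relationship", "inverse", "centered_markers"],
    normalize: bool = False,
) -> np.ndarray:
    """Network input rows p_i under one of the model representations.

    ``cholesky``: rows of C (t = Cu* + e); ``relationship``: rows of A or G
    (t = Au** + e); ``inverse``: rows of A⁻¹ (t = A⁻¹u*** + e);
    ``centered_markers``: rows of Z (marker-regression incidence).  With
    ``normalize`` the centered codes are divided by sqrt(ploidy·Σμ(1−μ)) so
    that P P' equals G and connection-strength variance is on the additive
    trait-variance scale.
    """
    if mode == "centered_markers":
        if not isinstance(source, MarkerMatrix):
            raise TypeError("centered_markers mode requires a MarkerMatrix")
        freqs = allele_frequencies(source)
        z = centered_codes(source, freqs)
        if normalize:
            denom = source.ploidy * float(np.sum(freqs.mu * (1 - freqs.mu)))
            if denom <= 0:
                raise ValueError("monomorphic panel cannot be normalized")
            z = z / np.sqrt(denom)
        return z
    if not isinstance(source, RelationshipMatrix):
        raise TypeError(f"mode {mode!r} requires a RelationshipMatrix")
    if mode == "relationship":
        return source.values.copy()
    if mode == "cholesky":
        if source.kind == "cholesky_C":
            return source.values.copy()
        return cholesky_lower(source).values
    if mode == "inverse":
        n = source.n
        cond = np.linalg.cond(source.values)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                "relationship matrix is singular: inverse representation "
                "unavailable"
            )
        return np.linalg.solve(source.values, np.eye(n))
    raise ValueError(f"unknown feature mode {mode!r}")
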