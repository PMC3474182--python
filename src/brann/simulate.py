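"""Synthetic genotypes, pedigrees, and phenotypes for pipeline testing.

Loci are simulated independently (linkage equilibrium, the assumption under
which the genomic-relationship denominator 2Σμ(1−μ) is derived).  The
phenotype is

    t = g_add + g_epi + e,

with additive values g_add = Z_qtl·a from a random subset of loci and an
epistatic component built from pairwise products of centered codes.  Two
interaction topologies are available: ``directional`` (default), where the
epistatic deviation is quadratic in the polygenic score — pairwise products
with rank-one effect structure e_jk = a_j·a_k, the classical synergistic
epistasis model and a low-dimensional interaction that a small tanh hidden
layer can represent while a linear regression cannot — and
``random_pairs``, unstructured products over random QTL pairs, whose
effective dimension grows with the pair count and which no small network
is expected to capture.  Components are rescaled so that the realized
additive:epistatic variance ratio and the heritability var(g)/var(t) = h²
match the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .relationships import MarkerMatrix, Pedigree, UNKNOWN

__all__ = [
    "SimConfig",
    "simulate_markers",
    "simulate_pedigree",
    "simulate_phenotypes",
    "simulate_dataset",
]


@dataclass
class SimConfig:
    """Generator settings for one synthetic dataset."""

    n: int = 300
    p: int = 300
    marker_type: Literal["snp_012", "dart_01"] = "snp_012"
    freq_min: float = 0.05
    freq_max: float = 0.95
    h2: float = 0.5
    epistatic_fraction: float = 0.0
    n_qtl: int = 20
    epistasis: Literal["directional", "random_pairs"] = "directional"
    n_epistatic_pairs: int | None = None  # random_pairs: default n_qtl pairs
    missing_rate: float = 0.0
    generations: int = 1
    family_size: int = 2
    n_founders: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("h2", "epistatic_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.freq_min <= self.freq_max <= 1.0:
            raise ValueError("allele-frequency bounds must satisfy 0<=min<=max<=1")
        if self.n_qtl > self.p:
            raise ValueError("n_qtl cannot exceed the number of markers")

    @property
    def ploidy(self) -> int:
        return 2 if self.marker_type == "snp_012" else 1


def simulate_markers(cfg: SimConfig) -> MarkerMatrix:
    """Independent loci with Uniform(freq_min, freq_max) allele frequencies."""
    rng = np.random.default_rng(cfg.seed)
    freqs = rng.uniform(cfg.freq_min, cfg.freq_max, size=cfg.p)
    codes = rng.binomial(cfg.ploidy, freqs, size=(cfg.n, cfg.p))
    mask = np.zeros((cfg.n, cfg.p), dtype=bool)
    if cfg.missing_rate > 0:
        mask = rng.random((cfg.n, cfg.p)) < cfg.missing_rate
        # never blank out a whole column: frequencies must stay estimable
        full = mask.all(axis=0)
        mask[0, full] = False
    return MarkerMatrix(
        codes=codes,
        ploidy=cfg.ploidy,
        missing_mask=mask,
        individual_ids=[f"ind{i}" for i in range(cfg.n)],
        marker_ids=[f"m{j}" for j in range(cfg.p)],
    )


def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Multi-generation pedigree: unrelated founders, then random matings.

    Each post-founder generation pairs random parents from the previous
    generation and produces ``family_size`` offspring per pair, until the
    requested total of ``cfg.n`` individuals is reached (or the generation
    count runs out).
    """
    if cfg.generations < 1:
        raise ValueError("generations must be >= 1")
    rng = np.random.default_rng(cfg.seed + 1)
    n_founders = min(cfg.n_founders, cfg.n) if cfg.generations > 1 else cfg.n
    records: list[tuple[str, str, str]] = [
        (f"ind{i}", UNKNOWN, UNKNOWN) for i in range(n_founders)
    ]
    prev = [r[0] for r in records]
    next_id = n_founders
    for _ in range(1, cfg.generations):
        if next_id >= cfg.n or len(prev) < 2:
            break
        current: list[str] = []
        while next_id < cfg.n and len(current) < max(
            cfg.family_size, len(prev)
        ) * cfg.family_size:
            sire, dam = rng.choice(prev, size=2, replace=False)
            for _ in range(cfg.family_size):
                if next_id >= cfg.n:
                    break
                iid = f"ind{next_id}"
                records.append((iid, sire, dam))
                current.append(iid)
                next_id += 1
        prev = current
    return Pedigree(records)


def simulate_phenotypes(
    m: MarkerMatrix, cfg: SimConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Phenotypes plus the true additive and total genetic values.

    Returns (targets, g_additive, g_total).  Truths are for recovery tests
    only and are written to a separate file by the CLI so no pipeline stage
    can consume them accidentally.
    """
    if m.missing_mask.any():
        raise ValueError("simulate_phenotypes requires complete genotypes")
    rng = np.random.default_rng(cfg.seed + 2)
    n = m.n_individuals
    z = m.codes.astype(float)
    z = z - z.mean(axis=0, keepdims=True)

    qtl = rng.choice(m.n_markers, size=cfg.n_qtl, replace=False)
    a = rng.normal(0.0, 1.0, size=cfg.n_qtl)
    g_add = z[:, qtl] @ a

    add_frac = 1.0 - cfg.epistatic_fraction
    if cfg.epistatic_fraction > 0 and cfg.n_qtl >= 2:
        if cfg.epistasis == "directional":
            # synergistic (directional) epistasis: the interaction deviation
            # is quadratic in the polygenic score, i.e. pairwise products
            # z_j·z_k with rank-one effect structure e_jk = a_j·a_k
            g_epi = g_add**2
        else:
            n_pairs = cfg.n_epistatic_pairs or cfg.n_qtl
            pairs = np.column_stack(
                [rng.choice(cfg.n_qtl, size=n_pairs),
                 rng.choice(cfg.n_qtl, size=n_pairs)]
            )
            # avoid self-pairs (a locus with itself is dominance-like)
            same = pairs[:, 0] == pairs[:, 1]
            pairs[same, 1] = (pairs[same, 1] + 1) % cfg.n_qtl
            eff = rng.normal(0.0, 1.0, size=n_pairs)
            g_epi = (z[:, qtl[pairs[:, 0]]] * z[:, qtl[pairs[:, 1]]]) @ eff
        g_epi = g_epi - g_epi.mean()
    else:
        g_epi = np.zeros(n)
        add_frac = 1.0

    # rescale realized components to the requested variance shares
    v_add = float(np.var(g_add))
    v_epi = float(np.var(g_epi))
    if v_add > 0:
        g_add = g_add * np.sqrt(add_frac / v_add)
    if v_epi > 0:
        g_epi = g_epi * np.sqrt((1.0 - add_frac) / v_epi)
    g_total = g_add + g_epi
    v_g = float(np.var(g_total))

    if cfg.h2 >= 1.0:
        t = g_total.copy()
    elif cfg.h2 <= 0.0:
        if v_g > 0:
            import warnings

            warnings.warn("h2 = 0: genetic values generated but drowned in noise")
        t = rng.normal(0.0, 1.0, size=n)
    else:
        sigma_e = np.sqrt(v_g * (1.0 - cfg.h2) / cfg.h2)
        t = g_total + rng.normal(0.0, sigma_e, size=n)
    return t, g_add, g_total


def simulate_dataset(cfg: SimConfig):
    """Markers + phenotypes + truths in one call (no missingness applied)."""
    markers = simulate_markers(cfg)
    complete = MarkerMatrix(
        codes=markers.codes,
        ploidy=markers.ploidy,
        missing_mask=None,
        individual_ids=list(markers.individual_ids),
        marker_ids=list(markers.marker_ids),
    )
    t, g_add, g_total = simulate_phenotypes(complete, cfg)
    return markers, t, g_add, g_total
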