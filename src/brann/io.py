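"""Delimited-text readers and writers for genotypes, pedigrees, and models.

Formats: CSV/TSV matrices with id headers (delimiter auto-detected,
comma default), the PLINK ``.raw`` dialect for genotypes (space-separated
with FID/IID/PAT/MAT/SEX/PHENOTYPE preamble columns), three-column pedigree
files ("0" or empty marks an unknown parent), and versioned JSON for model
files and run manifests.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .network import Architecture, WeightVector
from .regularize import RegularizationState, TrainedNetwork
from .relationships import MarkerMatrix, Pedigree, RelationshipMatrix

__all__ = [
    "read_markers",
    "write_markers",
    "read_pedigree",
    "write_pedigree",
    "read_phenotypes",
    "write_phenotypes",
    "read_relationship_matrix",
    "write_relationship_matrix",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1

PLINK_PREAMBLE = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _sniff_sep(path: str | Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") > first.count(",") else ","


def read_markers(
    path: str | Path, dialect: str = "csv_matrix", ploidy: int = 2
) -> MarkerMatrix:
    """Read a genotype matrix; NA/empty cells become missing-mask entries."""
    path = Path(path)
    if dialect == "csv_matrix":
        frame = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
        ids = [str(i) for i in frame.index]
        marker_ids = [str(c) for c in frame.columns]
    elif dialect == "plink_raw":
        frame = pd.read_csv(path, sep=r"\s+")
        missing_pre = [c for c in PLINK_PREAMBLE if c not in frame.columns]
        if missing_pre:
            raise ValueError(
                f"not a PLINK .raw file: missing columns {missing_pre}"
            )
        ids = [str(i) for i in frame["IID"]]
        frame = frame.drop(columns=PLINK_PREAMBLE)
        marker_ids = [str(c) for c in frame.columns]
    else:
        raise ValueError(f"unknown marker dialect {dialect!r}")

    values = frame.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    mask = ~np.isfinite(values)
    codes = np.where(mask, 0, values)
    if not np.array_equal(codes, np.round(codes)):
        bad = np.argwhere(codes != np.round(codes))[0]
        raise ValueError(
            f"non-integer genotype code at row {bad[0]}, column {bad[1]}"
        )
    codes = codes.astype(int)
    observed = codes[~mask]
    if observed.size and ((observed < 0).any() or (observed > ploidy).any()):
        bad = np.argwhere(~mask & ((codes < 0) | (codes > ploidy)))[0]
        raise ValueError(
            f"genotype code {codes[bad[0], bad[1]]} out of range at row "
            f"{bad[0]} ({ids[bad[0]]!r}), column {bad[1]} "
            f"({marker_ids[bad[1]]!r}); allowed 0..{ploidy}"
        )
    return MarkerMatrix(
        codes=codes,
        ploidy=ploidy,
        missing_mask=mask,
        individual_ids=ids,
        marker_ids=marker_ids,
    )


def write_markers(m: MarkerMatrix, path: str | Path, sep: str = ",") -> None:
    values = m.codes.astype(object)
    values[m.missing_mask] = "NA"
    frame = pd.DataFrame(values, index=m.individual_ids, columns=m.marker_ids)
    frame.to_csv(path, sep=sep)


def read_pedigree(path: str | Path) -> Pedigree:
    """Three-column delimited text: individual, sire, dam."""
    path = Path(path)
    frame = pd.read_csv(
        path, sep=_sniff_sep(path), header=None, dtype=str, comment="#"
    ).fillna("0")
    if frame.shape[1] < 3:
        raise ValueError("pedigree file needs 3 columns: id, sire, dam")
    first = [str(v).lower() for v in frame.iloc[0]]
    if first[:3] in (["id", "sire", "dam"], ["individual", "sire", "dam"]):
        frame = frame.iloc[1:]
    records = [
        (str(r.iloc[0]).strip(), str(r.iloc[1]).strip(), str(r.iloc[2]).strip())
        for _, r in frame.iterrows()
    ]
    return Pedigree(records)


def write_pedigree(ped: Pedigree, path: str | Path, sep: str = ",") -> None:
    with open(path, "w") as fh:
        for iid, sire, dam in ped.records:
            fh.write(f"{iid}{sep}{sire}{sep}{dam}\n")


def read_phenotypes(
    path: str | Path, align_ids: list[str] | None = None
) -> tuple[np.ndarray, list[str], list[str]]:
    """Two-column (id, value) table; returns (values, ids, unmatched ids)."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sniff_sep(path), header=None, dtype=str)
    first = str(frame.iloc[0, 1])
    try:
        float(first)
    except ValueError:
        frame = frame.iloc[1:]
    ids = [str(v).strip() for v in frame.iloc[:, 0]]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"duplicate phenotype id {dup!r}")
    values = np.empty(len(ids))
    for k, raw in enumerate(frame.iloc[:, 1]):
        try:
            values[k] = float(raw)
        except (TypeError, ValueError):
            raise ValueError(
                f"non-numeric phenotype {raw!r} at line {k + 1}"
            ) from None
    unmatched: list[str] = []
    if align_ids is not None:
        table = dict(zip(ids, values))
        unmatched = [i for i in ids if i not in set(align_ids)]
        missing = [i for i in align_ids if i not in table]
        if missing:
            raise ValueError(f"no phenotype for ids {missing[:5]}")
        values = np.array([table[i] for i in align_ids])
        ids = list(align_ids)
        if unmatched:
            import warnings

            warnings.warn(f"{len(unmatched)} phenotype ids not in genotypes; excluded")
    return values, ids, unmatched


def write_phenotypes(
    values: np.ndarray, ids: list[str], path: str | Path, sep: str = ","
) -> None:
    with open(path, "w") as fh:
        for iid, val in zip(ids, values):
            fh.write(f"{iid}{sep}{float(val)!r}\n")


def read_relationship_matrix(path: str | Path, kind: str = "numerator_A") -> RelationshipMatrix:
    path = Path(path)
    frame = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    return RelationshipMatrix(
        frame.to_numpy(dtype=float), kind=kind, ids=[str(i) for i in frame.index]
    )


def write_relationship_matrix(
    rel: RelationshipMatrix, path: str | Path, sep: str = ","
) -> None:
    pd.DataFrame(rel.values, index=rel.ids, columns=rel.ids).to_csv(path, sep=sep)


def save_model(net: TrainedNetwork, path: str | Path) -> None:
    """Versioned JSON dump of architecture, flattened weights, and state."""
    arch = net.arch
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "flatten_order": "input_to_hidden_row_major,hidden_biases,"
        "hidden_to_output,outer_bias",
        "architecture": {
            "n_inputs": arch.n_inputs,
            "n_neurons": arch.n_neurons,
            "hidden_activation": arch.hidden_activation,
            "linear": arch.linear,
            "outer_bias_trainable": arch.outer_bias_trainable,
        },
        "weights": net.weights.flatten().tolist(),
        "state": {
            "alpha": net.state.alpha,
            "beta": net.state.beta,
            "gamma": net.state.gamma,
            "e_d": net.state.e_d,
            "e_w": net.state.e_w,
        },
        "target_mean": net.target_mean,
        "status": net.status,
        "n_epochs": net.n_epochs,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path: str | Path) -> TrainedNetwork:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {payload.get('format_version')}"
        )
    arch = Architecture(**payload["architecture"])
    w = np.asarray(payload["weights"], dtype=float)
    if w.size != arch.n_weights:
        raise ValueError(
            f"model file has {w.size} weights, architecture requires "
            f"{arch.n_weights}"
        )
    st = payload["state"]
    state = RegularizationState(
        alpha=st["alpha"], beta=st["beta"], gamma=st["gamma"],
        e_d=st["e_d"], e_w=st["e_w"],
    )
    return TrainedNetwork(
        arch=arch,
        weights=WeightVector.from_flat(arch, w),
        state=state,
        status=payload.get("status", "loaded"),
        n_epochs=payload.get("n_epochs", 0),
        target_mean=payload.get("target_mean", 0.0),
    )
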