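"""Readers and writers for the tabular interchange formats.

All files are plain TSV with header rows; matrices carry the drug_id as the
first column and a JSON sidecar records the provenance parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pairs import DDIPair, SplitAssignment

DRUG_COLUMNS = ["drug_id", "name", "smiles", "description"]


def read_drug_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str).fillna("")
    missing = [c for c in DRUG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df["drug_id"].duplicated().any():
        dup = df.loc[df["drug_id"].duplicated(), "drug_id"].iloc[0]
        raise ValueError(f"{path}: duplicate drug_id {dup!r}")
    return df


def read_pairs(path: str | Path) -> list[DDIPair]:
    df = pd.read_csv(path, sep="\t", dtype={"drug_a": str, "drug_b": str, "class_id": int})
    return [
        DDIPair(a, b, int(c))
        for a, b, c in zip(df["drug_a"], df["drug_b"], df["class_id"])
    ]


def read_class_catalog(path: str | Path) -> dict[int, str]:
    df = pd.read_csv(path, sep="\t", dtype={"class_id": int, "description": str})
    return dict(zip(df["class_id"], df["description"]))


def write_split(split: SplitAssignment, path: str | Path) -> None:
    rows = [
        (p.drug_a, p.drug_b, p.class_id, part)
        for p, part in split.partition_of.items()
    ]
    pd.DataFrame(rows, columns=["drug_a", "drug_b", "class_id", "partition"]).to_csv(
        path, sep="\t", index=False
    )


def read_split(path: str | Path) -> dict[str, list[DDIPair]]:
    df = pd.read_csv(path, sep="\t", dtype={"drug_a": str, "drug_b": str})
    out: dict[str, list[DDIPair]] = {"train": [], "val": [], "test": []}
    for a, b, c, part in zip(df["drug_a"], df["drug_b"], df["class_id"], df["partition"]):
        out[part].append(DDIPair(a, b, int(c)))
    return out


def write_matrix(
    matrix: np.ndarray,
    drug_ids: list[str],
    path: str | Path,
    sidecar: dict | None = None,
) -> None:
    """Dense matrix TSV with a drug_id index column plus a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(matrix, index=pd.Index(drug_ids, name="drug_id"))
    df.to_csv(path, sep="\t")
    if sidecar is not None:
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col="drug_id")
    return df.to_numpy(dtype=float), [str(i) for i in df.index]
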