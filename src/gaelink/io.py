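"""TSV readers/writers and the flat key=value configuration format.

Everything on disk is keyed by string identifiers; integer indices never
leave memory. Floats are written with repr-level precision so round trips
are exact at the printed precision.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .model import Hyperparams
from .types import AssociationMatrix, DiseaseDAG, SimilarityMatrix

__all__ = [
    "read_association_edges",
    "write_association_edges",
    "read_similarity_tsv",
    "write_similarity_tsv",
    "read_dag",
    "write_dag",
    "read_config",
    "write_config",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

FLOAT_FMT = "%.17g"


def read_association_edges(path: str | Path) -> AssociationMatrix:
    """Two-column headered edge list; duplicate edges collapse to one."""
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # noqa: BLE001 - surface as a data error
        raise DataError(f"cannot read association edge list {path}: {exc}") from exc
    if frame.shape[1] != 2:
        raise DataError(
            f"association edge list must have exactly 2 columns, got {frame.shape[1]}"
        )
    if frame.isna().any().any():
        raise DataError("association edge list contains missing values")
    mirnas = sorted(frame.iloc[:, 0].unique())
    diseases = sorted(frame.iloc[:, 1].unique())
    mi = {name: k for k, name in enumerate(mirnas)}
    di = {name: k for k, name in enumerate(diseases)}
    values = np.zeros((len(mirnas), len(diseases)))
    for a, b in frame.itertuples(index=False):
        values[mi[a], di[b]] = 1.0
    return AssociationMatrix(values, mirnas, diseases)


def write_association_edges(path: str | Path, Y: AssociationMatrix) -> None:
    rows, cols = np.nonzero(Y.values)
    frame = pd.DataFrame(
        {
            "mirna_id": [Y.mirna_ids[i] for i in rows],
            "disease_id": [Y.disease_ids[j] for j in cols],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_similarity_tsv(path: str | Path) -> SimilarityMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if list(frame.index) != list(frame.columns):
        raise DataError(f"similarity table {path} rows/columns labels disagree")
    return SimilarityMatrix(frame.to_numpy(dtype=float), [str(x) for x in frame.index])


def write_similarity_tsv(path: str | Path, S: SimilarityMatrix) -> None:
    frame = pd.DataFrame(S.values, index=S.ids, columns=S.ids)
    frame.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def write_matrix_tsv(
    path: str | Path, values: np.ndarray, row_ids: list[str], col_ids: list[str]
) -> None:
    pd.DataFrame(values, index=row_ids, columns=col_ids).to_csv(
        path, sep="\t", float_format=FLOAT_FMT
    )


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return (
        frame.to_numpy(dtype=float),
        [str(x) for x in frame.index],
        [str(x) for x in frame.columns],
    )


def read_dag(edges_path: str | Path, membership_path: str | Path) -> DiseaseDAG:
    """(child, parent) edge list plus a disease -> DAG-node membership table."""
    edges_frame = pd.read_csv(edges_path, sep="\t", dtype=str)
    members_frame = pd.read_csv(membership_path, sep="\t", dtype=str)
    if edges_frame.shape[1] != 2 or members_frame.shape[1] != 2:
        raise DataError("DAG inputs must each have exactly two columns")
    edges = {(str(c), str(p)) for c, p in edges_frame.itertuples(index=False)}
    roots = {str(d): str(node) for d, node in members_frame.itertuples(index=False)}
    nodes = sorted({x for e in edges for x in e} | set(roots.values()))
    return DiseaseDAG(nodes, edges, roots)


def write_dag(
    edges_path: str | Path, membership_path: str | Path, dag: DiseaseDAG
) -> None:
    pd.DataFrame(sorted(dag.parent_edges), columns=["child", "parent"]).to_csv(
        edges_path, sep="\t", index=False
    )
    pd.DataFrame(
        sorted(dag.disease_roots.items()), columns=["disease_id", "dag_node"]
    ).to_csv(membership_path, sep="\t", index=False)


_HP_FIELDS = {f.name: f.type for f in fields(Hyperparams)}


def _coerce(name: str, raw: str):
    if name in ("hidden_dim", "inter_dim", "max_epochs", "seed"):
        return int(raw)
    if name in ("attention_scale", "loss_mode"):
        return raw
    return float(raw)


def read_config(path: str | Path) -> Hyperparams:
    """Flat ``key = value`` file mirroring Hyperparams; unknown keys rejected."""
    values = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, _, raw = stripped.partition("=")
        key, raw = key.strip(), raw.strip()
        if key not in _HP_FIELDS:
            raise ConfigError(f"{path}:{lineno}: unknown configuration key {key!r}")
        try:
            values[key] = _coerce(key, raw)
        except ValueError as exc:
            raise ConfigError(f"{path}:{lineno}: bad value for {key!r}: {raw!r}") from exc
    return Hyperparams(**values)


def write_config(path: str | Path, hp: Hyperparams) -> None:
    lines = [f"{f.name} = {getattr(hp, f.name)}" for f in fields(Hyperparams)]
    Path(path).write_text("\n".join(lines) + "\n")
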