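"""Plain-text readers/writers for connectome artifacts.

Canonical interchange formats:

* parcel table — TSV with columns ``parcel_id, name, hemisphere,
  surface_area_mm2, network, neighbors`` (neighbors semicolon-joined ids);
* matrices (streamlines, lengths, axon counts) — dense CSV with parcel ids as
  both header and index, so ordering is never positional-only;
* subjects table — TSV with columns ``subject_id, callosal_area_mm2, sex,
  age_group, matrix_path`` (matrix paths relative to the table);
* histology parameters — flat YAML.

Readers validate all type invariants; writers emit files their paired reader
accepts unchanged.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    HistologyParams,
    MatrixValidationError,
    ParcelTable,
    SchemaError,
    SubjectRecord,
    validate_connectivity_matrix,
)

_PARCEL_COLUMNS = ["parcel_id", "name", "hemisphere", "surface_area_mm2",
                   "network", "neighbors"]
_SUBJECT_COLUMNS = ["subject_id", "callosal_area_mm2", "sex", "age_group",
                    "matrix_path"]


def write_parcel_table(parcels: ParcelTable, path: str | Path) -> None:
    df = parcels.table.reset_index()
    df["neighbors"] = [
        ";".join(str(j) for j in sorted(nb)) for nb in parcels.neighbors
    ]
    df[_PARCEL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_parcel_table(path: str | Path) -> ParcelTable:
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "hemisphere": str})
    missing = [c for c in _PARCEL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if df["parcel_id"].duplicated().any():
        dupes = df.loc[df["parcel_id"].duplicated(), "parcel_id"].tolist()
        raise SchemaError(f"{path}: duplicate parcel_id {dupes}")
    df = df.sort_values("parcel_id").set_index("parcel_id")
    df.index.name = "parcel_id"
    neighbors = []
    for pid, cell in df["neighbors"].items():
        if pd.isna(cell) or str(cell).strip() == "":
            neighbors.append(set())
            continue
        try:
            neighbors.append({int(tok) for tok in str(cell).split(";")})
        except ValueError as exc:
            raise SchemaError(
                f"{path}: parcel_id {pid}: unparseable neighbors {cell!r}"
            ) from exc
    table = df.drop(columns=["neighbors"])
    return ParcelTable(table, neighbors)  # ParcelTable.validate runs here


def write_matrix(matrix: np.ndarray, path: str | Path) -> None:
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    pd.DataFrame(
        matrix,
        index=pd.RangeIndex(n, name="parcel_id"),
        columns=[str(i) for i in range(n)],
    ).to_csv(path)


def read_matrix(
    path: str | Path,
    parcels: ParcelTable | None = None,
    kind: str = "streamline",
) -> np.ndarray:
    """Read and validate a dense square matrix CSV.

    ``kind`` is ``"streamline"``, ``"length"`` or ``"axon"``; all share the
    symmetric/nonnegative/zero-diagonal contract. Dimensions are checked
    against ``parcels`` when given, and explicit ids in the header/index must
    be the dense 0..n-1 range.
    """
    df = pd.read_csv(path, index_col=0)
    try:
        cols = [int(c) for c in df.columns]
        rows = [int(r) for r in df.index]
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: matrix header/index must be parcel ids") from exc
    n_rows, n_cols = df.shape
    if n_rows != n_cols:
        raise MatrixValidationError(
            f"{path}: matrix must be square, got {n_rows}x{n_cols}"
        )
    if rows != list(range(n_rows)) or cols != list(range(n_cols)):
        raise SchemaError(f"{path}: parcel ids must be dense 0..{n_rows - 1}")
    try:
        return validate_connectivity_matrix(
            df.to_numpy(dtype=float),
            n_parcels=parcels.n_parcels if parcels is not None else None,
            kind=kind,
        )
    except MatrixValidationError as exc:
        raise MatrixValidationError(f"{path}: {exc}") from exc


def write_subjects_table(
    subjects: list[SubjectRecord], directory: str | Path,
    matrix_dir: str = "matrices",
) -> Path:
    """Write subjects.tsv plus one matrix CSV per subject under ``matrix_dir``."""
    directory = Path(directory)
    (directory / matrix_dir).mkdir(parents=True, exist_ok=True)
    rows = []
    for sub in subjects:
        rel = Path(matrix_dir) / f"{sub.subject_id}.csv"
        write_matrix(sub.streamlines, directory / rel)
        rows.append({
            "subject_id": sub.subject_id,
            "callosal_area_mm2": sub.callosal_area,
            "sex": sub.sex,
            "age_group": sub.age_group,
            "matrix_path": str(rel),
        })
    path = directory / "subjects.tsv"
    pd.DataFrame(rows)[_SUBJECT_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_subjects(path: str | Path, parcels: ParcelTable) -> list[SubjectRecord]:
    """Read a subjects TSV and every per-subject matrix it references."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "sex": str,
                                            "age_group": str})
    missing = [c for c in _SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if df["subject_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate subject ids")
    subjects = []
    for _, row in df.iterrows():
        mat = read_matrix(path.parent / row["matrix_path"], parcels, kind="streamline")
        subjects.append(SubjectRecord(
            subject_id=row["subject_id"],
            streamlines=mat,
            callosal_area=float(row["callosal_area_mm2"]),
            sex=row["sex"],
            age_group=row["age_group"],
        ))
    return subjects


def write_histology_params(params: HistologyParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "callosal_density": float(params.callosal_density),
                "ipsilateral_density": float(params.ipsilateral_density),
                "shrinkage_corrected": bool(params.shrinkage_corrected),
            },
            fh,
        )


def read_histology_params(path: str | Path) -> HistologyParams:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: expected a flat key-value mapping")
    known = {"callosal_density", "ipsilateral_density", "shrinkage_corrected"}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"{path}: unknown key(s) {sorted(unknown)}")
    return HistologyParams(**{k: raw[k] for k in known & set(raw)})


def read_cohort(directory: str | Path):
    """Read a cohort written by :func:`axoncalib.synthetic.write_cohort`.

    Returns ``(parcels, lengths, subjects, manifest_dict)``; the manifest is
    returned as the raw JSON mapping (absent manifests yield ``None``).
    """
    import json

    directory = Path(directory)
    parcels = read_parcel_table(directory / "parcels.tsv")
    lengths = read_matrix(directory / "lengths.csv", parcels, kind="length")
    subjects = read_subjects(directory / "subjects.tsv", parcels)
    manifest = None
    mpath = directory / "manifest.json"
    if mpath.exists():
        with open(mpath) as fh:
            manifest = json.load(fh)
    return parcels, lengths, subjects, manifest
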