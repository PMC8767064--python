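"""Readers and writers for the delimited text formats the pipeline touches.

All tables are tab-delimited UTF-8 with '.' as the decimal separator.  In
feature matrices an empty cell (or a configurable sentinel such as ``NA``)
means *not detected*.  Output tables are written with a fixed float
precision and deterministic row/column order so reruns diff cleanly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    DEFAULT_STAGES,
    FeatureMatrix,
    GENOTYPES,
    PathwaySets,
    SampleRecord,
    TISSUES,
)

logger = logging.getLogger(__name__)

#: Number of significant digits used when rendering floats to text.
FLOAT_FORMAT = "%.8g"

METADATA_COLUMNS = ("sample_id", "genotype", "tissue", "stage", "replicate")


def read_feature_matrix(
    path: str | Path,
    kind: str,
    missing_sentinels: Sequence[str] = ("",),
) -> FeatureMatrix:
    """Read a features x samples TSV; sentinel cells become not-detected.

    The first column holds feature ids, the header row sample ids.  Raises
    on duplicate feature ids and on cells that are neither numeric nor a
    declared sentinel.
    """
    raw = pd.read_csv(
        path, sep="\t", dtype=str, index_col=0, keep_default_na=False
    )
    dup = raw.index[raw.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate feature id(s): {sorted(set(dup))}")
    sentinels = set(missing_sentinels)
    values = np.empty(raw.shape, dtype=float)
    arr = raw.to_numpy()
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            cell = arr[i, j].strip()
            if cell in sentinels:
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"non-numeric cell {cell!r} at feature "
                        f"{raw.index[i]!r}, sample {raw.columns[j]!r}"
                    ) from None
    frame = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    return FeatureMatrix(frame, kind)


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Inverse of :func:`read_feature_matrix`; NaN renders as an empty cell."""
    out = matrix.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, na_rep="")


def read_sample_metadata(
    path: str | Path, stages: Sequence[int] = DEFAULT_STAGES
) -> list[SampleRecord]:
    """Read the five-column sample sheet and validate every row's enums."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"metadata is missing column(s): {missing}")
    records: list[SampleRecord] = []
    stage_set = set(int(s) for s in stages)
    for idx, row in table.iterrows():
        try:
            stage = int(row["stage"])
            replicate = int(row["replicate"])
        except ValueError as exc:
            raise ValueError(f"metadata row {idx}: {exc}") from None
        if stage not in stage_set:
            raise ValueError(
                f"metadata row {idx} (sample {row['sample_id']!r}): stage "
                f"{stage} not in declared stages {sorted(stage_set)}"
            )
        try:
            rec = SampleRecord(
                sample_id=row["sample_id"],
                genotype=row["genotype"],
                tissue=row["tissue"],
                stage=stage,
                replicate=replicate,
            )
        except ValueError as exc:
            raise ValueError(f"metadata row {idx}: {exc}") from None
        records.append(rec)
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample id(s) in metadata: {dup}")
    return records


def write_sample_metadata(
    records: Sequence[SampleRecord], path: str | Path
) -> None:
    from .types import records_to_frame

    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> PathwaySets:
    """Parse GMT text: id, description, then members, all tab-separated."""
    mapping: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} field(s); "
                    "expected id, description and at least one member"
                )
            pid, name, *members = fields
            members = [m for m in members if m]
            if pid in mapping:
                raise ValueError(f"{path}: duplicate pathway id {pid!r}")
            mapping[pid] = (name, members)
    return PathwaySets.from_mapping(mapping)


def write_gmt(pathways: PathwaySets, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pw in pathways:
            fh.write("\t".join([pw.pathway_id, pw.name, *pw.members]) + "\n")


@dataclass
class DesignSummary:
    """Replicate bookkeeping produced by :func:`validate_design`."""

    cell_counts: pd.DataFrame  # genotype, tissue, stage, n_replicates
    untestable_cells: list[tuple[str, str, int]]  # cells with < 2 replicates


def validate_design(
    matrix: FeatureMatrix, records: Sequence[SampleRecord]
) -> tuple[FeatureMatrix, DesignSummary]:
    """Pair matrix columns with sample records; report replicate counts.

    Mismatches in either direction are an error; design cells with fewer
    than two replicates are flagged as untestable, not rejected.
    """
    by_id = {r.sample_id: r for r in records}
    matrix_ids = set(matrix.sample_ids)
    meta_ids = set(by_id)
    only_matrix = sorted(matrix_ids - meta_ids)
    only_meta = sorted(meta_ids - matrix_ids)
    if only_matrix or only_meta:
        raise ValueError(
            "matrix/metadata mismatch: "
            f"samples only in matrix: {only_matrix}; "
            f"samples only in metadata: {only_meta}"
        )
    ordered = [by_id[i] for i in matrix.sample_ids]
    paired = FeatureMatrix(matrix.values.copy(), matrix.kind, ordered)

    counts: dict[tuple[str, str, int], int] = {}
    for rec in ordered:
        counts[rec.cell] = counts.get(rec.cell, 0) + 1
    rows = [
        {"genotype": g, "tissue": t, "stage": s, "n_replicates": n}
        for (g, t, s), n in sorted(
            counts.items(),
            key=lambda kv: (
                GENOTYPES.index(kv[0][0]),
                TISSUES.index(kv[0][1]),
                kv[0][2],
            ),
        )
    ]
    cell_counts = pd.DataFrame(rows)
    untestable = [
        (r["genotype"], r["tissue"], r["stage"])
        for r in rows
        if r["n_replicates"] < 2
    ]
    if untestable:
        logger.warning(
            "%d design cell(s) have < 2 replicates and are untestable: %s",
            len(untestable),
            untestable,
        )
    return paired, DesignSummary(cell_counts, untestable)


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a results table deterministically.

    Rows are sorted by feature then stage when those columns exist (all
    remaining columns break ties); floats are rendered at fixed precision.
    """
    out = table.copy()
    sort_cols = [
        c for c in ("feature_id", "feature", "gene", "stage") if c in out.columns
    ]
    if sort_cols:
        out = out.sort_values(sort_cols, kind="stable")
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
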