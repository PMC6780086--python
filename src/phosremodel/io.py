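"""Readers and writers for the plain TSV exchange formats.

All tables are UTF-8, tab-separated, '.' decimal separator, one header
row.  Multi-valued fields (EC numbers, pathway ids, gene lists) are
semicolon-joined.  Floats are written with nine significant digits so a
write -> read round trip preserves values well past six significant
digits.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError, InputError
from .types import AnnotationTable, ContrastResult, ExpressionMatrix, SampleDesign

_FLOAT_FMT = "{:.9g}"


def load_design(path: str | Path) -> list[SampleDesign]:
    """Read a sample design table (sample_id, condition, replicate[, phosphate_level])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "condition", "replicate"}
    if not required.issubset(df.columns):
        raise FormatError(f"design table must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        kwargs: dict[str, Any] = dict(
            sample_id=row["sample_id"],
            condition=row["condition"],
            replicate=int(row["replicate"]),
        )
        if "phosphate_level" in df.columns and not pd.isna(row["phosphate_level"]):
            kwargs["phosphate_level"] = float(row["phosphate_level"])
        out.append(SampleDesign(**kwargs))
    return out


def load_expression_matrix(
    path: str | Path, design: Sequence[SampleDesign]
) -> ExpressionMatrix:
    """Load a gene x sample TPM table.

    First column is the gene id; remaining columns must be named by the
    ``sample_id`` fields of ``design`` (any order; the result follows
    design order).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    design_ids = [s.sample_id for s in design]
    missing = [i for i in design_ids if i not in df.columns]
    extra = [c for c in df.columns if c not in design_ids]
    if missing or extra:
        raise DesignError(
            f"matrix columns do not match design: missing {missing}, extra {extra}"
        )
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise FormatError(f"duplicate gene id(s): {dupes[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric value {df.iat[r, c]!r} at gene {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    if (numeric.to_numpy() < 0).any():
        r, c = np.argwhere(numeric.to_numpy() < 0)[0]
        raise FormatError(
            f"negative value at gene {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return ExpressionMatrix(numeric[design_ids].astype(float), list(design))


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.9g")


def load_annotation(path: str | Path) -> AnnotationTable:
    """Read a gene annotation table (gene_id, ec_numbers, pathway_ids).

    ``ec_numbers`` and ``pathway_ids`` are semicolon-joined and may be
    empty.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_id", "ec_numbers", "pathway_ids"}
    if not required.issubset(df.columns):
        raise FormatError(f"annotation table must have columns {sorted(required)}")
    if df["gene_id"].duplicated().any():
        dupes = sorted(df.loc[df["gene_id"].duplicated(), "gene_id"].unique())
        raise FormatError(f"duplicate gene_id row(s): {dupes[:5]}")
    ecs: dict[str, tuple[str, ...]] = {}
    pws: dict[str, tuple[str, ...]] = {}
    for _, row in df.iterrows():
        gene = row["gene_id"]
        ecs[gene] = _split_multi(row["ec_numbers"])
        pws[gene] = _split_multi(row["pathway_ids"])
    return AnnotationTable(ecs, pws)


def write_annotation(annotation: AnnotationTable, path: str | Path) -> None:
    rows = [
        {
            "gene_id": g,
            "ec_numbers": ";".join(annotation.ec_numbers[g]),
            "pathway_ids": ";".join(annotation.pathways[g]),
        }
        for g in annotation.genes
    ]
    pd.DataFrame(rows, columns=["gene_id", "ec_numbers", "pathway_ids"]).to_csv(
        path, sep="\t", index=False
    )


def write_design(design: Sequence[SampleDesign], path: str | Path) -> None:
    rows = [dataclasses.asdict(s) for s in design]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.9g")


def write_table(records: Sequence[Any], path: str | Path, fields: Sequence[str] | None = None) -> None:
    """Write a homogeneous list of result dataclasses as a TSV with header.

    Scalars are written as-is (floats with >= 6 significant digits);
    tuple/list fields are semicolon-joined.  An empty list with no
    ``fields`` hint produces an empty file with no way to infer a header,
    so pass ``fields`` for the empty case when the header matters.
    """
    if records:
        if len({type(r) for r in records}) != 1:
            raise InputError("write_table requires records of one type")
        if not dataclasses.is_dataclass(records[0]):
            raise InputError("write_table requires dataclass records")
        names = [f.name for f in dataclasses.fields(records[0])]
    elif fields is not None:
        names = list(fields)
    else:
        names = []
    lines = ["\t".join(names)]
    for rec in records:
        cells = []
        for name in names:
            cells.append(_format_cell(getattr(rec, name)))
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_contrast_results(path: str | Path) -> list[ContrastResult]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return [
        ContrastResult(
            gene_id=row.gene_id,
            mean_a=float(row.mean_a),
            mean_b=float(row.mean_b),
            log2fc=float(row.log2fc),
            p_value=float(row.p_value),
            fdr=float(row.fdr),
            direction=row.direction,
        )
        for row in df.itertuples(index=False)
    ]


def _split_multi(cell: str) -> tuple[str, ...]:
    cell = cell.strip()
    if not cell:
        return ()
    return tuple(part.strip() for part in cell.split(";") if part.strip())


def _format_cell(value: Any) -> str:
    if isinstance(value, float) or isinstance(value, np.floating):
        return _FLOAT_FMT.format(float(value))
    if isinstance(value, (tuple, list)):
        return ";".join(str(v) for v in value)
    if isinstance(value, np.ndarray):
        return ";".join(_FLOAT_FMT.format(float(v)) for v in value)
    return str(value)
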