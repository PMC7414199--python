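"""Readers and writers for the pipeline's delimited-text formats.

All tables are tab-separated UTF-8 with a mandatory header row and "."
decimals.  Readers reject malformed input with an error locating the
offending line or cell rather than silently coercing.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import GeneSetLibrary
from .meta_deg import ExpressionStudy
from .synthetic import REG_EDGE_COLUMNS

logger = logging.getLogger(__name__)

SEP = "\t"
FLOAT_FORMAT = "%.10g"


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    frame.to_csv(path, sep=SEP, index=index, float_format=FLOAT_FORMAT,
                 encoding="utf-8", lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=SEP, encoding="utf-8")


# ---------------------------------------------------------------------------
# expression


def read_expression(
    path: str | Path,
    annotation_path: str | Path,
) -> list[ExpressionStudy]:
    """Read one expression matrix plus its sample annotation into studies.

    The matrix is genes/probes x samples, first column the identifier.
    The annotation needs columns ``sample``, ``study_id`` and ``group``
    (``case``/``control``).  Every matrix sample must be annotated; cells
    must parse as finite numbers.  Returns one study per study_id, sample
    order preserved within each study.
    """
    matrix = pd.read_csv(path, sep=SEP, index_col=0, encoding="utf-8")
    ann = pd.read_csv(annotation_path, sep=SEP, encoding="utf-8")
    for col in ("sample", "study_id", "group"):
        if col not in ann.columns:
            raise ValueError(f"{annotation_path}: missing column {col!r}")
    ann = ann.set_index("sample")
    if ann.index.duplicated().any():
        dup = list(ann.index[ann.index.duplicated()][:5])
        raise ValueError(f"{annotation_path}: duplicated samples {dup}")

    missing = [s for s in matrix.columns if s not in ann.index]
    if missing:
        raise ValueError(
            f"{path}: samples absent from annotation: {missing[:5]}"
            f"{'...' if len(missing) > 5 else ''}")
    extra = ann.index.difference(matrix.columns)
    if len(extra):
        logger.warning("%s: %d annotated samples not in the matrix",
                       annotation_path, len(extra))

    for col in matrix.columns:
        if not np.issubdtype(matrix[col].dtype, np.number):
            converted = pd.to_numeric(matrix[col], errors="coerce")
            bad = matrix.index[converted.isna() & matrix[col].notna()]
            row = bad[0] if len(bad) else matrix.index[converted.isna()][0]
            raise ValueError(
                f"{path}: non-numeric value at row {row!r}, column {col!r}")
    if not np.isfinite(matrix.to_numpy()).all():
        r, c = np.argwhere(~np.isfinite(matrix.to_numpy()))[0]
        raise ValueError(
            f"{path}: non-finite value at row {matrix.index[r]!r}, "
            f"column {matrix.columns[c]!r}")

    studies = []
    for sid in sorted(ann.loc[matrix.columns, "study_id"].unique()):
        cols = [s for s in matrix.columns if ann.loc[s, "study_id"] == sid]
        studies.append(ExpressionStudy(
            study_id=str(sid),
            data=matrix[cols],
            groups=ann.loc[cols, "group"],
        ))
    return studies


def write_expression(
    studies: list[ExpressionStudy],
    matrix_path: str | Path,
    annotation_path: str | Path,
) -> None:
    """Write studies as one combined matrix plus a sample annotation."""
    if not studies:
        raise ValueError("no studies to write")
    genes = studies[0].genes
    for s in studies[1:]:
        if not s.genes.equals(genes):
            raise ValueError("studies have differing gene lists; cannot "
                             "share one matrix")
    matrix = pd.concat([s.data for s in studies], axis=1)
    matrix.index.name = matrix.index.name or "gene"
    write_table(matrix, matrix_path, index=True)
    ann = pd.concat([
        pd.DataFrame({"sample": s.samples, "study_id": s.study_id,
                      "group": s.groups.to_numpy()})
        for s in studies
    ])
    write_table(ann, annotation_path)


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path, library_name: str | None = None) -> GeneSetLibrary:
    """Read a GMT file: ``set_name<TAB>description<TAB>gene...`` per line.

    Duplicate genes within one set are de-duplicated; empty sets are
    dropped with a warning; lines with fewer than three fields are an
    error naming the line number.
    """
    path = Path(path)
    name = library_name or path.stem
    sets: dict[str, frozenset] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "need >= 3 (name, description, genes)")
            set_name = fields[0]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                logger.warning("%s:%d: empty set %r dropped", path, lineno,
                               set_name)
                continue
            if set_name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set {set_name!r}")
            sets[set_name] = genes
    return GeneSetLibrary(library_name=name, sets=sets)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_name in sorted(library.sets):
            genes = "\t".join(sorted(library.sets[set_name]))
            fh.write(f"{set_name}\t{library.library_name}\t{genes}\n")


# ---------------------------------------------------------------------------
# maps and edge tables


def read_probe_map(path: str | Path) -> pd.DataFrame:
    frame = read_table(path)
    for col in ("probe", "gene"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return frame


def read_ppi_table(path: str | Path) -> tuple[str, pd.DataFrame]:
    """Read a PPI edge table, auto-detecting its dialect by columns.

    Returns ``("biogrid", frame)`` when an ``evidence_count`` column is
    present, ``("hippie", frame)`` for a ``score`` column.
    """
    frame = read_table(path)
    base = {"partner_a", "partner_b"}
    if not base <= set(frame.columns):
        raise ValueError(
            f"{path}: missing columns {sorted(base - set(frame.columns))}")
    if "evidence_count" in frame.columns:
        return "biogrid", frame
    if "score" in frame.columns:
        return "hippie", frame
    raise ValueError(
        f"{path}: cannot detect PPI dialect; need an 'evidence_count' "
        "(BioGRID-like) or 'score' (HIPPIE-like) column")


def read_reg_edges(path: str | Path) -> pd.DataFrame:
    """Read a typed regulatory edge table (one ``dialect`` value per row)."""
    frame = read_table(path)
    required = {"source", "target", "edge_type", "species", "dialect"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in REG_EDGE_COLUMNS:
        if col not in frame.columns:
            frame[col] = np.nan
    return frame[REG_EDGE_COLUMNS]
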