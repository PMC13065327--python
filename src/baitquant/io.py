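"""Readers and writers for the pipeline's plain-text formats.

All tables are UTF-8, tab-delimited, with a header row and the id in the
first column, matching the wide DIA-NN report matrices
(``report.pg_matrix.tsv`` / ``report.phosphosites_99.tsv``) after column
renaming. Lines starting with ``#`` are provenance comments and are skipped
on read. Zero intensities denote non-detection in label-free MS and are
converted to missing by default (``zeros_as_missing``).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AnnotationTable,
    IntensityMatrix,
    PhosphoMatrix,
    PhosphoSiteId,
    SampleDesign,
)

logger = logging.getLogger(__name__)


def read_design(path: str | Path) -> SampleDesign:
    """Read and validate a sample-design TSV
    (sample_id/condition/replicate/tag/fraction)."""
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return SampleDesign(table)


def write_design(design: SampleDesign, path: str | Path,
                 comments: Sequence[str] = ()) -> None:
    _write_table(design.table, path, comments, index=False)


def read_intensity_matrix(
    path: str | Path,
    design: SampleDesign,
    fraction: str = "N",
    zeros_as_missing: bool = True,
) -> IntensityMatrix:
    """Read a wide protein-group matrix, restricted to the design's columns
    of the given fraction.

    File columns not in the design are ignored with a warning; design
    columns of the fraction absent from the file raise.
    """
    df = _read_wide(path, zeros_as_missing)
    wanted = design.select(fraction=fraction)
    return IntensityMatrix(_restrict(df, wanted, path), provenance="raw")


def read_phospho_matrix(
    path: str | Path,
    design: SampleDesign,
    zeros_as_missing: bool = True,
    dialect: str = "canonical",
) -> PhosphoMatrix:
    """Read a wide phospho-site matrix (PE columns). Row ids are parsed as
    phospho-site ids in the given dialect and stored in canonical form."""
    df = _read_wide(path, zeros_as_missing)
    canonical = [PhosphoSiteId.parse(rid, dialect=dialect).format() for rid in df.index]
    df.index = pd.Index(canonical, name=df.index.name)
    wanted = design.select(fraction="PE")
    return PhosphoMatrix(_restrict(df, wanted, path), provenance="raw")


def _read_wide(path: str | Path, zeros_as_missing: bool) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"{path}: duplicate row id(s): {dup}")
    df = df.astype(float)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative intensity value(s)")
    if zeros_as_missing:
        df = df.mask(df == 0.0)
    return df


def _restrict(df: pd.DataFrame, wanted: Sequence[str], path) -> pd.DataFrame:
    extra = [c for c in df.columns if c not in set(wanted)]
    if extra:
        logger.warning("%s: ignoring %d column(s) not in design: %s",
                       path, len(extra), extra)
    absent = [c for c in wanted if c not in df.columns]
    if absent:
        raise ValueError(f"{path}: design column(s) absent from file: {absent}")
    return df.loc[:, list(wanted)]


def write_matrix(matrix: IntensityMatrix, path: str | Path,
                 comments: Sequence[str] = ()) -> None:
    """Write a matrix as TSV with ``#`` provenance comments; missing cells
    are written empty so the round-trip preserves them."""
    comments = list(comments) + [f"provenance: {matrix.provenance}"]
    _write_table(matrix.data, path, comments, index=True)


def _write_table(df: pd.DataFrame, path: str | Path, comments: Sequence[str],
                 index: bool) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def write_table(df: pd.DataFrame, path: str | Path,
                comments: Sequence[str] = (), index: bool = False) -> None:
    """Write a tidy results table as commented TSV."""
    _write_table(df, path, comments, index=index)


def read_annotation(path: str | Path) -> AnnotationTable:
    """Read a protein annotation TSV (protein/subcomplex/is_kinetochore)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"protein": str})
    df["is_kinetochore"] = df["is_kinetochore"].map(_parse_bool)
    return AnnotationTable(df.set_index("protein")[["subcomplex", "is_kinetochore"]])


def write_annotation(annotation: AnnotationTable, path: str | Path,
                     comments: Sequence[str] = ()) -> None:
    _write_table(annotation.table.reset_index(), path, comments, index=False)


def _parse_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("true", "1", "yes")
    return bool(v)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences; header's first token is the protein id.
    Sequences are uppercased; duplicates and empty sequences raise."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        pid = record.id
        if pid in sequences:
            raise ValueError(f"duplicate FASTA id: {pid}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for {pid}")
        sequences[pid] = seq
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
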