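"""The three-step normalisation chain.

1. Column-median normalisation within sample groups: every value in a
   column is multiplied by ``R_g / median(column)`` where ``R_g`` is the
   group reference (the median of the per-column medians within the group),
   so after the operation every column's non-missing median equals ``R_g``.
   Tag and no-tag IPs are normalised separately, as are the N (protein) and
   PE (phospho) tables; all conditions and replicates of a group are
   normalised together.
2. Phospho-to-protein normalisation: each PE phospho-site value is divided
   by the matched N sample's value for the site's protein and multiplied by
   1000 — a per-site occupancy proxy that cancels protein-abundance changes.
3. Bait scaling: each protein value is divided by the bait's (Dsn1's) value
   in the same sample, giving a bait-relative stoichiometry proxy.

Medians are computed over non-missing values only; no imputation anywhere.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import IntensityMatrix, PhosphoMatrix, SampleDesign

logger = logging.getLogger(__name__)


def median_normalize(
    matrix: IntensityMatrix,
    groups: Mapping[str, Sequence[str]] | Iterable[Sequence[str]],
) -> IntensityMatrix:
    """Column-median normalisation within each sample group.

    ``groups`` partitions the matrix's columns (dict name → columns, or an
    iterable of column lists). Raises on an empty group, an all-missing
    column, or columns left out of / shared between groups.
    """
    if isinstance(groups, Mapping):
        named = {str(k): list(v) for k, v in groups.items()}
    else:
        named = {f"group{i}": list(v) for i, v in enumerate(groups)}

    seen: list[str] = []
    for name, cols in named.items():
        if not cols:
            raise ValueError(f"empty normalisation group: {name}")
        unknown = [c for c in cols if c not in matrix.data.columns]
        if unknown:
            raise ValueError(f"group {name}: column(s) not in matrix: {unknown}")
        seen.extend(cols)
    if len(seen) != len(set(seen)):
        raise ValueError("normalisation groups overlap")
    uncovered = [c for c in matrix.data.columns if c not in set(seen)]
    if uncovered:
        raise ValueError(f"column(s) not covered by any group: {uncovered}")

    out = matrix.data.copy()
    for name, cols in named.items():
        medians = out[cols].median(axis=0, skipna=True)
        if medians.isna().any():
            bad = medians.index[medians.isna()].tolist()
            raise ValueError(f"group {name}: all-missing column(s): {bad}")
        reference = float(medians.median())
        factors = reference / medians
        out[cols] = out[cols] * factors
    return matrix.with_data(out, provenance="median_normalized")


def normalize_phospho_to_protein(
    phospho: PhosphoMatrix,
    protein: IntensityMatrix,
    design: SampleDesign,
) -> PhosphoMatrix:
    """Divide each PE phospho-site value by the matched N sample's protein
    value and multiply by 1000.

    Output is missing wherever the site, the matched protein value, or the
    protein row itself is missing — never zero, never silently dropped.
    Raises for a PE column with no matched N sample in the design.
    """
    for m, stage in ((phospho, "phospho"), (protein, "protein")):
        if m.provenance != "median_normalized":
            logger.warning(
                "%s matrix has provenance %r; expected median_normalized",
                stage, m.provenance,
            )
    unmatched = [c for c in phospho.data.columns if c not in design.pe_to_n]
    if unmatched:
        raise ValueError(f"PE sample(s) with no matched N sample: {unmatched}")

    n_cols = [design.pe_to_n[c] for c in phospho.data.columns]
    absent = [c for c in n_cols if c not in protein.data.columns]
    if absent:
        raise ValueError(f"matched N column(s) absent from protein matrix: {absent}")

    # Protein denominators aligned to sites: rows reindexed by each site's
    # protein (absent proteins become all-NaN), columns by the matched N
    # sample of each PE column.
    denom = protein.data.reindex(index=phospho.site_proteins.to_numpy(),
                                 columns=n_cols)
    denom.index = phospho.data.index
    denom.columns = phospho.data.columns
    out = 1000.0 * phospho.data / denom
    return phospho.with_data(out, provenance="protein_normalized")


def bait_scale(
    matrix: IntensityMatrix,
    bait: str = "Dsn1",
    columns: Sequence[str] | None = None,
) -> IntensityMatrix:
    """Divide every value by the bait's value in the same sample.

    The bait must be present and non-missing in every scaled column;
    columns lacking it (e.g. no-tag IPs) must be excluded upstream —
    a missing bait raises, naming the sample. The bait row is exactly 1
    everywhere afterwards.
    """
    if bait not in matrix.data.index:
        raise ValueError(f"bait {bait!r} not in matrix")
    data = matrix.data if columns is None else matrix.subset_columns(columns).data
    bait_row = data.loc[bait]
    missing = bait_row.index[bait_row.isna()].tolist()
    if missing:
        raise ValueError(f"bait {bait!r} missing in sample(s): {missing}")
    out = data / bait_row
    return matrix.with_data(out, provenance="bait_scaled")


def columns_with_bait(matrix: IntensityMatrix, bait: str,
                      columns: Sequence[str]) -> list[str]:
    """The subset of ``columns`` in which the bait was quantified; used to
    exclude bait-dropout columns before scaling (logged)."""
    if bait not in matrix.data.index:
        raise ValueError(f"bait {bait!r} not in matrix")
    ok = [c for c in columns if pd.notna(matrix.data.at[bait, c])]
    dropped = sorted(set(columns) - set(ok))
    if dropped:
        logger.warning("excluding %d column(s) lacking bait %s: %s",
                       len(dropped), bait, dropped)
    return ok
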