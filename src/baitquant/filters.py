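"""Replicate-completeness filtering and replicate-intersection accounting.

In lieu of imputation, rows are retained only if quantified in all
replicates of at least one (condition, tag) group — the completeness
filter. Venn-style region counts over detection sets support replicate
and condition intersection summaries.
"""

from __future__ import annotations

import itertools
import logging
from typing import Collection, Iterable, Mapping, Sequence

import pandas as pd

from .model import IntensityMatrix, SampleDesign

logger = logging.getLogger(__name__)


def completeness_filter(
    matrix: IntensityMatrix,
    design: SampleDesign,
    fraction: str,
    unit: str = "condition_tag",
) -> IntensityMatrix:
    """Keep rows with a non-missing value in every replicate column of at
    least one group; row order preserved.

    ``unit`` is ``"condition_tag"`` (default) or ``"condition"``. Groups are
    intersected with the matrix's columns; an empty result is allowed and
    logged.
    """
    by = {"condition_tag": ("condition", "tag"), "condition": ("condition",)}
    if unit not in by:
        raise ValueError(f"unknown completeness unit: {unit!r}")
    groups = design.replicate_groups(fraction, by=by[unit])
    present = matrix.data.notna()
    keep = pd.Series(False, index=matrix.data.index)
    for key, cols in groups.items():
        cols = [c for c in cols if c in matrix.data.columns]
        if not cols:
            continue
        keep |= present[cols].all(axis=1)
    out = matrix.data.loc[keep]
    logger.info("completeness filter (%s): %d of %d rows kept",
                unit, len(out), len(matrix.data))
    if out.empty:
        logger.warning("completeness filter left no rows")
    return matrix.with_data(out)


def exclude_samples(design: SampleDesign, exclusions: Iterable[str]) -> SampleDesign:
    """Remove listed samples from the design (e.g. low-coverage replicates);
    downstream group sizes shrink accordingly."""
    return design.exclude(exclusions)


def detection_sets(
    matrix: IntensityMatrix, columns_by_set: Mapping[str, Sequence[str]]
) -> dict[str, set[str]]:
    """Row-id detection set per named column group: a row is detected in a
    set if non-missing in every listed column (a single column gives
    per-replicate detection)."""
    out: dict[str, set[str]] = {}
    present = matrix.data.notna()
    for name, cols in columns_by_set.items():
        cols = list(cols)
        missing = [c for c in cols if c not in matrix.data.columns]
        if missing:
            raise ValueError(f"set {name!r}: column(s) not in matrix: {missing}")
        mask = present[cols].all(axis=1)
        out[name] = set(matrix.data.index[mask])
    return out


def venn_counts(sets: Mapping[str, Collection[str]]) -> pd.DataFrame:
    """Exclusive-region counts for a Venn diagram over >=2 named sets.

    Each element of the union is assigned to exactly one region (the set of
    names containing it), so region counts sum to the union size. Returns a
    tidy table with columns ``members`` ("A&B"), ``degree`` and ``count``,
    including empty regions.
    """
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need at least 2 sets")
    membership: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            membership[frozenset(combo)] = 0
    for element in set().union(*[set(s) for s in sets.values()]):
        region = frozenset(n for n in names if element in set(sets[n]))
        membership[region] += 1
    rows = [
        {
            "members": "&".join(n for n in names if n in region),
            "degree": len(region),
            "count": count,
        }
        for region, count in membership.items()
    ]
    df = pd.DataFrame(rows).sort_values(["degree", "members"]).reset_index(drop=True)
    return df


def replicate_intersections(
    matrix: IntensityMatrix,
    design: SampleDesign,
    fraction: str,
    by: str = "replicate",
    tag: str = "tag",
) -> dict[tuple, pd.DataFrame]:
    """Venn region counts of detected rows.

    ``by="replicate"``: within each (condition, tag) group of the given
    fraction, one set per replicate column. ``by="condition"``: at the given
    tag, one set per condition, a row counting as detected in a condition if
    non-missing in all of its replicate columns.
    """
    out: dict[tuple, pd.DataFrame] = {}
    if by == "replicate":
        for key, cols in design.replicate_groups(fraction).items():
            cols = [c for c in cols if c in matrix.data.columns]
            if len(cols) < 2:
                continue
            sets = detection_sets(
                matrix, {f"rep{design.factor(c, 'replicate')}": [c] for c in cols}
            )
            out[key] = venn_counts(sets)
    elif by == "condition":
        groups = {
            key[0]: [c for c in cols if c in matrix.data.columns]
            for key, cols in design.replicate_groups(fraction).items()
            if key[1] == tag
        }
        groups = {k: v for k, v in groups.items() if v}
        if len(groups) >= 2:
            out[(tag,)] = venn_counts(detection_sets(matrix, groups))
    else:
        raise ValueError(f"unknown intersection mode: {by!r}")
    return out
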