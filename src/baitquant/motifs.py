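"""Kinase consensus-motif analysis of phospho-site sequence context.

Each phospho-site is represented by a +/-k window of the protein sequence
centred on the acceptor residue ('_' pads beyond the termini). A motif is
a map from relative position to an allowed residue set (position 0, the
acceptor, defaults to {S, T}); a window matches iff every constrained
position's residue is allowed, and a pad character never matches. On top
of the matcher sit per-stratum match fractions (stage, sub-complex),
position-probability matrices for sequence logos, and per-condition
abundance tables of matching sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .groupstats import condition_means
from .model import (
    AMINO_ACIDS,
    AnnotationTable,
    PhosphoMatrix,
    PhosphoSiteId,
    SampleDesign,
)

logger = logging.getLogger(__name__)

PAD = "_"


@dataclass(frozen=True)
class SequenceWindow:
    """A 2k+1 window of protein sequence centred on a phospho-site."""

    site: PhosphoSiteId
    window: str
    k: int

    def __post_init__(self):
        if len(self.window) != 2 * self.k + 1:
            raise ValueError("window length must be 2k+1")
        if self.window[self.k] != self.site.residue:
            raise ValueError("window centre does not match site residue")

    def residue_at(self, offset: int) -> str:
        return self.window[self.k + offset]


@dataclass(frozen=True)
class MotifPattern:
    """Position-specific residue-class constraints; position 0 defaults to
    the phospho-acceptors {S, T} when not given explicitly."""

    name: str
    constraints: Mapping[int, frozenset]

    def __post_init__(self):
        constraints = {int(p): frozenset(r) for p, r in self.constraints.items()}
        if 0 not in constraints:
            constraints[0] = frozenset("ST")
        for pos, residues in constraints.items():
            if not residues:
                raise ValueError(f"motif {self.name}: empty residue set at {pos:+d}")
            bad = residues - set(AMINO_ACIDS)
            if bad:
                raise ValueError(
                    f"motif {self.name}: non-canonical residue(s) {sorted(bad)}"
                )
        object.__setattr__(self, "constraints", constraints)

    def describe(self) -> str:
        parts = [
            f"{pos:+d}:[{''.join(sorted(res))}]"
            for pos, res in sorted(self.constraints.items())
        ]
        return " ".join(parts)


def extract_window(
    site: PhosphoSiteId, sequences: Mapping[str, str], k: int = 6
) -> SequenceWindow:
    """The +/-k sequence window around a site, '_'-padded at termini.

    Raises if the protein is absent or the FASTA residue at the site's
    position differs from the site id (a stale-annotation signal).
    """
    seq = sequences.get(site.protein)
    if seq is None:
        raise KeyError(f"protein {site.protein!r} not in sequences")
    if site.position > len(seq):
        raise ValueError(f"site {site.format()} beyond sequence end ({len(seq)})")
    actual = seq[site.position - 1]
    if actual != site.residue:
        raise ValueError(
            f"site {site.format()}: FASTA has {actual!r} at position {site.position}"
        )
    start = site.position - 1 - k
    end = site.position + k
    left_pad = max(0, -start)
    right_pad = max(0, end - len(seq))
    window = PAD * left_pad + seq[max(0, start):min(end, len(seq))] + PAD * right_pad
    return SequenceWindow(site=site, window=window, k=k)


def extract_windows(
    sites: Iterable[PhosphoSiteId], sequences: Mapping[str, str], k: int = 6
) -> list[SequenceWindow]:
    return [extract_window(s, sequences, k=k) for s in sites]


def match_motif(window: SequenceWindow, pattern: MotifPattern) -> bool:
    """True iff every constrained position's residue is in its allowed set;
    terminal padding matches nothing."""
    for pos, allowed in pattern.constraints.items():
        if abs(pos) > window.k:
            raise ValueError(
                f"motif {pattern.name}: position {pos:+d} outside +/-{window.k} window"
            )
        if window.residue_at(pos) not in allowed:
            return False
    return True


def load_motif_config(path: str | Path | None = None) -> list[MotifPattern]:
    """Load motif definitions from a YAML config (name -> {position:
    residue string}); the packaged default set when ``path`` is None."""
    if path is None:
        text = resources.files("baitquant.data").joinpath("motifs.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError("motif config must map motif names to constraint maps")
    patterns = []
    for name, constraints in raw.items():
        patterns.append(
            MotifPattern(
                name=str(name),
                constraints={int(p): frozenset(str(r)) for p, r in (constraints or {}).items()},
            )
        )
    return patterns


def motif_fractions(
    windows: Sequence[SequenceWindow],
    patterns: Sequence[MotifPattern],
    strata: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Percent of sites matching each motif, overall or per stratum.

    ``strata`` maps canonical site id -> stratum labels the site belongs to
    (e.g. the conditions it was detected in, or its sub-complex); a site
    can count in several strata. Returns a tidy table (pattern, stratum,
    n_sites, n_match, percent, definition); an empty stratum reports NaN.
    """
    if strata is None:
        strata = {w.site.format(): ("all",) for w in windows}
    labels = sorted({lab for labs in strata.values() for lab in labs})
    rows = []
    for pattern in patterns:
        matches = {w.site.format(): match_motif(w, pattern) for w in windows}
        for label in labels:
            in_stratum = [
                sid for sid, labs in strata.items()
                if label in labs and sid in matches
            ]
            n = len(in_stratum)
            n_match = sum(matches[sid] for sid in in_stratum)
            rows.append(
                {
                    "pattern": pattern.name,
                    "stratum": label,
                    "n_sites": n,
                    "n_match": n_match,
                    "percent": 100.0 * n_match / n if n else np.nan,
                    "definition": pattern.describe(),
                }
            )
    return pd.DataFrame(rows)


def site_condition_strata(
    phospho: PhosphoMatrix, design: SampleDesign, tag: str = "tag"
) -> dict[str, set]:
    """Site -> set of conditions in which it passes the completeness filter
    (non-missing in all replicates of that (condition, tag) group)."""
    strata: dict[str, set] = {sid: set() for sid in phospho.data.index}
    for key, cols in design.replicate_groups("PE").items():
        condition, key_tag = key
        if key_tag != tag:
            continue
        cols = [c for c in cols if c in phospho.data.columns]
        if not cols:
            continue
        complete = phospho.data[cols].notna().all(axis=1)
        for sid in phospho.data.index[complete]:
            strata[sid].add(condition)
    return strata


def position_probability_matrix(
    windows: Sequence[SequenceWindow], k: int | None = None
) -> pd.DataFrame:
    """Residue frequencies per window position (rows -k..k, columns the 20
    amino acids), computed over non-pad characters; every position with at
    least one residue sums to 1, all-pad positions are all-zero."""
    if not windows:
        raise ValueError("need at least one window")
    if k is None:
        k = windows[0].k
    if any(w.k != k for w in windows):
        raise ValueError("windows have mixed half-widths")
    positions = range(-k, k + 1)
    counts = pd.DataFrame(0.0, index=list(positions), columns=list(AMINO_ACIDS))
    for w in windows:
        for pos in positions:
            ch = w.residue_at(pos)
            if ch != PAD:
                counts.at[pos, ch] += 1.0
    totals = counts.sum(axis=1)
    empty = totals == 0
    if empty.any():
        logger.warning("all-pad position(s) in PPM: %s",
                       counts.index[empty].tolist())
    ppm = counts.div(totals.where(~empty, 1.0), axis=0)
    ppm.index.name = "position"
    return ppm


def motif_site_heatmap_table(
    phospho: PhosphoMatrix,
    windows: Sequence[SequenceWindow],
    pattern: MotifPattern,
    annotation: AnnotationTable,
    design: SampleDesign,
    tag: str = "tag",
) -> pd.DataFrame:
    """Per-condition mean abundance of kinetochore phospho-sites matching a
    motif, ordered by sub-complex (then site id)."""
    matching = {
        w.site.format() for w in windows
        if match_motif(w, pattern) and annotation.is_kinetochore(w.site.protein)
    }
    keep = [sid for sid in phospho.data.index if sid in matching]
    if not keep:
        logger.warning("no kinetochore sites match motif %s", pattern.name)
        return pd.DataFrame()
    sub = phospho.with_data(phospho.data.loc[keep])
    table = condition_means(sub, design, "PE", tag=tag)
    table.insert(0, "subcomplex",
                 [annotation.subcomplex(p) for p in sub.site_proteins])
    order = {name: i for i, name in enumerate(
        ("CCAN", "KMN", "Dam1c", "Cbf3", "MAPs", "SAC", "CPC", "accessory", "other"))}
    table = table.sort_values(
        by=["subcomplex"], key=lambda s: s.map(order), kind="stable"
    )
    table.index.name = "site"
    return table
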