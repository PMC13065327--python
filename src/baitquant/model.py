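"""Shared data model for bait-anchored IP-MS experiments.

An experiment consists of immunoprecipitations from strains carrying a
tagged bait protein (``tag``) or the untagged control (``no_tag``), across
cell-cycle conditions and replicates. Each IP yields two mass-spec samples:
the non-phospho-enriched fraction (``N``, total peptides, quantified at the
protein level) and the phospho-enriched fraction (``PE``, quantified at the
phospho-site level). ``SampleDesign`` maps sample ids to these factors and
drives every grouping downstream; ``IntensityMatrix``/``PhosphoMatrix`` hold
the wide per-sample intensity tables with ``NaN`` for missing (undetected)
values; ``AnnotationTable`` maps proteins to kinetochore sub-complexes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The study's four cell-cycle conditions; the design accepts any label,
#: these are the defaults the simulator and documentation use.
DEFAULT_CONDITIONS = ("mitotic_metaphase", "prophase", "metaphase_I", "metaphase_II")

TAGS = ("tag", "no_tag")
FRACTIONS = ("N", "PE")

PHOSPHO_RESIDUES = frozenset("STY")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

SUBCOMPLEXES = (
    "CCAN", "KMN", "Dam1c", "Cbf3", "MAPs", "SAC", "CPC", "accessory", "other",
)

# Site-id dialects: canonical dash form ("Ndc80-T-54") and a DIA-NN-style
# underscore form ("Ndc80_T54"). The protein part is matched greedily so
# protein names may themselves contain separators.
_SITE_RE = {
    "canonical": re.compile(r"^(?P<protein>.+)-(?P<residue>[A-Z])-(?P<position>\d+)$"),
    "underscore": re.compile(r"^(?P<protein>.+)_(?P<residue>[A-Z])(?P<position>\d+)$"),
}


class PhosphoSiteId(NamedTuple):
    """A phospho-site: protein, acceptor residue and 1-based position.

    Canonical string form is ``"Protein-Residue-Position"``, e.g.
    ``"Ndc80-T-54"``; :meth:`parse` and :meth:`format` round-trip.
    """

    protein: str
    residue: str
    position: int

    def format(self) -> str:
        return f"{self.protein}-{self.residue}-{self.position}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()

    @classmethod
    def parse(cls, text: str, dialect: str = "canonical") -> "PhosphoSiteId":
        """Parse a site id string in the given dialect.

        Raises ``ValueError`` for unparseable ids or a residue outside the
        phospho-acceptor set {S, T, Y}.
        """
        if dialect == "auto":
            for d in ("canonical", "underscore"):
                try:
                    return cls.parse(text, dialect=d)
                except ValueError:
                    continue
            raise ValueError(f"unparseable phospho-site id: {text!r}")
        try:
            pattern = _SITE_RE[dialect]
        except KeyError:
            raise ValueError(f"unknown site-id dialect: {dialect!r}") from None
        m = pattern.match(text)
        if m is None:
            raise ValueError(f"unparseable phospho-site id: {text!r}")
        residue = m.group("residue")
        if residue not in PHOSPHO_RESIDUES:
            raise ValueError(
                f"site {text!r}: residue {residue!r} is not a phospho-acceptor (S/T/Y)"
            )
        position = int(m.group("position"))
        if position < 1:
            raise ValueError(f"site {text!r}: position must be >= 1")
        return cls(m.group("protein"), residue, position)


class SampleDesign:
    """Validated sample-to-factor mapping.

    Wraps a DataFrame with columns ``sample_id``, ``condition``,
    ``replicate``, ``tag`` and ``fraction``. Invariants enforced on
    construction: unique sample ids, unique factor combinations, valid
    enum values, and (unless ``require_pe_partner=False``) every PE sample
    having a matched N sample sharing (condition, replicate, tag).
    """

    COLUMNS = ("sample_id", "condition", "replicate", "tag", "fraction")

    def __init__(self, table: pd.DataFrame, require_pe_partner: bool = True):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"design is missing columns: {missing}")
        table = table.loc[:, list(self.COLUMNS)].copy()
        table["sample_id"] = table["sample_id"].astype(str)
        table["condition"] = table["condition"].astype(str)
        table["replicate"] = table["replicate"].astype(int)
        table["tag"] = table["tag"].astype(str)
        table["fraction"] = table["fraction"].astype(str)

        dup = table["sample_id"][table["sample_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample_id: {sorted(set(dup))}")
        if (table["replicate"] < 1).any():
            raise ValueError("replicate must be a positive integer")
        bad_tag = set(table["tag"]) - set(TAGS)
        if bad_tag:
            raise ValueError(f"unknown tag value(s): {sorted(bad_tag)}")
        bad_frac = set(table["fraction"]) - set(FRACTIONS)
        if bad_frac:
            raise ValueError(f"unknown fraction value(s): {sorted(bad_frac)}")
        combo = table[["condition", "replicate", "tag", "fraction"]]
        if combo.duplicated().any():
            dup_rows = table.loc[combo.duplicated(), "sample_id"].tolist()
            raise ValueError(
                f"duplicate (condition, replicate, tag, fraction) for: {dup_rows}"
            )

        self.table = table.reset_index(drop=True)
        self._by_id = self.table.set_index("sample_id")

        n_keys = {
            (r.condition, r.replicate, r.tag): r.sample_id
            for r in self.table.itertuples()
            if r.fraction == "N"
        }
        pe_to_n: dict[str, str] = {}
        orphans: list[str] = []
        for r in self.table.itertuples():
            if r.fraction != "PE":
                continue
            partner = n_keys.get((r.condition, r.replicate, r.tag))
            if partner is None:
                orphans.append(r.sample_id)
            else:
                pe_to_n[r.sample_id] = partner
        if orphans:
            if require_pe_partner:
                raise ValueError(f"unmatched PE sample(s): {orphans}")
            logger.warning("PE sample(s) without a matched N sample: %s", orphans)
        self.pe_to_n: dict[str, str] = pe_to_n

    # -- queries ---------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def conditions(self) -> list[str]:
        """Conditions in first-appearance order."""
        return list(dict.fromkeys(self.table["condition"]))

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id.index

    def select(
        self,
        condition: str | None = None,
        replicate: int | None = None,
        tag: str | None = None,
        fraction: str | None = None,
    ) -> list[str]:
        """Sample ids matching all given factor levels (None = any)."""
        mask = pd.Series(True, index=self.table.index)
        for col, val in (
            ("condition", condition),
            ("replicate", replicate),
            ("tag", tag),
            ("fraction", fraction),
        ):
            if val is not None:
                mask &= self.table[col] == val
        return self.table.loc[mask, "sample_id"].tolist()

    def normalization_groups(self, fraction: str | None = None) -> dict[str, list[str]]:
        """Default median-normalisation groups: tag and no-tag IPs separately,
        N and PE tables separately; all conditions/replicates of a group
        together. Keys look like ``"tag:N"``."""
        groups: dict[str, list[str]] = {}
        for tag in TAGS:
            for frac in FRACTIONS:
                if fraction is not None and frac != fraction:
                    continue
                ids = self.select(tag=tag, fraction=frac)
                if ids:
                    groups[f"{tag}:{frac}"] = ids
        return groups

    def replicate_groups(
        self, fraction: str, by: Sequence[str] = ("condition", "tag")
    ) -> dict[tuple, list[str]]:
        """Replicate column groups of one fraction keyed by the given factors
        (default (condition, tag) — the completeness-filter unit)."""
        sub = self.table[self.table["fraction"] == fraction]
        out: dict[tuple, list[str]] = {}
        for key, grp in sub.groupby(list(by), sort=False):
            if not isinstance(key, tuple):
                key = (key,)
            out[key] = grp["sample_id"].tolist()
        return out

    def factor(self, sample_id: str, name: str):
        return self._by_id.at[sample_id, name]

    # -- transforms ------------------------------------------------------

    def exclude(self, sample_ids: Iterable[str]) -> "SampleDesign":
        """Design without the given samples (e.g. low-coverage replicates).

        Unknown ids raise; emptying a (condition, tag, fraction) group or
        orphaning a PE sample logs a warning but is allowed — downstream
        group sizes simply shrink.
        """
        sample_ids = list(sample_ids)
        unknown = [s for s in sample_ids if s not in self]
        if unknown:
            raise ValueError(f"unknown sample_id(s) in exclusion list: {unknown}")
        keep = self.table[~self.table["sample_id"].isin(sample_ids)]
        before = {
            k for k, v in self.replicate_groups("N").items()
        } | {k for k in self.replicate_groups("PE")}
        new = SampleDesign(keep, require_pe_partner=False)
        after = set(new.replicate_groups("N")) | set(new.replicate_groups("PE"))
        emptied = before - after
        if emptied:
            logger.warning("exclusion emptied group(s): %s", sorted(emptied))
        return new


class IntensityMatrix:
    """Wide protein-level intensity table: rows proteins, columns samples,
    ``NaN`` for missing. ``provenance`` records the processing stage
    (``raw`` → ``median_normalized`` → ``bait_scaled``)."""

    def __init__(self, data: pd.DataFrame, provenance: str = "raw",
                 log_scale: bool = False):
        data = data.astype(float)
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()].tolist()
            raise ValueError(f"duplicate row id(s): {sorted(set(map(str, dup)))}")
        if data.columns.has_duplicates:
            raise ValueError("duplicate sample column(s)")
        vals = data.to_numpy()
        finite = np.isfinite(vals) | np.isnan(vals)
        if not finite.all():
            raise ValueError("non-finite intensity value(s)")
        if not log_scale and np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("negative intensity value(s)")
        self.data = data
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.provenance = provenance
        self.log_scale = log_scale
        self._validate_rows()

    def _validate_rows(self) -> None:  # overridden by PhosphoMatrix
        pass

    @property
    def row_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def with_data(self, data: pd.DataFrame, provenance: str | None = None,
                  log_scale: bool | None = None):
        """New matrix of the same kind with replaced values."""
        return type(self)(
            data,
            provenance or self.provenance,
            self.log_scale if log_scale is None else log_scale,
        )

    def subset_columns(self, sample_ids: Sequence[str]):
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValueError(f"sample column(s) not in matrix: {missing}")
        return self.with_data(self.data.loc[:, list(sample_ids)])


class PhosphoMatrix(IntensityMatrix):
    """Per-phospho-site intensity table (PE fraction). Row ids are canonical
    ``"Protein-Residue-Position"`` strings; parsed ids are exposed via
    :attr:`sites` and :attr:`site_proteins`."""

    def _validate_rows(self) -> None:
        self.sites: list[PhosphoSiteId] = [
            PhosphoSiteId.parse(rid) for rid in self.data.index
        ]
        self.site_proteins = pd.Series(
            [s.protein for s in self.sites], index=self.data.index, name="protein"
        )


@dataclass
class AnnotationTable:
    """Protein → (sub-complex, is_kinetochore). Unannotated proteins default
    to (``other``, False)."""

    table: pd.DataFrame  # index protein; columns subcomplex, is_kinetochore

    def __post_init__(self):
        t = self.table
        if t.index.has_duplicates:
            raise ValueError("duplicate protein in annotation table")
        bad = set(t["subcomplex"]) - set(SUBCOMPLEXES)
        if bad:
            raise ValueError(f"unknown subcomplex value(s): {sorted(bad)}")
        self.table = t.assign(is_kinetochore=t["is_kinetochore"].astype(bool))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, tuple[str, bool]]) -> "AnnotationTable":
        df = pd.DataFrame(
            {
                "subcomplex": {p: v[0] for p, v in mapping.items()},
                "is_kinetochore": {p: v[1] for p, v in mapping.items()},
            }
        )
        df.index.name = "protein"
        return cls(df)

    def subcomplex(self, protein: str) -> str:
        if protein in self.table.index:
            return self.table.at[protein, "subcomplex"]
        return "other"

    def is_kinetochore(self, protein: str) -> bool:
        if protein in self.table.index:
            return bool(self.table.at[protein, "is_kinetochore"])
        return False

    @property
    def kinetochore_proteins(self) -> list[str]:
        return self.table.index[self.table["is_kinetochore"]].tolist()
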