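"""Synthetic IP-MS experiment generator with known ground truth.

Emulates the study design — four cell-cycle conditions x three replicates
x {tag, no-tag} IPs x {N, PE} fractions — so every pipeline stage can be
tested end-to-end without raw data. The generative model:

* tag N intensity(p, sample) = bait_level * stoichiometry(p, condition)
  * sample_scale * log-normal noise, with the bait at stoichiometry 1;
* no-tag samples contain the background proteins (condition-independent
  log-normal abundances shared with tag samples) plus a small configurable
  carryover of true complex members;
* PE intensity(site, sample) = the matched protein's expected abundance
  * occupancy(site, condition) * enrichment efficiency * sample_scale
  * noise;
* cells are dropped by an intensity-dependent (MNAR) logistic model in
  log10 abundance, with the midpoint at a low abundance percentile, so
  dropout concentrates in faint signals as in real label-free MS;
* random protein sequences are generated with each site's residue placed
  at its annotated position.

The same seed yields byte-identical output files. ``SimulationTruth``
carries the stoichiometry and occupancy maps, sample scale factors and
per-cell missing indicators, sufficient to recompute every expected
intensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import spearmanr

from . import io as bq_io
from .model import (
    AMINO_ACIDS,
    DEFAULT_CONDITIONS,
    AnnotationTable,
    IntensityMatrix,
    PhosphoMatrix,
    SampleDesign,
)
from .normalize import (
    bait_scale,
    columns_with_bait,
    median_normalize,
    normalize_phospho_to_protein,
)
from .groupstats import condition_means

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults emulate the study conditions.

    ``n_proteins`` counts complex members including the bait;
    ``noise_cv`` is the log-normal measurement CV; ``sample_scale_sd`` is
    the per-sample scale distortion SD on the log2 scale;
    ``mnar_midpoint_percentile``/``mnar_slope`` parameterise the logistic
    dropout in log10 intensity; ``null=True`` removes every condition
    effect (shared stoichiometries and occupancies) for error-control
    studies.
    """

    n_proteins: int = 60
    n_background: int = 40
    conditions: Sequence[str] = DEFAULT_CONDITIONS
    n_replicates: int = 3
    bait: str = "Dsn1"
    bait_level: float = 1e8
    sites_per_protein_mean: float = 2.0
    noise_cv: float = 0.20
    sample_scale_sd: float = 0.5
    mnar_midpoint_percentile: float = 15.0
    mnar_slope: float = 2.0
    mnar_enabled: bool = True
    pe_efficiency: float = 5.0
    carryover: float = 0.01
    condition_effect_fraction: float = 0.3
    condition_effect_sd: float = 1.0
    occupancy_effect_fraction: float = 0.3
    occupancy_effect_sd: float = 1.0
    background_median: float = 2e6
    background_sd_log2: float = 1.5
    null: bool = False
    seed: int = 0
    #: optional explicit truth: protein -> {condition: bait-relative level}
    #: and canonical site id -> {condition: occupancy}; random draws are
    #: still consumed so overriding does not shift the rng stream.
    stoichiometry_override: Mapping | None = None
    occupancy_override: Mapping | None = None

    def __post_init__(self):
        if self.n_proteins < 2:
            raise ValueError("need at least the bait plus one member")
        if self.n_background < 0 or self.n_replicates < 1:
            raise ValueError("invalid design sizes")
        if not (0 <= self.noise_cv and 0 <= self.sample_scale_sd):
            raise ValueError("noise parameters must be nonnegative")
        if not 0 < self.mnar_midpoint_percentile < 100:
            raise ValueError("mnar_midpoint_percentile must be in (0, 100)")
        if self.sites_per_protein_mean < 0 or self.pe_efficiency <= 0:
            raise ValueError("invalid phospho parameters")
        if not 0 <= self.carryover:
            raise ValueError("carryover must be nonnegative")


@dataclass
class SimulationTruth:
    stoichiometry: pd.DataFrame      # member protein x condition (bait == 1)
    background_levels: pd.Series     # background protein -> abundance
    occupancy: pd.DataFrame          # site x condition, in [0, 1]
    sample_scales: pd.Series         # sample -> multiplicative scale
    missing_protein: pd.DataFrame    # bool, protein x sample
    missing_phospho: pd.DataFrame    # bool, site x sample


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    design: SampleDesign
    protein: IntensityMatrix
    phospho: PhosphoMatrix
    annotation: AnnotationTable
    sequences: dict
    truth: SimulationTruth


def _sample_id(condition: str, tag: str, fraction: str, rep: int) -> str:
    return f"{condition}.{tag}.{fraction}.r{rep}"


def simulate_experiment(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SimulatedExperiment:
    """Generate one synthetic experiment; optionally write its files.

    Written files: ``design.tsv``, ``protein_matrix.tsv``,
    ``phospho_matrix.tsv``, ``annotation.tsv``, ``proteins.fasta`` and the
    truth tables (``truth_*.tsv``). Identical configs (same seed) produce
    byte-identical files.
    """
    rng = np.random.default_rng(config.seed)
    conditions = list(config.conditions)

    members = [config.bait] + [f"Ktp{i:02d}" for i in range(2, config.n_proteins + 1)]
    background = [f"Bgp{i:02d}" for i in range(1, config.n_background + 1)]
    proteins = members + background

    # --- design -------------------------------------------------------
    rows = []
    for cond in conditions:
        for tag in ("tag", "no_tag"):
            for frac in ("N", "PE"):
                for rep in range(1, config.n_replicates + 1):
                    rows.append(
                        {
                            "sample_id": _sample_id(cond, tag, frac, rep),
                            "condition": cond,
                            "replicate": rep,
                            "tag": tag,
                            "fraction": frac,
                        }
                    )
    design = SampleDesign(pd.DataFrame(rows))

    # --- ground truth -------------------------------------------------
    stoich = _draw_stoichiometry(rng, members, conditions, config)
    bg_levels = pd.Series(
        2.0 ** rng.normal(np.log2(config.background_median),
                          config.background_sd_log2, len(background)),
        index=background, name="abundance",
    )
    scales = pd.Series(
        2.0 ** rng.normal(0.0, config.sample_scale_sd, len(design)),
        index=design.sample_ids, name="scale",
    )

    sites, sequences = _draw_sites_and_sequences(rng, proteins, config)
    occupancy = _draw_occupancy(rng, sites, conditions, config)

    # --- expected protein abundances (before scale/noise) -------------
    n_samples = design.select(fraction="N")
    expected_n = pd.DataFrame(0.0, index=proteins, columns=n_samples)
    for col in n_samples:
        cond = design.factor(col, "condition")
        tag = design.factor(col, "tag")
        level = config.bait_level * stoich[cond]
        if tag == "no_tag":
            level = level * config.carryover
        expected_n.loc[members, col] = level.to_numpy()
        expected_n.loc[background, col] = bg_levels.to_numpy()

    sigma = np.sqrt(np.log1p(config.noise_cv**2))

    protein_obs = expected_n * scales[n_samples]
    protein_obs = protein_obs * np.exp(rng.normal(0.0, sigma, protein_obs.shape))

    # --- expected phospho abundances ----------------------------------
    pe_samples = design.select(fraction="PE")
    site_ids = [s.format() for s in sites]
    if sites:
        site_protein = [s.protein for s in sites]
        phospho_obs = pd.DataFrame(0.0, index=site_ids, columns=pe_samples)
        for col in pe_samples:
            n_partner_expected = expected_n[
                _sample_id(design.factor(col, "condition"),
                           design.factor(col, "tag"), "N",
                           int(design.factor(col, "replicate")))
            ]
            cond = design.factor(col, "condition")
            phospho_obs[col] = (
                n_partner_expected.loc[site_protein].to_numpy()
                * occupancy[cond].to_numpy()
                * config.pe_efficiency
            )
        phospho_obs = phospho_obs * scales[pe_samples]
        phospho_obs = phospho_obs * np.exp(
            rng.normal(0.0, sigma, phospho_obs.shape)
        )
    else:
        phospho_obs = pd.DataFrame(
            np.empty((0, len(pe_samples))), index=site_ids, columns=pe_samples
        )

    # --- MNAR dropout -------------------------------------------------
    miss_p = _mnar_mask(rng, protein_obs, config)
    miss_s = _mnar_mask(rng, phospho_obs, config)
    protein_data = protein_obs.mask(miss_p)
    phospho_data = phospho_obs.mask(miss_s)

    annotation = _annotate(members, background, config.bait)
    truth = SimulationTruth(
        stoichiometry=stoich,
        background_levels=bg_levels,
        occupancy=occupancy,
        sample_scales=scales,
        missing_protein=miss_p,
        missing_phospho=miss_s,
    )
    sim = SimulatedExperiment(
        config=config,
        design=design,
        protein=IntensityMatrix(protein_data, provenance="raw"),
        phospho=PhosphoMatrix(phospho_data, provenance="raw"),
        annotation=annotation,
        sequences=sequences,
        truth=truth,
    )
    if out_dir is not None:
        write_simulation(sim, out_dir)
    return sim


def _draw_stoichiometry(rng, members, conditions, config) -> pd.DataFrame:
    n = len(members)
    base = 10.0 ** rng.uniform(-1.7, 0.3, n)
    base[0] = 1.0  # bait
    varying = rng.random(n) < config.condition_effect_fraction
    varying[0] = False
    effects = rng.normal(0.0, config.condition_effect_sd, (n, len(conditions)))
    if config.null:
        effects[:] = 0.0
    effects[~varying] = 0.0
    table = pd.DataFrame(
        base[:, None] * 2.0**effects, index=members, columns=conditions
    )
    table.loc[members[0]] = 1.0
    if config.stoichiometry_override is not None:
        for protein, levels in config.stoichiometry_override.items():
            if protein not in table.index:
                raise ValueError(f"override for unknown protein {protein!r}")
            for cond, value in levels.items():
                table.at[protein, cond] = float(value)
        if not (table.loc[members[0]] == 1.0).all():
            raise ValueError("bait stoichiometry must stay 1")
    if (table.to_numpy() <= 0).any():
        raise ValueError("stoichiometries must be > 0")
    table.index.name = "protein"
    return table


def _draw_sites_and_sequences(rng, proteins, config):
    sites = []
    sequences: dict[str, str] = {}
    if config.sites_per_protein_mean == 0:
        # phospho layer disabled: no sites, no sequences
        return sites, sequences
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
    residues = np.array(["S", "T", "Y"])
    from .model import PhosphoSiteId

    for protein in proteins:
        length = int(rng.integers(200, 601))
        seq = aa[rng.integers(0, len(aa), length)]
        n_sites = int(rng.poisson(config.sites_per_protein_mean))
        n_sites = min(n_sites, length)
        positions = np.sort(rng.choice(length, size=n_sites, replace=False)) + 1
        for pos in positions:
            res = residues[rng.choice(3, p=[0.6, 0.3, 0.1])]
            seq[pos - 1] = res
            sites.append(PhosphoSiteId(protein, str(res), int(pos)))
        sequences[protein] = "".join(seq)
    return sites, sequences


def _draw_occupancy(rng, sites, conditions, config) -> pd.DataFrame:
    n = len(sites)
    base = rng.uniform(0.05, 0.9, n)
    varying = rng.random(n) < config.occupancy_effect_fraction
    effects = rng.normal(0.0, config.occupancy_effect_sd, (n, len(conditions)))
    if config.null:
        effects[:] = 0.0
    effects[~varying] = 0.0
    occ = np.clip(base[:, None] * 2.0**effects, 0.01, 1.0)
    table = pd.DataFrame(occ, index=[s.format() for s in sites], columns=conditions)
    if config.occupancy_override is not None:
        for site_id, levels in config.occupancy_override.items():
            if site_id not in table.index:
                raise ValueError(f"override for unknown site {site_id!r}")
            for cond, value in levels.items():
                table.at[site_id, cond] = float(value)
    if ((table.to_numpy() < 0) | (table.to_numpy() > 1)).any():
        raise ValueError("occupancies must lie in [0, 1]")
    table.index.name = "site"
    return table


def _mnar_mask(rng, observed: pd.DataFrame, config) -> pd.DataFrame:
    if observed.empty or not config.mnar_enabled or config.mnar_slope == 0:
        return pd.DataFrame(False, index=observed.index, columns=observed.columns)
    vals = observed.to_numpy()
    positive = vals > 0
    with np.errstate(divide="ignore"):
        log10 = np.where(positive, np.log10(np.where(positive, vals, 1.0)), -np.inf)
    midpoint = np.percentile(log10[positive], config.mnar_midpoint_percentile)
    p_miss = expit(-config.mnar_slope * (log10 - midpoint))
    mask = (rng.random(observed.shape) < p_miss) | ~positive
    return pd.DataFrame(mask, index=observed.index, columns=observed.columns)


def _annotate(members, background, bait) -> AnnotationTable:
    complexes = ("CCAN", "KMN", "Dam1c", "Cbf3", "MAPs", "SAC", "CPC", "accessory")
    mapping = {bait: ("KMN", True)}
    for i, p in enumerate(m for m in members if m != bait):
        mapping[p] = (complexes[i % len(complexes)], True)
    for p in background:
        mapping[p] = ("other", False)
    return AnnotationTable.from_mapping(mapping)


def write_simulation(sim: SimulatedExperiment, out_dir: str | Path) -> dict[str, Path]:
    """Write the simulated experiment's files; returns the path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    comments = [f"baitquant simulation, seed: {sim.config.seed}"]
    paths = {
        "design": out_dir / "design.tsv",
        "protein_matrix": out_dir / "protein_matrix.tsv",
        "phospho_matrix": out_dir / "phospho_matrix.tsv",
        "annotation": out_dir / "annotation.tsv",
        "fasta": out_dir / "proteins.fasta",
        "truth_stoichiometry": out_dir / "truth_stoichiometry.tsv",
        "truth_occupancy": out_dir / "truth_occupancy.tsv",
        "truth_scales": out_dir / "truth_scales.tsv",
        "truth_missing_protein": out_dir / "truth_missing_protein.tsv",
        "truth_missing_phospho": out_dir / "truth_missing_phospho.tsv",
    }
    bq_io.write_design(sim.design, paths["design"], comments)
    bq_io.write_matrix(sim.protein, paths["protein_matrix"], comments)
    bq_io.write_matrix(sim.phospho, paths["phospho_matrix"], comments)
    bq_io.write_annotation(sim.annotation, paths["annotation"], comments)
    bq_io.write_fasta(sim.sequences, paths["fasta"])
    t = sim.truth
    bq_io.write_table(t.stoichiometry.reset_index(), paths["truth_stoichiometry"], comments)
    bq_io.write_table(t.occupancy.reset_index(), paths["truth_occupancy"], comments)
    bq_io.write_table(
        t.sample_scales.rename_axis("sample_id").reset_index(),
        paths["truth_scales"], comments,
    )
    bq_io.write_table(
        t.missing_protein.astype(int).rename_axis("protein").reset_index(),
        paths["truth_missing_protein"], comments,
    )
    bq_io.write_table(
        t.missing_phospho.astype(int).rename_axis("site").reset_index(),
        paths["truth_missing_phospho"], comments,
    )
    return paths


# ---------------------------------------------------------------------
# recovery metrics


def recovery_report(sim: SimulatedExperiment, bait: str | None = None) -> pd.DataFrame:
    """Run the standard normalisation chain on a simulated experiment and
    score how well it recovers the ground truth.

    Per condition: Spearman correlation between true stoichiometry and the
    estimated bait-scaled mean over tag-N replicates (complex members,
    bait excluded), and between true site occupancy and the estimated
    protein-normalised phospho mean over tag-PE replicates. Returns a tidy
    table (metric, condition, value, n).
    """
    bait = bait or sim.config.bait
    design = sim.design

    protein_norm = median_normalize(
        sim.protein, design.normalization_groups(fraction="N")
    )
    tag_n = design.select(tag="tag", fraction="N")
    usable = columns_with_bait(protein_norm, bait, tag_n)
    scaled = bait_scale(protein_norm, bait=bait, columns=usable)
    est_stoich = condition_means(scaled, design, "N", tag="tag")

    rows = []
    members = [p for p in sim.truth.stoichiometry.index if p != bait]
    for cond in sim.config.conditions:
        if cond not in est_stoich.columns:
            continue
        true = sim.truth.stoichiometry.loc[members, cond]
        est = est_stoich.reindex(members)[cond]
        ok = est.notna()
        rho = spearmanr(true[ok], est[ok]).statistic if ok.sum() >= 3 else np.nan
        rows.append(
            {"metric": "stoichiometry_spearman", "condition": cond,
             "value": float(rho), "n": int(ok.sum())}
        )

    if len(sim.phospho.data):
        phospho_norm = median_normalize(
            sim.phospho, design.normalization_groups(fraction="PE")
        )
        occ_est_all = normalize_phospho_to_protein(phospho_norm, protein_norm, design)
        est_occ = condition_means(occ_est_all, design, "PE", tag="tag")
        for cond in sim.config.conditions:
            if cond not in est_occ.columns:
                continue
            true = sim.truth.occupancy[cond]
            est = est_occ.reindex(true.index)[cond]
            ok = est.notna()
            rho = spearmanr(true[ok], est[ok]).statistic if ok.sum() >= 3 else np.nan
            rows.append(
                {"metric": "occupancy_spearman", "condition": cond,
                 "value": float(rho), "n": int(ok.sum())}
            )
    return pd.DataFrame(rows)
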