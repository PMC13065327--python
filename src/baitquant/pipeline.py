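"""End-to-end orchestration: simulate/read -> normalise -> filter -> test.

A single run config (YAML or dict) drives the whole chain; every output
TSV carries a header comment with the tool version, a hash of the config
and the seed, and the analysis path contains no unseeded randomness, so
re-running an identical config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from . import io as bq_io
from .diffenrich import (
    differential_test,
    foldchange_heatmap_table,
    log2_transform,
)
from .filters import completeness_filter, exclude_samples, replicate_intersections
from .groupstats import (
    phospho_site_max_range,
    protein_phospho_sum,
    ranked_list_builder,
)
from .motifs import (
    extract_windows,
    load_motif_config,
    motif_fractions,
    motif_site_heatmap_table,
    position_probability_matrix,
    site_condition_strata,
)
from .normalize import (
    bait_scale,
    columns_with_bait,
    median_normalize,
    normalize_phospho_to_protein,
)
from .simulate import SimulationConfig, simulate_experiment, write_simulation

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "simulate", "simulation", "inputs", "bait", "zeros_as_missing",
    "exclude_samples", "completeness_unit", "test_method", "top_n",
    "motif_config", "window_k", "seed", "site_id_dialect",
}
_KNOWN_INPUT_KEYS = {"design", "protein_matrix", "phospho_matrix",
                     "annotation", "fasta"}


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    validate_config(cfg)
    return cfg


def validate_config(config: Mapping[str, Any]) -> None:
    """Fail fast on unknown keys before any computation."""
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    inputs = config.get("inputs") or {}
    unknown_inputs = set(inputs) - _KNOWN_INPUT_KEYS
    if unknown_inputs:
        raise ValueError(f"unknown inputs key(s): {sorted(unknown_inputs)}")
    if not config.get("simulate"):
        required = {"design", "protein_matrix", "phospho_matrix"}
        missing = required - set(inputs)
        if missing:
            raise ValueError(
                f"config must set simulate: true or provide inputs: {sorted(missing)}"
            )
    sim_keys = config.get("simulation") or {}
    valid_sim = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown_sim = set(sim_keys) - valid_sim
    if unknown_sim:
        raise ValueError(f"unknown simulation key(s): {sorted(unknown_sim)}")


def config_hash(config: Mapping[str, Any]) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def run_all(config: Mapping[str, Any], out_dir: str | Path,
            seed: int | None = None) -> dict[str, Path]:
    """Execute the full pipeline under one config; returns the output path
    map. ``seed`` overrides the config seed for the simulation step (the
    analysis path itself is deterministic)."""
    validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    comments = [
        f"baitquant {__version__}",
        f"config: {config_hash(config)}",
        f"seed: {seed}",
    ]
    paths: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = out_dir / f"{name}.tsv"
        bq_io.write_table(df, path, comments, index=index)
        paths[name] = path

    bait = config.get("bait", "Dsn1")
    zeros_as_missing = bool(config.get("zeros_as_missing", True))

    # --- stage 1: inputs ---------------------------------------------
    if config.get("simulate"):
        sim_cfg = SimulationConfig(**{**(config.get("simulation") or {}),
                                      "seed": seed})
        sim = simulate_experiment(sim_cfg)
        sim_dir = out_dir / "simulated_input"
        write_simulation(sim, sim_dir)
        design, protein, phospho = sim.design, sim.protein, sim.phospho
        annotation, sequences = sim.annotation, sim.sequences
        bait = sim_cfg.bait
    else:
        inputs = config["inputs"]
        design = bq_io.read_design(inputs["design"])
        protein = bq_io.read_intensity_matrix(
            inputs["protein_matrix"], design, fraction="N",
            zeros_as_missing=zeros_as_missing,
        )
        phospho = bq_io.read_phospho_matrix(
            inputs["phospho_matrix"], design,
            zeros_as_missing=zeros_as_missing,
            dialect=config.get("site_id_dialect", "canonical"),
        )
        annotation = (bq_io.read_annotation(inputs["annotation"])
                      if "annotation" in inputs else None)
        sequences = (bq_io.read_fasta(inputs["fasta"])
                     if "fasta" in inputs else None)
    logger.info("inputs: %d proteins x %d N samples, %d sites x %d PE samples",
                *protein.shape, *phospho.shape)

    exclusions = config.get("exclude_samples") or []
    if exclusions:
        design = exclude_samples(design, exclusions)
        protein = protein.subset_columns(
            [c for c in protein.sample_ids if c in design.sample_ids])
        # a PE sample whose matched N sample was excluded cannot be
        # protein-normalised; it leaves the phospho analysis too
        keep_pe = [c for c in phospho.sample_ids
                   if c in design.pe_to_n]
        orphaned = [c for c in phospho.sample_ids
                    if c in design.sample_ids and c not in design.pe_to_n]
        if orphaned:
            logger.warning("dropping orphaned PE column(s): %s", orphaned)
        phospho = phospho.subset_columns(keep_pe)

    # --- stage 2: normalisation --------------------------------------
    def groups_for(matrix, fraction):
        groups = {
            name: [c for c in cols if c in matrix.data.columns]
            for name, cols in design.normalization_groups(fraction).items()
        }
        return {name: cols for name, cols in groups.items() if cols}

    protein_norm = median_normalize(protein, groups_for(protein, "N"))
    phospho_norm = median_normalize(phospho, groups_for(phospho, "PE"))
    phospho_occ = normalize_phospho_to_protein(phospho_norm, protein_norm, design)
    tag_n = design.select(tag="tag", fraction="N")
    scaled = bait_scale(protein_norm, bait=bait,
                        columns=columns_with_bait(protein_norm, bait, tag_n))
    emit("protein_median_normalized", protein_norm.data, index=True)
    emit("protein_bait_scaled", scaled.data, index=True)
    emit("phospho_protein_normalized", phospho_occ.data, index=True)

    # --- stage 3: filtering ------------------------------------------
    unit = config.get("completeness_unit", "condition_tag")
    protein_f = completeness_filter(protein_norm, design, "N", unit=unit)
    scaled_f = scaled.with_data(
        scaled.data.loc[scaled.data.index.intersection(protein_f.data.index)])
    phospho_f = completeness_filter(phospho_occ, design, "PE", unit=unit)
    logger.info("filtered: %d proteins, %d sites kept",
                len(protein_f.data), len(phospho_f.data))
    for key, venn in replicate_intersections(protein_f, design, "N").items():
        emit(f"venn_protein_{'_'.join(map(str, key))}", venn)

    # --- stage 4: differential enrichment ----------------------------
    method = config.get("test_method", "moderated_t")
    log_unscaled = log2_transform(protein_f)
    tag_results: dict[str, pd.DataFrame] = {}
    for cond in design.conditions:
        a = design.select(condition=cond, tag="tag", fraction="N")
        b = design.select(condition=cond, tag="no_tag", fraction="N")
        if len(a) < 2 or len(b) < 2:
            continue
        res = differential_test(log_unscaled, a, b, method=method)
        tag_results[cond] = res
        emit(f"diff_tag_vs_notag_{cond}", res, index=True)
    if annotation is not None and tag_results:
        emit("foldchange_heatmap",
             foldchange_heatmap_table(tag_results, annotation), index=True)

    log_scaled = log2_transform(scaled_f)
    stage_results: dict[tuple[str, str], pd.DataFrame] = {}
    for cond_a, cond_b in itertools.permutations(design.conditions, 2):
        a = [c for c in design.select(condition=cond_a, tag="tag", fraction="N")
             if c in log_scaled.data.columns]
        b = [c for c in design.select(condition=cond_b, tag="tag", fraction="N")
             if c in log_scaled.data.columns]
        if len(a) < 2 or len(b) < 2:
            continue
        res = differential_test(log_scaled, a, b, method=method)
        stage_results[(cond_a, cond_b)] = res
        if cond_a < cond_b:  # one file per unordered pair
            emit(f"diff_stage_{cond_a}_vs_{cond_b}", res, index=True)

    # --- stage 5: group statistics & ranked lists --------------------
    emit("protein_phospho_sum",
         protein_phospho_sum(phospho_f, design), index=True)
    site_ranges, protein_ranges = phospho_site_max_range(phospho_f, design)
    emit("phospho_site_ranges", site_ranges, index=True)
    emit("phospho_protein_ranges", protein_ranges, index=True)
    if annotation is not None:
        top_n = int(config.get("top_n", 50))
        for focal in design.conditions:
            triplet = [stage_results[(focal, other)]
                       for other in design.conditions
                       if other != focal and (focal, other) in stage_results]
            if not triplet:
                continue
            ranked = ranked_list_builder(triplet, annotation, top_n=top_n)
            emit(f"ranked_list_{focal}",
                 pd.DataFrame({"protein": ranked}))

    # --- stage 6: motifs ---------------------------------------------
    if sequences is not None:
        k = int(config.get("window_k", 6))
        patterns = load_motif_config(config.get("motif_config"))
        usable_sites = [s for s in phospho_f.sites if s.protein in sequences]
        windows = extract_windows(usable_sites, sequences, k=k)
        strata = site_condition_strata(phospho_f, design)
        emit("motif_fractions_by_stage",
             motif_fractions(windows, patterns, strata))
        if annotation is not None:
            sub_strata = {
                s.format(): (annotation.subcomplex(s.protein),)
                for s in usable_sites if annotation.is_kinetochore(s.protein)
            }
            emit("motif_fractions_by_subcomplex",
                 motif_fractions(windows, patterns, sub_strata))
            for pattern in patterns:
                if pattern.name in ("minimal_Polo", "minimal_Cdk"):
                    emit(f"motif_sites_{pattern.name}",
                         motif_site_heatmap_table(
                             phospho_f, windows, pattern, annotation, design),
                         index=True)
        if windows:
            emit("motif_ppm_all_sites",
                 position_probability_matrix(windows, k=k), index=True)
    return paths
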