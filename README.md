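# baitquant

Quantification pipeline for bait-anchored immunoprecipitation
mass-spectrometry (IP-MS) with a matched phospho-proteomics arm, built
for kinetochore purifications across cell-cycle stages but applicable to
any tagged-bait complex pull-down quantified as wide intensity matrices.

## The problem

A tagged bait protein (here the kinetochore MIND subunit **Dsn1**) is
immunoprecipitated from cells arrested at different stages (mitotic
metaphase, meiotic prophase, metaphase I, metaphase II), alongside
no-tag control IPs that measure non-specific background. Each IP yields
a protein-level sample ("N") and a phospho-enriched sample ("PE",
per-site intensities at high localisation confidence). The questions:
which proteins co-purify specifically, how does complex **stoichiometry**
change between stages, and how does per-site **phosphorylation
occupancy** change — all from label-free intensities with substantial
intensity-dependent missingness.

## The method

For protein intensities `I(p, s)` and phospho-site intensities
`F(site, s)`:

1. **Median normalisation** within sample groups (tag and no-tag IPs
   separately; N and PE tables separately):
   `I'(p, c) = I(p, c) · R_g / median_p I(p, c)`, with `R_g` the median
   of the group's column medians — after which every column's median
   equals `R_g`.
2. **Occupancy proxy**: `F'(site, s_PE) = 1000 · F(site, s_PE) /
   I'(protein(site), s_N)` with `s_N` the matched N sample (same
   condition, replicate, tag).
3. **Bait scaling**: `Ĩ(p, s) = I'(p, s) / I'(bait, s)` — a
   bait-relative stoichiometry proxy (bait row ≡ 1).
4. **Completeness filter**: keep rows quantified in all replicates of at
   least one (condition, tag) group; no imputation anywhere.
5. **Differential enrichment** per row on log2 values with an
   empirical-Bayes moderated t (`s̃² = (d₀s₀² + d s²)/(d₀ + d)`, prior
   estimated by moment matching on the scaled-F model), Bonferroni
   adjustment; Wilcoxon rank-sum (exact when small and tie-free) and
   pooled t for panel comparisons.
6. **Kinase-motif classification** of ±6 sequence windows around each
   site against configurable consensus patterns (minimal/strict Cdk,
   minimal/stringent Polo, Ipl1/Aurora, DDK), with match fractions by
   stage and sub-complex and position-probability matrices for logos.

A fully seeded simulator generates synthetic experiments with known
stoichiometries, occupancies, per-sample scale distortions, log-normal
noise and logistic missing-not-at-random dropout, so the whole chain is
validated against ground truth. See `docs/methods.md` for the model
details and assumptions.

## Worked example

```python
import baitquant as bq

cfg = bq.SimulationConfig(seed=1)          # 60 members, 40 background, 4x3 design
sim = bq.simulate_experiment(cfg)
print(f"simulated {sim.protein.shape[0]} proteins x {sim.protein.shape[1]} N samples, "
      f"{sim.phospho.shape[0]} phospho-sites")

report = bq.recovery_report(sim)           # run the chain, score vs truth
print(report.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

norm = bq.median_normalize(sim.protein, sim.design.normalization_groups("N"))
filt = bq.completeness_filter(norm, sim.design, "N")
res = bq.differential_test(
    bq.log2_transform(filt),
    sim.design.select(condition="prophase", tag="tag", fraction="N"),
    sim.design.select(condition="prophase", tag="no_tag", fraction="N"),
)
hits = res[(res["p_adjusted"] < 0.05) & (res["log2_fold_change"] > 0)]
print(f"{len(hits)} of {len(res)} proteins enriched in the tagged IP "
      f"(Bonferroni p < 0.05)")
```

prints

```
simulated 100 proteins x 24 N samples, 193 phospho-sites
                metric         condition  value   n
stoichiometry_spearman mitotic_metaphase  0.996  59
stoichiometry_spearman          prophase  0.994  59
stoichiometry_spearman       metaphase_I  0.993  59
stoichiometry_spearman      metaphase_II  0.994  59
    occupancy_spearman mitotic_metaphase  0.949 186
    occupancy_spearman          prophase  0.954 181
    occupancy_spearman       metaphase_I  0.958 186
    occupancy_spearman      metaphase_II  0.953 186
27 of 99 proteins enriched in the tagged IP (Bonferroni p < 0.05)
```

The Spearman rows say the pipeline's bait-scaled condition means rank
the true member stoichiometries almost perfectly in every stage, and the
protein-normalised phospho means track the true site occupancies, despite
20% measurement noise, per-sample scale distortions and intensity-
dependent dropout. The enrichment line is the tag-vs-no-tag volcano in
one number: members with enough signal over the no-tag background (about
half at the default 1% carryover and three replicates) reach
Bonferroni-corrected significance.

The same run is available from the shell:

```sh
baitquant simulate --out-dir sim --seed 1
baitquant run-all --config run.yaml --out-dir out --seed 1   # run.yaml: "simulate: true"
```

which writes all analysis tables (normalised matrices, per-contrast
differential results, fold-change heatmap input, phospho sums/ranges,
ranked GO-input lists, motif fractions and PPMs) as commented TSVs.

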