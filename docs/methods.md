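# Methods

## Overview

`baitquant` quantifies affinity-purification mass-spectrometry (IP-MS)
experiments anchored on a tagged bait protein, here the kinetochore MIND
subunit Dsn1, across cell-cycle conditions (mitotic metaphase, meiotic
prophase, metaphase I, metaphase II), with a matched phospho-proteomics
arm. Each immunoprecipitation yields a non-phospho-enriched fraction
("N", quantified at the protein-group level) and a phospho-enriched
fraction ("PE", quantified per phospho-site at high localisation
confidence); no-tag control IPs measure non-specific background. The
package implements the downstream quantification only — it starts from
wide intensity matrices of the kind a DIA search engine exports and a
sample-design table, never from raw spectra.

## Normalisation chain

1. **Column-median normalisation.** Within a sample group, every value in
   column *c* is multiplied by `R_g / median(c)`, where `median(c)` is the
   median over non-missing values and `R_g` is the group reference. The
   reference is taken as the median of the per-column medians within the
   group — under this convention every column's post-normalisation median
   equals `R_g` exactly, and the operation is idempotent. (The grand
   median of all pooled values is an alternative reading that coincides
   for balanced data; we chose the per-column-median convention because it
   is the one under which the factor formula "median intensity of all
   sample columns divided by the median sample intensity of that
   individual column" gives each column the same median.) Default groups:
   tag and no-tag IPs separately, N and PE tables separately, all
   conditions and replicates of a group together — four groups in the full
   design.
2. **Phospho-to-protein normalisation.** Each PE phospho-site value is
   divided by the matched N sample's value for the site's protein
   (matched = same condition, replicate and tag) and multiplied by 1000.
   The result is an occupancy proxy: it cancels protein-abundance and
   sample-loading changes, leaving per-site modification stoichiometry up
   to a site-specific detection-efficiency constant. Output is missing
   wherever either term is missing — never zero, never dropped.
3. **Bait scaling.** Protein values are divided by the bait's value in
   the same sample, giving bait-relative stoichiometries (bait row ≡ 1).
   The bait must be quantified in every scaled column; columns lacking it
   (no-tag IPs, or rare dropout) are excluded before scaling, with a
   logged warning, rather than silently imputed.

Missing values are honoured throughout: medians and means use non-missing
values only and **no imputation is performed anywhere**. Zero intensities
in input files denote non-detection and are converted to missing by
default (`zeros_as_missing`).

## Filtering

The completeness filter retains rows quantified in **all replicates of at
least one (condition, tag) group** (configurable to condition-only). It is
idempotent and monotone in the observed cells. Filtering is applied after
normalisation; sample exclusions (e.g. low-coverage replicates) are run
configuration, not code. Venn-style region counts over replicate or
condition detection sets support intersection reporting; region counts
always sum to the union size.

## Differential enrichment

Contrasts are two-sample tests per row on log2 intensities: tag vs no-tag
within a condition (specific enrichment over background, unscaled) and
stage vs stage on bait-scaled values (stoichiometry changes). The default
test is an empirical-Bayes **moderated t**: per-row pooled variances
`s_g²` with residual df `d_g` are shrunk toward a prior,

    s̃² = (d₀·s₀² + d_g·s_g²) / (d₀ + d_g),
    t = (x̄_A − x̄_B) / (s̃·√(1/n_A + 1/n_B)),   df = d_g + d₀,

with `(d₀, s₀²)` estimated from the ensemble of row variances by moment
matching on the scaled-F hierarchical model (matching mean and variance of
`log s_g²` through digamma/trigamma corrections; the trigamma inverse is
solved by Newton iteration). When the observed spread of log-variances is
within sampling noise, `d₀ = ∞` and all rows share `s₀²`. `prior_df=0`
reproduces the ordinary pooled t exactly; Welch's t is also available.
One unit test cross-checks the whole moderated-t path against
Bioconductor limma (`lmFit`/`eBayes`) on a shared matrix.

Rows with fewer than two non-missing values in either group are reported
untested (NaN statistics) rather than dropped, preserving row accounting.
P-values are two-sided; the multiple-testing family is all rows tested
within one contrast, adjusted with Bonferroni by default (BH available).
Published volcano statistics from any specific software version are not
expected to be bit-reproducible; the moderated-t model itself is the
documented contract.

## Group statistics

* Boxplot-style comparisons use the two-sided Wilcoxon rank-sum test:
  exact null distribution when both groups have ≤ 10 observations and the
  pooled sample is tie-free, otherwise the normal approximation with tie
  and continuity corrections (delegated to `scipy.stats.mannwhitneyu`).
  Individual-site bar comparisons use the two-sided pooled-variance t.
  Both adjust with Bonferroni over the comparisons on one panel.
* Per-protein phospho sums: for each condition, the sum over a protein's
  sites of the mean across that condition's non-missing replicates.
  A site undetected in a condition contributes nothing — fabricating
  zeros would contradict the no-imputation rule. Proteins are ranked by
  descending all-stage total.
* Per-site maximum range: max − min of per-condition means over
  conditions with a defined mean; sites detected in fewer than two
  conditions are excluded and counted. Proteins are summarised by the
  median of their sites' ranges.
* Ranked lists for GO input: per pairwise comparison, annotated
  kinetochore proteins are excluded, rows are ranked by descending log2
  fold change (ordering is identical for raw ratios), the top N taken
  (N = 50 for GO input, 20 for ranked tables), and the three lists of a
  focal stage concatenated and deduplicated preserving first occurrence.

## Motif analysis

Each phospho-site is represented by a ±k sequence window (default k = 6,
the common logo convention; configurable) centred on the acceptor, with
`_` padding beyond the termini; the FASTA residue at the site position
must agree with the site id, otherwise the site is rejected as stale. A
motif is a map from relative position to an allowed residue set; the
centre position defaults to {S, T}; padding matches nothing. The shipped
defaults are: minimal Cdk (+1 P), strict Cdk (+1 P, +3 K/R), stringent
Polo ([DEN]x[ST]F), minimal Polo (−2 D/E), Ipl1/Aurora (−2 R/K) and DDK
(+1 D/E). Only the stringent Polo definition is anchored to a published
stage-specific consensus; the others are common literature defaults and
are meant to be overridden per study — every fraction table echoes the
definitions used. Match fractions are stratified by the conditions in
which a site passes the completeness filter and/or by sub-complex;
position-probability matrices (per-position residue frequencies over
non-pad characters, rows summing to 1) feed sequence logos.

## Synthetic data generator

The simulator emulates the study design — 4 conditions × 3 replicates ×
{tag, no-tag} × {N, PE}, 48 samples — with known ground truth:

| parameter | default | meaning |
|---|---|---|
| `n_proteins` | 60 | complex members incl. bait |
| `n_background` | 40 | non-specific proteins |
| `bait_level` | 1e8 | bait intensity (arbitrary MS units) |
| stoichiometry | log-uniform 0.02–2 | bait-relative member abundance |
| `condition_effect_fraction` / `sd` | 0.3 / 1.0 | share of members with per-condition log2 effects and their SD |
| `sites_per_protein_mean` | 2 | Poisson mean phospho-sites per protein |
| occupancy | uniform 0.05–0.9 | per-site modified fraction, with per-condition effects as above |
| `noise_cv` | 0.20 | log-normal measurement CV |
| `sample_scale_sd` | 0.5 | per-sample scale distortion SD (log2) |
| `mnar_midpoint_percentile` / `mnar_slope` | 15 / 2 | logistic dropout in log10 intensity |
| `pe_efficiency` | 5 | phospho-enrichment gain |
| `carryover` | 0.01 | member signal in no-tag IPs |

Tag-N intensities are `bait_level × stoichiometry × sample scale ×
noise`; no-tag samples carry the background distribution plus the
carryover; PE intensities are the matched protein's expected abundance ×
occupancy × enrichment efficiency × scale × noise. Dropout is
missing-not-at-random: logistic in log10 intensity with its midpoint at a
low-abundance percentile, so faint signals vanish preferentially, as in
real label-free MS. Random protein sequences are generated with each
site's residue placed at its annotated position. A single seeded stream
makes identical configs byte-identical on disk; `null=True` removes all
condition effects for error-control studies.

What the simulator does **not** model: peptide-level quantification and
shared peptides, interference/ratio compression, retention-time or batch
drift, correlated missingness between fractions, and real protein
sequence composition (windows are uniform-random, so motif fractions on
simulated data sit at chance level). Passing recovery tests therefore
demonstrates correctness of the quantification chain under the stated
generative model, not performance on any particular real dataset.

## Validation strategy and problem sizes

The test suite checks each operation against an independent oracle
(hand-computed examples, brute-force set logic, full permutation
enumeration, regex-compiled motif classes, textbook step-up adjustment,
limma) and each pipeline invariant end-to-end on simulated data. The
standing validation runs use: 200 random matrices for the
median-normalisation invariant; 200×12 matrices for the completeness
filter oracle; 10⁴ random windows for the motif matcher; 20 seeds of the
default simulation for recovery (Spearman ρ ≥ 0.9 between true
stoichiometry and estimated bait-scaled means in every condition); and
200 null simulations of 500 rows for error control (Bonferroni-adjusted
p < 0.05 fraction within binomial margin of 0.05). `scripts/acceptance.py`
recomputes these quantities from scratch for any seed.

## Numerical choices and edge cases

* All computation in double precision; no intermediate rounding.
* Medians/means over non-missing values only; all-missing columns are an
  error at normalisation time (they indicate a broken upstream table).
* Identical groups give t = 0, p = 1 (the 0/0 limit is resolved to 0).
* `d₀ = ∞` (complete shrinkage) falls back to the normal reference
  distribution for the moderated t.
* Ties in ranked lists and sub-complex ordering are broken by stable
  sort, keeping outputs deterministic.
* Output TSVs carry `#` header comments (tool version, config hash,
  seed) and encode missing cells as empty fields; readers skip comments,
  so every output round-trips.

## Known limitations

* The pipeline assumes per-site phospho rows are already collapsed by
  the upstream search engine; no re-aggregation of multiply-modified
  peptides is attempted.
* Occupancy proxies are relative, not absolute: the ×1000 protein
  normalisation leaves a site-specific detection-efficiency factor, so
  values compare a site across conditions, not one site to another.
* The moderated t assumes exchangeable row variances within a contrast;
  with strong mean-variance trends a trended prior (not implemented)
  would fit better.
* GO enrichment itself is out of scope; the package only builds the
  ranked input lists.
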