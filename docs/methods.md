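# Methods

## Problem setting

Chromatin-modifying enzymes act on sets of target genes. If an enzyme's
activity varies across tissues or cell lines, the expression of its target
module should co-vary with it: positively for activating marks (H3K4me3,
maintained near active promoters and removed by KDM5-family demethylases),
negatively for repressive ones (H3K27me3, deposited by the Polycomb
methyltransferase EZH2). `chromsig` quantifies module activity per sample,
correlates it with enzyme expression, clusters samples on enzyme-gene
profiles, and quantifies enzyme transcripts on qPCR panels.

## Expression preprocessing

1. **log2 transform.** Linear intensities are log2-transformed; all
   downstream arithmetic is on the log2 scale. Non-positive linear values
   are an error, not silently floored.
2. **Probe QC.** A probe that never rises above the detection floor (by
   default the matrix minimum; configurable) in any sample is removed.
   Among sibling probes of one gene, probes are removed greedily — worst
   mean Pearson correlation against the remaining siblings first — while
   any probe falls below the `min_interprobe_pcc` threshold (default 0.5).
   The greedy form is forced by the semantics: with two concordant probes
   and one anti-tracking probe, a single-pass mean-PCC rule would flag all
   three (the bad probe drags every mean down), while worst-first removal
   isolates the culprit. Single-probe genes are never touched; a
   discordant two-probe pair is kept, since there is no evidence which
   probe is at fault. Filtering operates on log2 values; whether QC
   precedes or follows the transform is an open choice and this order is
   ours, not asserted as canonical.
3. **Collapsing.** One row per gene = arithmetic mean of its probe rows
   per sample. Genes losing all probes are omitted with a warning.
4. **Gene normalization.** Per row: subtract the mean, divide by the
   *sample* standard deviation (denominator n−1; switchable via `ddof`).
   Constant rows are centred and flagged instead of divided by zero; rows
   with fewer than two observed values are set to missing and flagged.
   Missing cells propagate as missing throughout (pairwise-complete
   statistics everywhere); they are never imputed or zero-filled.

## Module enrichment z-score

The observed statistic is the **median** gene-normalized expression of the
module's genes in one sample (even-size modules: mean of the two central
values). The null is the median of random same-size gene sets drawn
**without replacement** from the genes measured in that sample — a random
module is a set of distinct genes. The z-score standardizes the observed
median by the mean and **population** s.d. (ddof 0) of the sampled
medians: the z is a standardization against the realized null, not an
inference on it. Defaults: 10,000 draws; the standard-normal thresholds
±1.96 give the over/under calls per cell with no multiplicity correction
(an optional Benjamini–Hochberg adjustment across samples is available
behind a flag, off by default).

Numerical conventions:

* Degenerate null (`null_sd = 0`): z is 0 when the observed median equals
  the null mean (e.g. the module spans the whole universe, or the sample
  is constant) and undefined (NaN, called `ns`) otherwise.
* Module genes absent from the matrix shrink the effective size (logged);
  they are never imputed.
* Seeding: one `SeedSequence` child per (module index, sample index), so
  the z-matrix is independent of iteration order and any single cell can
  be recomputed in isolation.
* `exact_null` enumerates all C(n, k) same-size subsets when that count
  is below a cap (default 200,000) and returns the exact null moments; it
  is the oracle the Monte-Carlo path is tested against (|Δz| < 0.1 at
  50,000 draws on ≤12-gene universes).

The draw count and replacement convention of the original interactive
tooling for this statistic are not documented anywhere authoritative;
both are explicit configuration here, with the defaults above.

## Correlation signatures

Pearson product-moment correlation across samples, pairwise-complete, with
the complete-pair count reported next to every coefficient. Undefined
cases (constant vector, fewer than 3 complete pairs) are missing, never 0.
Enzyme–module correlations use the module's z-score profile by default;
`modules_as="median"` switches to the per-sample median normalized
expression of the module's genes — both are exported so the two summaries
can be compared. No p-values by default; a two-sided t-approximation is
available behind a flag.

## Sample clustering

Agglomerative clustering of sample columns under the **Manhattan**
(city-block) distance, computed over pairwise-complete genes. Linkage is
**average** by default (complete and single available) — the distance
metric is fixed by design, the linkage is a documented choice, surfaced in
the output metadata. Flat clusters are extracted by a requested *k*
(default 3) rather than a height threshold. Determinism: sample columns
are sorted by id before the distance matrix is built, so the result is
exactly invariant to input column order; remaining height ties resolve
through scipy's deterministic merge scan on that sorted layout. The tree
is exported as Newick with branch lengths equal to parent-minus-child
merge heights (leaves at height 0), the standard ultrametric encoding:
root-to-leaf path length equals the root merge height.

## qPCR quantification

Per-well QC, applied before anything else: wells with irregular melt
peaks (non-specific amplification) are **removed**; wells with no product
or Ct strictly above the cap (default 35 cycles) are **assigned** the
sentinel Ct 40 — assigned, not excluded, so they participate in the
per-gene mean by default (`include_assigned_in_mean=False` gives the
exclusion variant for sensitivity analysis; which the original protocol
used is not stated). A Ct of exactly 35 is untouched. Technical
replicates are averaged on the Ct scale.

Quantification, per sample *s* and gene *g* with reference *r* (B2M by
default):

    ΔCt(s,g)  = Ct(s,g) − Ct(s,r)
    ΔΔCt(s,g) = ΔCt(s,g) − mean_s' ΔCt(s',g)
    fold(s,g) = 2^(−ΔΔCt(s,g))

Centring on the gene's across-panel mean ΔCt makes levels arbitrary but
comparable: per gene, mean ΔΔCt is 0 (to 1e-12) and the geometric mean of
folds over the centring samples is 1. Samples lacking the reference gene
are flagged `missing_reference` with undefined folds. For rendering,
folds are clipped to [0, 10] with 1 the neutral midpoint and exported
alongside the raw values; baseline-threshold setting is an instrument-side
step and out of scope — Ct values are taken as given, with `plate_id`
retained so plate effects can be inspected.

## Synthetic data

One latent activity factor per sample, a_s ~ Normal(group mean,
`latent_sd`), drives everything:

    module gene g in M:  x_gs = baseline_g + beta_M * a_s + eps
    enzyme gene e:       x_es = baseline_e + loading_e * a_s + eps
    background gene:     x_gs = baseline_g + eps

with eps ~ Normal(0, `noise_sd`) and probes expanded from genes by adding
Normal(0, `probe_noise_sd`) probe effects. Defaults: baselines
Normal(7, 1.5) log2 units (the typical intensity range of log2 microarray
data), `noise_sd` 0.3, `probe_noise_sd` 0.1, three 20-sample groups at
latent means −2/0/+2, two 40-gene modules coupled +1/−1 with enzymes
loaded +1/−1 — one antagonistic activating/repressive axis. A single
latent factor is the simplest structure producing the positive
enzyme–module and negative module–module correlations of interest;
independent factors can be emulated by composing scenarios. Random
streams are partitioned by purpose (assignment, baseline, latent, noise,
probe, qPCR noise/dropout/melt) via `SeedSequence` spawn keys, so
changing one rate leaves the other draws untouched; a fixed scenario and
seed is bit-identical.

qPCR plates are constructed so the ΔΔCt pipeline recovers the planted
folds: a stable reference at Ct 20 and Ct(s,g) = 20 + c_g − log2 fold.
Because the pipeline centres each gene on its across-panel mean ΔCt, only
folds relative to the per-gene geometric mean are identifiable; input
folds are rescaled to geometric mean 1 and the rescaled values are the
reported truth, which noise-free analysis recovers exactly (a fold of 2
is one cycle below the fold-neutral Ct by construction).

**What the generator does not emulate:** array hybridization physics,
batch or plate effects, real tissue ontologies, correlated noise between
genes outside the planted factor, amplification-efficiency differences
between primers. A green test on synthetic data establishes that the
pipeline recovers the stated generative structure at the stated noise —
not that any particular biological dataset exhibits that structure.

## Known limitations

* The enrichment null is competitive within the sample (random gene sets
  from the same sample); self-contained or phenotype-permutation tests are
  out of scope.
* Raw ±1.96 calls per cell are liberal over many modules × samples; the
  BH option exists but is off by default for fidelity to the procedure
  being reproduced.
* Manhattan distances over pairwise-complete genes are not rescaled for
  differing completeness; with heavy missingness, distances are not
  comparable across pairs.
* Multi-reference-gene normalization and efficiency-corrected qPCR models
  are out of scope.
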