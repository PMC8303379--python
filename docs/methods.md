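# Methods

`immlncnet` re-implements, as a tested library, a common bulk-RNA-seq
analysis chain for screening immune-associated long non-coding RNAs
(imm-lncRNAs) in a two-genotype, histamine-perturbed myocardial-infarction
time course: differential expression from raw counts, temporal profile
clustering, gene-set over-representation, single-sample GSEA immune
infiltration scoring, and thresholded correlation networks assembled into a
multilayer lncRNA → immunocyte → functional-term network. All stages run
against synthetic data with planted ground truth; no external download is
required.

## Study design encoded by the synthetic generator

The generator (`immlncnet.simulate`) emulates the experimental layout the
pipeline targets: three arms — wild-type vehicle (`WT_vehicle`), knockout
vehicle (`KO_vehicle`), knockout + histamine (`KO_histamine`) — sampled at
0, 1 and 7 days after injury with 3 replicates each (27 libraries; any arm
subset can be requested). Its generative model, per gene *g* and sample
*s*:

1. **Baseline.** log2 mean μ_g ~ Uniform(3, 10) — counts from ~8 to ~1000,
   the dynamic range of moderately-to-well expressed genes.
2. **Latent immunocyte abundance.** a_{c,s} = δ_c·1[affected condition] +
   ε_{c,s}, with ε ~ N(0, σ² = 0.1). By default the five myeloid cell
   types (neutrophils, monocytes, three macrophage states) are *affected*:
   their abundance is raised by δ = `abundance_effect` (default 1 log2
   unit) in the knockout-vehicle arm at days 1 and 7 and restored under
   histamine — the qualitative infiltration pattern the pipeline is meant
   to detect.
3. **Marker coupling.** Each of the 22 immunocyte signatures owns
   `markers_per_celltype` (default 10) protein-coding genes whose log2 mean
   is μ_g + b·a_{c,s}, b = `marker_gain` (default 3.5). The coupling is
   log-additive, hence invertible for tests.
4. **Planted DE genes.** A fraction `frac_de` (default 0.1) of genes gets a
   persistent ±`de_log2fc` (default 2) shift in the affected arm(s), split
   between the knockout contrast (shift in both knockout arms) and the
   histamine contrast (shift in the histamine arm only). DE genes are drawn
   from non-marker protein-coding genes so the planted DE axis and the
   planted lncRNA–immunocyte axis stay orthogonal — a DE-shifted lncRNA
   would genuinely correlate with condition-shifted infiltration scores and
   make the link screen's ground truth ambiguous.
5. **Planted imm-lncRNAs.** `n_imm_lnc` (default 6) lncRNAs track one cell
   type's latent abundance: log2 mean μ_ℓ + b·a_{c,s} + N(0, σ_extra).
   σ_extra is chosen so that the *expected measured* Pearson correlation
   between log2 expression and a_{c,·} equals `imm_lnc_r` (default 0.9),
   where the count-level noise contribution is approximated by the delta
   method, Var(log2 Y) ≈ (1/m + φ)/ln²2. Planted lncRNAs are drawn from
   the moderately-to-highly expressed range (baseline ≥ 2^6) because below
   that the count noise alone exceeds the noise budget of r = 0.9. Links
   attach to *unaffected* cell types, whose latent abundances are mutually
   independent, so true and false links are unambiguous.
6. **Counts.** y ~ NB(mean = L_s·2^{log2 mean}, Var = m + φm²) with
   dispersion φ = `dispersion` (default 0.1) and library factor
   L_s ~ Uniform(0.7, 1.3); φ < 1e-8 falls back to Poisson. A single
   seeded generator drives everything; identical configs give byte-identical
   outputs.

What the generator does **not** model: batch effects, GC/length bias,
count outliers, correlated replicate structure, signature overlap between
cell types, and real marker-gene biology (the 22 signatures are disjoint
synthetic panels, not curated marker lists). Passing tests therefore
demonstrate algorithmic correctness and calibration under the assumed NB
model, not robustness to real-data artefacts.

## Differential expression

Normalization uses trimmed-mean-of-M-values (TMM) factors: per sample
against a reference (upper-quartile-closest-to-mean by default), log ratios
M and abundances A over genes positive in both, a 30%/5% two-sided trim on
M/A, a precision-weighted mean of the retained M, and rescaling to
geometric mean 1.

Dispersion is estimated per gene by the method of moments on counts scaled
to a common effective library size, variances pooled within groups:
φ̂ = max(0, (s² − m̄)/m̄²), then shrunk toward the common dispersion with
weight prior_df/(prior_df + pooled residual df), prior_df = 10 (≈0.71 at
3 vs 3). Two numerical choices matter and were validated by simulation:
the common value is the across-gene **mean** (raw moment estimates at 4 df
are right-skewed, so the median sits ~20% below the truth), and the
dof-based weight is the moderation strength needed to keep the exact test's
size near nominal — with a fixed weight of 0.3 the measured null rejection
at p < 0.05 was 0.083–0.094; with the shipped estimator it is 0.043–0.052.

Testing is an exact conditional NB test: counts are scaled to the mean
effective library size, group sums rounded, and, conditional on the total
(with the common per-sample mean estimated from it), the two-sided p-value
sums the probabilities of all splits no more likely than the observed one.
Group sums of n iid NB(m, φ) variables are NB(nm, φ/n). log2 fold changes
use normalized group means with a prior count of 0.5 to avoid infinities.
Genes are pre-filtered to CPM > 1 in ≥ 2 samples (configurable; the
original analysis's filter is unstated).

DEGs are called at |log2FC| ≥ 0.5 and p < 0.05, thresholds inclusive. The
fold-change rule is read on the log2 scale (a raw fold-change threshold of
0.5 excludes nothing on the up side and everything meaningful on the down
side). The p-value is unadjusted by default, following the source
convention; BH-adjusted values are always reported and `use_adjusted`
flips the criterion. Parameter-recovery checks use the adjusted criterion,
since a false-discovery-proportion bound is what BH controls; with
unadjusted calling at a 10% planted fraction the FDP is ~0.25 by
arithmetic (0.05 type-I on ~90% null genes), not an implementation defect.

## Temporal profile clustering

Candidate templates are all integer unit-change profiles over the ordered
timepoints, first entry 0, steps bounded by `max_unit_change` (default 2;
24 templates for 3 timepoints). Timepoints are ordinal — the 1→7-day gap
is not time-weighted. Gene trajectories (mean log2-CPM deltas vs day 0 in
the contrast arm) are assigned to the best-Pearson-correlated template,
ties to the lowest id, zero-variance trajectories to a flat bin.
Significance permutes each gene's non-baseline values independently and
re-assigns (p floor 1/(1+B), Bonferroni across templates).

Two structural caveats, documented rather than hidden: with three
timepoints the permutation group has only two elements per gene, so
swap-symmetric templates such as (0, 1, 1) can never be significant —
only monotone-type occupancy is testable; and neighbouring templates
correlate up to ~0.95, so exact-template recovery from noisy three-point
trajectories is intrinsically limited (measured: 81% at noise σ = 0.3,
96% at σ = 0.2 with the 8-template set). Cluster counts are
data-dependent and are not fixed constants of the method.

## Over-representation analysis

One-sided hypergeometric test per gene set: p = P[X ≥ k] via the survival
function, universe defaulting to expressed genes, term sizes restricted to
[3, 500] after intersection with the universe, BH adjustment across
retained terms (the adjusted-p method in the source is unstated; BH is
assumed). The discrete test is slightly conservative: measured null
rejection at p < 0.05 is ~0.035–0.045.

## ssGSEA infiltration scoring

Per sample, genes are ranked by expression (rank N at the top; ties broken
by gene id after a stable sort, for bitwise reproducibility). For a
signature G the enrichment score accumulates
P_in(i) − P_out(i) over all list positions, where P_in weights in-set
ranks by rank^α (α = 0.25 default) and P_out is the unweighted out-of-set
step function. Scores depend only on within-sample ranks, hence are
invariant to any strictly monotone per-sample transform; log2-CPM is the
conventional input. Signatures with zero or complete overlap with the
matrix are rejected rather than special-cased. Raw scores are
range-normalized over the whole matrix to [0, 1] and converted per sample
to fractions summing to 1. Cell–cell association uses Pearson r with
two-sided t p-values (n − 2 df); zero-variance cell types propagate NA
with a warning.

## Correlation networks and the multilayer screen

Gene-level correlations run on TMM-corrected log2-CPM, pooling all
samples. Plain library-size CPM was measurably wrong here: a strong
marker upshift inflates affected samples' library sizes and depresses
every other gene's CPM there, manufacturing spurious negative
gene–score correlations; TMM absorbs the compositional shift.

Edge screens: lncRNA–pcRNA at |r| > 0.9 and BH-adjusted p < 0.01 (BH over
all tested pairs); lncRNA–immunocyte at |r| > 0.75 and raw p < 0.001 —
both literal readings of the source thresholds, both configurable, with a
`positive_only` option. Hub categories are terciles of the positive-degree
distribution (boundary ties resolve upward); the source's hub rule is
unquantified, so terciles are this package's choice. Every lncRNA with a
retained cell edge is an imm-lncRNA candidate; its correlated
protein-coding set is ORA-tested and terms at adjusted p < 0.05 become
lncRNA → term edges. Exports: GraphML, edge-list TSV, and a Sankey-style
long table (one row per cell edge × attached term, weighted by |r| and
gene ratio).

At 18–27 samples the count noise caps gene–gene correlations near 0.85
even for genes driven by the same latent abundance, so the default
|r| > 0.9 pcRNA screen is intentionally strict and may return no edges on
synthetic data of this size; mechanism-level tests relax it to 0.75.

## Problem sizes in tests and the acceptance script

Calibration runs use 5000-gene null simulations (3 seeds), recovery runs
the default 2300-gene experiment (5 seeds in tests, 3 in the script), the
ORA null uses 2000 term-tests, and profile calibration 20 noise runs of
300 genes — sizes at which every quantity's sampling error is well inside
its acceptance band while the whole suite stays fast. The full default
pipeline run completes in a few seconds on one CPU.

## Known limitations

* Two-group contrasts only; no GLM framework, covariates, or multi-factor
  designs.
* The exact test treats the moderated dispersion as known; heavily
  overdispersed outlier genes (far above the common dispersion) remain
  slightly anti-conservative, as in any moderated small-sample NB test.
* Signature quality is the user's responsibility for real data; the
  bundled 22-set panel is synthetic scaffolding, not a curated resource.
* Gene identifiers are opaque strings; no symbol/ID mapping layer.
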