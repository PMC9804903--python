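# Methods

## Study design being modelled

The pipeline targets a two-species heat-wave experiment: two related plant
species (a heat-tolerant extremophyte, called species B, and a
stress-sensitive reference, species A) sampled under nine conditions —
morning and afternoon controls (CM, CN), four heat-wave samplings over
three consecutive hot days (HW1M, HW1N, HW2N, HW3N), two recovery days
(R1N, R2N) and a recovery-matched control (CR2N) — with three biological
replicates per condition and species.  The unit of cross-species
comparison is the one-to-one ortholog pair.

## Count model and simulation

Counts are negative binomial with `Var = μ + αμ²`; α is the dispersion
(default 0.05, a typical value for well-replicated plant bulk RNA-seq;
α = 0 degenerates to Poisson).  For each ortholog pair one baseline mean is
drawn log2-uniformly on [3, 11] (≈8–2000 counts, spanning weakly to highly
expressed genes) and shared by both species; the pair's ground-truth mode
then shapes per-condition means:

| mode | species A | species B |
|---|---|---|
| shared_up / shared_down | ±effect in heat | ±effect in heat |
| unique_A / unique_B | effect in one species only (sign randomized) | — |
| opposite | +effect | −effect (orientation randomized) |
| no_response | flat | flat |
| stress_ready_A (resp. B) | constitutively offset by `stress_ready_offset_lfc`, flat across conditions | responds in heat with lfc equal to the offset, reaching the ready species' level |

`effect_lfc` defaults to 2 (a 4-fold change, the magnitude of a strong
heat-shock response); the stress-ready offset defaults to the same value
so the responsive species exactly reaches the ready species' constitutive
level.  Mode proportions default to the frequencies reported for the
Arabidopsis/Anastatica comparison (82% shared, 4.5%/1.9% stress-ready,
≈5% unique, 2.1% opposite, 4.4% none); published rounded percentages sum
to 99.9% and are renormalized.

Two generator choices matter for realism and are deliberate:

- **Per-condition response structure.** A responsive gene responds in a
  random subset of the four heat samplings (each with probability 0.75, at
  least one).  Real heat-wave series separate early and late responders;
  equally importantly, if *every* responsive gene shifted in *every* heat
  sample, more than half of a sample's genes would move one way and
  median-of-ratios normalization (whose breakdown point is 50% shifted
  genes) would fail on data that real pipelines normalize routinely.
  Recovery conditions always revert to baseline.
- **Length-conserved orthologs.** The two orthologs of a pair get the same
  transcript length up to ±10% jitter.  Orthologous transcripts are nearly
  length-conserved, and this is precisely what licenses comparing TPM
  levels across species; fully independent lengths would scramble the
  level tests with a random length ratio.  The jitter keeps the two length
  files genuinely different so length correction is still exercised.

Response polarities of unique/opposite pairs are randomized per gene so
that neither species' per-sample composition is predominantly one-sided.
Stress-ready polarity is a global switch (constitutively high by default,
low with `stress_ready_down`).  `effect_lfc_scale_B` multiplies species
B's fold-changes to simulate an asymmetrically more reactive species.
All draws come from one seeded PCG64 generator; outputs are byte-stable
under a fixed seed.

What the generator does **not** emulate: GC/length biases within a
species, batch effects, correlated gene-gene noise outside planted
modules, unequal replicate quality, multi-mapping artifacts, and
condition-dependent dispersion.  Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under the NB model, not
that real libraries are free of these artifacts.

## Normalization

TPM uses annotated length as effective length (the gene-level simulation
has no fragment model).  Size factors are classic median-of-ratios with a
geometric-mean reference over genes expressed in every sample.  The log
transform is `log2(normalized + 1)` — a monotone, variance-taming stand-in
for a regularized log; downstream statistics use ranks, means and
replicate t-tests, for which empirical-Bayes shrinkage of the transform
would change little.  A caveat the simulation exposes: when a large
fraction of genes responds strongly and asymmetrically, the median ratio
in heat samples drifts off the true null center and measured inductions
compress; the housekeeping basal-ratio control (mean ± SD of per-pair
control-condition ratios) is the diagnostic for this.

## Differential expression

Each contrast is a two-group comparison on size-factor-normalized counts:
HW1M vs CM, HW1N/HW2N/HW3N and R1N vs CN, R2N vs CR2N.  The log2
fold-change is `log2((m_trt + 0.5)/(m_ctl + 0.5))` (the 0.5 pseudocount
keeps zero-mean groups testable); its standard error comes from the delta
method under NB variance, and p-values from the normal reference.
Dispersion is the method-of-moments estimate per group, averaged, floored
at 0.01 — and, inside the caller, moderated by flooring each gene at the
across-gene mean: per-gene moments from three replicates are far too
noisy to stand alone, and allowing a gene's dispersion to fall below the
pooled level makes the Wald test anticonservative.  The test suite checks
the null rejection rate at p < 0.05 stays within [0.03, 0.08] under the
study's replicate structure, and ≥90% power at |log2FC| = 2.  BH
adjustment is applied within each contrast; a gene is up/down when
q ≤ 0.05 (inclusive) with the configured |log2FC| gate (default 0, so any
significant change counts).  The Union status of a gene is the status of
its most significant heat contrast (smallest q, ties by larger |log2FC|).

Genes with all-zero counts in both groups are flagged untestable and
reported as ns.

## Co-expression modules

Unsigned networks by default (`|r|^β`; a signed option exists).  β is the
smallest grid power whose connectivity distribution fits scale-free
topology with R² ≥ 0.8 (log-log regression over 10 connectivity bins);
when no grid power reaches the target — typical for small or strongly
modular data, which is not scale-free — the conventional default power (6
unsigned, 12 signed) is used rather than the best of a bad fit.
Topological overlap is computed in matrix form and verified against an
O(n³) triple-loop oracle.  Genes cluster by average linkage on 1 − TOM
with a deterministic static cut: by default at the midpoint of the largest
gap between consecutive merge heights, which lands between within-module
and between-module merges whenever the tree separates cleanly (a fixed
fraction of the data-dependent tree height can straddle them).  Clusters
below `min_module_size` (default 30) are unassigned.  Eigengenes are first
principal components of standardized module expression, sign-anchored to
correlate positively with their genes; modules whose eigengenes correlate
above 0.85 are merged greedily (highest correlation first, deterministic
tie-break) to a fixed point.  In the pipeline, networks are built on the
`coexpr_max_genes` (default 1000) most variable genes for tractability;
module labels are a consistency annotation on the mode calls, not an input
to classification.

## Mode classification

Inputs per pair: the two species' Union DE statuses and level-equivalence
t-tests on TPM.  Decision order: both responsive and same sign → shared;
both responsive, opposite signs → opposite; exactly one responsive →
stress-ready if the non-responsive species' control level equals the
responsive species' heat extreme (p > 0.05) *and* the two control levels
differ (p ≤ 0.05), else unique; neither responsive → no response; missing
data → unassigned.  The heat extreme is the replicate-wise maximum (for
up-regulation) or minimum (for down-regulation) of TPM across the four
heat samplings; control levels pool CM and CN replicates.  Welch's
t-variant is the default (cross-species variances need not match); a
pooled-variance switch exists.  The two stress-ready gates are what keep
the mode distinct from a unique response — without the control-difference
gate, every unique responder whose partner happens to sit at a similar
level would be called stress-ready; both gates are switchable.

The classifier is exhaustive and exclusive over all status combinations,
and species-symmetric (swapping species maps A-modes to B-modes).  On
simulated data at the default settings the suite requires ≥85% overall
accuracy, ≥80% stress-ready precision, and recovered mode proportions
within ±3 percentage points of the generator truth.  Stress-ready recall
is intentionally partial — the equivalence gate must *fail to reject*,
which favours precision over recall — and rises with the constitutive
offset (a property the suite checks over five offsets).

## Reactivity statistics

Basal expression is the CM (control morning) level on the log scale.
Percent change from basal is `100 × (extreme − basal) / basal` computed on
log-scale values (a linear-scale option exists); up-regulated genes use
the max over heat samplings, down-regulated the min.  In the per-ortholog
comparison the numerators are replicate-matched but the denominator is
the mean basal level: dividing each replicate by its own noisy basal draw
inflates within-gene variance without informing the contrast, while a
fully mean-based variant hides the basal error from the within-group
spread and inflates the false-verdict rate.  The comparison itself is a
two-sided pooled-variance Student t-test on |percent change| replicates
(α = 0.05), with the verdict direction from the sign of the difference.
Under a symmetric null the suite checks the per-side verdict rate stays
within the binomial band around α/2, and that simulated 2×-stronger
responders are flagged with ≥80% recall on counts with known library
factors.  End-to-end (with estimated size factors) recall is a few points
lower because strong asymmetric responses bias the median-of-ratios
factors — see Normalization above.

The genome-wide shift test is the two-sided Wilcoxon rank-sum: exact
enumeration when the smaller sample has ≤8 values and no cross-sample
ties, otherwise the normal approximation with tie correction.

## Selection screen

The screen consumes per-ortholog-group summaries of a nested codon-model
pair (branch-site null and alternative): log-likelihoods, foreground
dN/dS, and per-site empirical-Bayes posteriors.  Codon-model optimization
itself is out of scope; any codeml-style TSV can be loaded.  The LRT
statistic is `max(0, 2ΔlnL)` with a χ² reference (df = 1 by default, the
difference of one free parameter between the models; per-record df is
honoured).  Alternatives within numerical tolerance below the null are
floored; larger violations are rejected as non-nested.  Multiplicity uses
Benjamini–Yekutieli (harmonic-sum penalty `c(m) = Σ 1/i`), valid under
the arbitrary dependence expected among ortholog groups sharing a
phylogeny; BY dominates BH elementwise, which the suite verifies.  A gene
is a PSG when q < 0.05 and foreground ω > 1; selected sites need
posterior > 0.95.  q-passing records lacking an ω estimate are excluded
and flagged rather than guessed.  The null simulator draws pure χ²₁ by
default; a point-mass-at-zero mixture (the boundary case of branch-site
practice) is available.

## Determinism and orchestration

One global seed fans out to per-stage child seeds through a SHA-256 hash
of `"{seed}:{stage}"` (taken mod 2³¹), so adding a stage never perturbs
earlier stages' draws.  All tables are written sorted with fixed float
formatting; two runs with the same config and seed are byte-identical,
which the suite asserts file by file.  The pipeline's summary report
collects per-contrast DEG percentages, mode counts and proportions, the
reactive-set size, the housekeeping ratio and the PSG count.

## Problem sizes

The default verification sizes — 5,000 ortholog pairs for classifier
recovery, 2,000 genes for DE calibration, 10,000 draws for LRT
uniformity, 1,000 pairs for reactivity power, 120 genes for planted-module
recovery, 150 pairs for determinism runs — are chosen so the full suite
and the acceptance script each complete in a few minutes on a single
core while leaving Monte-Carlo error well below the margins being
asserted.

## Known limitations

- The log transform is not a true regularized log; extremely low counts
  are stabilized only by the pseudocount.
- Median-of-ratios normalization degrades when responses are strong,
  dense and asymmetric between conditions; the housekeeping control
  flags, but does not correct, this.
- The Wald DE test relies on a normal reference with three replicates;
  calibration is verified empirically rather than guaranteed by theory.
- Stress-ready classification depends on accepting a null hypothesis
  (level equivalence) at n = 3–6, so its recall is bounded by test power;
  calls are precise rather than complete.
- The mode classifier uses DE status plus level tests; co-expression
  module membership is reported alongside but does not gate calls.
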