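# heatortho

Cross-species comparison of heat-stress transcriptomes through one-to-one
orthologs.

When a stress-tolerant species is compared with a sensitive relative, two
competing pictures are possible: the tolerant species may hold its
stress-response genes constitutively high (a "stress-ready" transcriptome),
or it may keep a low basal state and react more strongly when stress
arrives.  Distinguishing them requires comparing, for every ortholog pair,
*absolute* expression levels across species and *relative* responses within
species.  `heatortho` implements that comparison as a tested, reusable
pipeline for two-species RNA-seq count data, together with a synthetic-data
generator that makes every stage verifiable against known ground truth —
the setting mirrors a desert Brassicaceae (heat-tolerant, species B)
against *Arabidopsis thaliana* (species A) over three daily heat waves with
morning/afternoon samplings, recovery days, and three biological
replicates per condition.

## What it computes

- **Normalization** (`heatortho.quantify`): TPM
  (`tpm_gs = (c_gs / l_g[kb]) / Σ_g (c_gs / l_g[kb]) × 10⁶`),
  median-of-ratios size factors
  (`s_s = median_g c_gs / (Π_t c_gt)^{1/n}`), and a log transform
  `log2(c_gs / s_s + 1)` used by all downstream statistics.
- **Differential expression** (`heatortho.de`): per-gene NB Wald test per
  heat/recovery contrast against its matched control, with
  method-of-moments dispersion `α̂ = max(0, (s² − m̄)/m̄²)` moderated by the
  across-gene mean, Benjamini–Hochberg FDR, and the **Union** set (DE in at
  least one of HW1M, HW1N, HW2N, HW3N).
- **Co-expression modules** (`heatortho.coexpr`): soft-threshold adjacency
  `a_ij = |cor(x_i, x_j)|^β` with β from the scale-free topology criterion,
  topological overlap
  `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`,
  average-linkage clustering with a deterministic static cut, eigengenes
  (first principal components) and eigengene-correlation merging.
- **Response-mode classification** (`heatortho.modes`): each ortholog pair
  becomes *shared* (up/down), *unique*, *opposite*, *no response*, or
  *stress-ready* — the mode where one species' control level already equals
  the other species' heat extreme (Student/Welch t-tests on TPM levels,
  P ≤ 0.05 gates).
- **Reactivity statistics** (`heatortho.reactivity`): basal (control
  morning) expression, percent change from basal to the heat-wave extreme
  (`100 × (extreme − basal)/basal` on log-scale values), per-ortholog
  tests for a stronger response in one species, Wilcoxon rank-sum
  distribution-shift tests, and a housekeeping basal-ratio control.
- **Positive-selection screen** (`heatortho.selection`): likelihood-ratio
  test `Λ = 2(lnL_alt − lnL_null)` against χ², Benjamini–Yekutieli FDR
  (valid under arbitrary dependence), and PSG calling with q < 0.05,
  foreground dN/dS > 1, and site posteriors > 0.95.
- **Synthetic data** (`heatortho.simulate`): NB counts
  (`Var = μ + αμ²`) for both species under the full condition design, with
  configurable mode proportions, effect sizes, constitutive stress-ready
  offsets, dispersions, library size factors and gene lengths — and the
  ground truth returned for every pair.

## Worked example

`examples/01_simulate_and_classify_modes.py` simulates 2,000 ortholog
pairs at realistic mode proportions and runs DE + mode classification:

```
                n_pairs  pct_of_assigned  truth_pct
mode
stress_ready_A       11             0.55       1.75
stress_ready_B       44             2.20       4.85
shared_up           819            40.95      41.00
shared_down         828            41.40      40.80
unique_A             94             4.70       2.20
unique_B             63             3.15       2.55
opposite             84             4.20       2.30
no_response          57             2.85       4.55
unassigned            0              NaN        NaN

classification accuracy vs ground truth: 93.1%
```

Reading the table: 82% of pairs respond alike in both species (shared
up/down), a few percent respond in only one species, and ~2% of pairs are
"stress-ready" in species B — its control-condition level already sits at
the heat level of its species-A ortholog.  The recovered percentages track
the generator's truth column within a few points; stress-ready calls are
conservative (high precision, partial recall) because they must pass two
level-equivalence gates.

The other examples cover differential expression and the Union set (02),
module detection (03), the species-reactivity comparison with the
housekeeping control (04), and the selection screen (05).  The same
stages are available from the shell:

```bash
heatortho simulate --n-orthologs 2000 --seed 1 --out run/
heatortho run-all --seed 1 --out run/
```

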