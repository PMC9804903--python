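"""Per-contrast differential expression and the Union DEG set.

Runs the NB Wald caller for species A over the six condition-vs-control
contrasts and prints, per contrast, how many genes move up/down and the
percentage of all genes that respond — the shape of a heat-wave series:
strong responses during the heat days, near silence after recovery.
"""

from heatortho import SimulationConfig, simulate_experiment, run_de
from heatortho.de import deg_percentages

exp = simulate_experiment(SimulationConfig(n_orthologs=2000, seed=2))
table = run_de(exp.counts_A, exp.sample_sheet, "A")

pct = deg_percentages(table, n_total_genes=2000)
print(pct.round(2).to_string(index=False))
print("\nHW* rows are the heat contrasts; R1N/R2N are recovery days where "
      "expression returns to baseline.  'Union' counts genes differentially "
      "expressed in at least one heat contrast.")
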