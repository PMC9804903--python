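"""Detect co-expression modules with the weighted-network recipe.

Builds an expression matrix with three planted co-expression modules,
runs soft-threshold adjacency -> topological overlap -> average-linkage
clustering -> eigengene merging, and prints the detected module sizes and
the agreement (adjusted Rand index) with the planted structure.
"""

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from heatortho import detect_modules
from heatortho.quantify import ExpressionMatrix

rng = np.random.default_rng(0)
profiles = rng.normal(size=(3, 27))  # three module expression programs
rows, planted = [], []
for m in range(3):
    for _ in range(40):
        rows.append(profiles[m] * rng.uniform(0.7, 1.3) + rng.normal(0, 0.35, 27))
        planted.append(m)

expr = ExpressionMatrix(
    pd.DataFrame(np.array(rows), index=[f"g{i}" for i in range(120)],
                 columns=[f"s{j}" for j in range(27)]),
    "rlog",
)

result = detect_modules(expr, min_module_size=10)
print("chosen soft power:", result.chosen_power,
      f"(scale-free R^2 = {result.scale_free_r2:.2f})")
print(result.labels.value_counts().to_string())
ari = adjusted_rand_score(planted, pd.factorize(result.labels)[0])
print(f"adjusted Rand index vs planted modules: {ari:.3f}")
print("ARI 1.0 means the three planted co-expression programs were "
      "recovered exactly; eigengenes summarize each module's profile.")
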