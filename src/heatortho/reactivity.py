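"""Basal-expression, percent-change and transcriptome-reactivity statistics.

Basal expression is the rlog level under the morning control (CM).
Percent change from basal is 100 * (extreme - basal) / basal computed on
rlog values, where "extreme" is the replicate-wise maximum over the four
heat-wave conditions for up-regulated genes and the minimum for
down-regulated genes.  Per ortholog pair, a two-sample Student t-test on
the |percent change| replicates decides which species reacts more
strongly; genome-wide distribution shifts are tested with the Wilcoxon
rank-sum test; and a housekeeping basal-ratio control checks that
cross-species normalization is unbiased.

In the pairwise comparison the replicate percent changes use the mean
basal level as the denominator (numerators stay replicate-matched):
dividing each replicate by its own noisy basal draw inflates the
within-gene variance without informing the contrast, while a shared
denominator keeps replicates independent (the t-test stays calibrated,
unlike a fully mean-based variant whose common basal error is invisible
to the within-group spread).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import HEAT_CONDITIONS, OrthologMap, SampleSheet, ValidationError
from .quantify import ExpressionMatrix


def basal_expression(
    expr: ExpressionMatrix, sheet: SampleSheet, species: str, gene: str
) -> np.ndarray:
    """rlog values of a gene in the CM (control morning) replicates."""
    if gene not in expr.values.index:
        raise ValidationError(f"gene not found: {gene!r}")
    ids = sheet.samples_for(species, "CM")
    if not ids:
        raise ValidationError(f"no CM samples for species {species}")
    return expr.values.loc[gene, ids].to_numpy()


def extreme_expression(
    expr: ExpressionMatrix, sheet: SampleSheet, species: str, gene: str, direction: str
) -> np.ndarray:
    """Replicate-wise heat extreme (max if up, min if down) of rlog values."""
    if direction not in ("up", "down"):
        raise ValidationError(f"direction must be 'up' or 'down', got {direction!r}")
    cols = [sheet.samples_for(species, c) for c in HEAT_CONDITIONS]
    stack = np.stack([expr.values.loc[gene, ids].to_numpy() for ids in cols])
    return stack.max(axis=0) if direction == "up" else stack.min(axis=0)


def percent_change(basal, extreme, direction: str) -> np.ndarray:
    """Signed percent change from basal, replicate-paired by index."""
    basal = np.asarray(basal, dtype=float)
    extreme = np.asarray(extreme, dtype=float)
    if basal.shape != extreme.shape:
        raise ValidationError("basal and extreme replicate vectors must align")
    if direction not in ("up", "down"):
        raise ValidationError(f"direction must be 'up' or 'down', got {direction!r}")
    if np.any(basal == 0):
        raise ValidationError("zero basal expression; percent change undefined")
    return 100.0 * (extreme - basal) / basal


def compare_reactivity(
    orthologs: OrthologMap,
    expr_A: ExpressionMatrix,
    expr_B: ExpressionMatrix,
    sheet: SampleSheet,
    direction: pd.Series,
    alpha: float = 0.05,
    welch: bool = False,
    species: tuple = ("A", "B"),
    paired_denominator: bool = False,
) -> pd.DataFrame:
    """Per-ortholog comparison of |percent change| between species.

    ``direction`` maps gene_A ids to 'up'/'down' (genes absent or 'ns' are
    skipped).  The verdict is higher_in_B / higher_in_A when the two-sided
    t-test on |percent change| replicates is significant, else ns.  Pairs
    with a zero basal replicate (percent change undefined even after the
    log-transform pseudocount) are dropped.  ``species`` names the sample-
    sheet species of ``expr_A`` / ``expr_B``, letting callers swap sides.
    """
    sp_a, sp_b = species
    if len(sheet.samples_for(sp_a, "CM")) != len(sheet.samples_for(sp_b, "CM")):
        raise ValidationError("replicate mismatch between species")
    pairs = orthologs.pairs
    dirs = direction.reindex(pairs["gene_A"]).fillna("ns").to_numpy()
    frames = []
    for d in ("up", "down"):
        sel = dirs == d
        if not sel.any():
            continue
        genes_a = pairs.loc[sel, "gene_A"].to_numpy()
        genes_b = pairs.loc[sel, "gene_B"].to_numpy()
        ids_a = sheet.samples_for(sp_a, "CM")
        ids_b = sheet.samples_for(sp_b, "CM")
        basal_a = expr_A.values.loc[genes_a, ids_a].to_numpy()
        basal_b = expr_B.values.loc[genes_b, ids_b].to_numpy()
        stack_a = np.stack(
            [expr_A.values.loc[genes_a, sheet.samples_for(sp_a, c)].to_numpy()
             for c in HEAT_CONDITIONS]
        )
        stack_b = np.stack(
            [expr_B.values.loc[genes_b, sheet.samples_for(sp_b, c)].to_numpy()
             for c in HEAT_CONDITIONS]
        )
        ext_a = stack_a.max(axis=0) if d == "up" else stack_a.min(axis=0)
        ext_b = stack_b.max(axis=0) if d == "up" else stack_b.min(axis=0)
        ok = (basal_a != 0).all(axis=1) & (basal_b != 0).all(axis=1)
        genes_a, genes_b = genes_a[ok], genes_b[ok]
        basal_a, basal_b = basal_a[ok], basal_b[ok]
        ext_a, ext_b = ext_a[ok], ext_b[ok]
        if not len(genes_a):
            continue
        if paired_denominator:
            den_a, den_b = basal_a, basal_b
        else:
            den_a = basal_a.mean(axis=1, keepdims=True)
            den_b = basal_b.mean(axis=1, keepdims=True)
        pc_a = 100.0 * (ext_a - basal_a) / den_a
        pc_b = 100.0 * (ext_b - basal_b) / den_b
        res = stats.ttest_ind(np.abs(pc_b), np.abs(pc_a), axis=1, equal_var=not welch)
        p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
        diff = np.abs(pc_b).mean(axis=1) - np.abs(pc_a).mean(axis=1)
        verdict = np.where(
            (p <= alpha) & (diff > 0), "higher_in_B",
            np.where((p <= alpha) & (diff < 0), "higher_in_A", "ns"),
        )
        frames.append(
            pd.DataFrame(
                {
                    "gene_A": genes_a,
                    "gene_B": genes_b,
                    "basal_A": basal_a.mean(axis=1),
                    "basal_B": basal_b.mean(axis=1),
                    "percent_change_A": pc_a.mean(axis=1),
                    "percent_change_B": pc_b.mean(axis=1),
                    "direction": d,
                    "p_compare": p,
                    "verdict": verdict,
                }
            )
        )
    columns = [
        "gene_A", "gene_B", "basal_A", "basal_B",
        "percent_change_A", "percent_change_B", "direction", "p_compare",
        "verdict",
    ]
    if not frames:
        return pd.DataFrame(columns=columns)
    return pd.concat(frames, ignore_index=True)[columns]


def global_shift_test(values_A, values_B):
    """Two-sided Wilcoxon rank-sum test.

    Exact enumeration when the smaller sample has <= 8 values and there are
    no cross-sample ties; otherwise the normal approximation with tie
    correction.  Returns (W, p) where W is the rank-sum of the first sample.
    """
    x = np.asarray(values_A, dtype=float)
    y = np.asarray(values_B, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("empty sample in rank-sum test")
    n1 = x.size
    has_ties = np.unique(np.concatenate([x, y])).size < n1 + y.size
    method = "exact" if (min(n1, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic) + n1 * (n1 + 1) / 2.0  # U -> rank-sum W
    return w, float(res.pvalue)


def housekeeping_ratio(
    expr_A: ExpressionMatrix,
    expr_B: ExpressionMatrix,
    sheet: SampleSheet,
    hk_pairs: pd.DataFrame,
):
    """Mean and SD of per-pair basal (CM) expression ratios A / B.

    Expression should be on a linear scale (TPM or normalized counts); a
    ratio near 1 indicates unbiased cross-species levels for genes expected
    to be equally expressed.
    """
    if hk_pairs.empty:
        raise ValidationError("empty housekeeping set")
    ratios = []
    for gene_a, gene_b in hk_pairs[["gene_A", "gene_B"]].itertuples(index=False):
        a = basal_expression(expr_A, sheet, "A", gene_a).mean()
        b = basal_expression(expr_B, sheet, "B", gene_b).mean()
        if b == 0:
            raise ValidationError(f"zero basal expression for {gene_b!r}")
        ratios.append(a / b)
    ratios = np.asarray(ratios)
    return float(ratios.mean()), float(ratios.std(ddof=0))
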