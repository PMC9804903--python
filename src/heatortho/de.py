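"""Negative-binomial differential expression for two-group heat contrasts.

Each heat or recovery condition is tested against its matched control
(HW1M vs CM; HW1N/HW2N/HW3N and R1N vs CN; R2N vs CR2N).  The caller is a
closed-form NB Wald test on size-factor-normalized group means: the
log2 fold-change is the log-ratio of (pseudocounted) group means, its
standard error comes from the delta method under NB variance
Var = mu + alpha * mu^2, and the two-sided p-value from the normal
reference.  The per-gene dispersion alpha is a method-of-moments estimate
pooled across the two groups and floored.  Benjamini-Hochberg adjustment
is applied within each contrast.

The "Union" DEG set collects genes differentially expressed in at least
one of the four heat contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, SampleSheet, ValidationError
from .quantify import normalized_counts, size_factors

#: (name, treatment, control) for the six tested contrasts.
CONTRASTS = (
    ("HW1M_vs_CM", "HW1M", "CM"),
    ("HW1N_vs_CN", "HW1N", "CN"),
    ("HW2N_vs_CN", "HW2N", "CN"),
    ("HW3N_vs_CN", "HW3N", "CN"),
    ("R1N_vs_CN", "R1N", "CN"),
    ("R2N_vs_CR2N", "R2N", "CR2N"),
)

#: Heat contrasts entering the Union DEG set.
HEAT_CONTRASTS = ("HW1M_vs_CM", "HW1N_vs_CN", "HW2N_vs_CN", "HW3N_vs_CN")

DISPERSION_FLOOR = 0.01


@dataclass
class Contrast:
    name: str
    treatment: str
    control: str

    def __post_init__(self) -> None:
        if self.treatment == self.control:
            raise ValidationError("treatment and control conditions must differ")


def estimate_dispersion(*groups, floor: float = DISPERSION_FLOOR) -> float:
    """Method-of-moments NB dispersion, averaged over groups and floored.

    For each group with mean m and variance s2, alpha = max(0, (s2-m)/m^2);
    all-zero groups contribute the floor.
    """
    total = sum(len(g) for g in groups)
    if total < 2:
        raise ValidationError("need at least 2 replicates to estimate dispersion")
    estimates = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        m = g.mean()
        if m <= 0:
            estimates.append(floor)
            continue
        s2 = g.var(ddof=1) if len(g) > 1 else 0.0
        estimates.append(max(0.0, (s2 - m) / m**2))
    return max(floor, float(np.mean(estimates)))


def _dispersion_vector(
    trt: np.ndarray, ctl: np.ndarray, floor: float, moderate: bool = False
) -> np.ndarray:
    """Vectorized per-gene MoM dispersion over two groups (genes x reps).

    With ``moderate=True`` each gene's estimate is raised to at least the
    across-gene mean: per-gene moments at 3 replicates are far too noisy to
    stand alone, and letting a gene's dispersion fall below the pooled
    level makes the Wald test anticonservative.
    """
    est = np.zeros(trt.shape[0])
    for g in (trt, ctl):
        m = g.mean(axis=1)
        s2 = g.var(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            a = np.where(
                m > 0, np.maximum(0.0, (s2 - m) / np.maximum(m, 1e-300) ** 2), floor
            )
        est += a
    est = np.maximum(floor, est / 2)
    if moderate and est.size:
        est = np.maximum(est, est.mean())
    return est


def nb_wald_test(trt, ctl, dispersion, pseudocount: float = 0.5):
    """Closed-form NB Wald test on normalized group means.

    Accepts 1-D replicate vectors (single gene) or 2-D genes x replicate
    arrays; ``dispersion`` scalar or per-gene.  Returns (log2fc, se, p).
    """
    trt = np.atleast_2d(np.asarray(trt, dtype=float))
    ctl = np.atleast_2d(np.asarray(ctl, dtype=float))
    if trt.shape[1] < 2 or ctl.shape[1] < 2:
        raise ValidationError("both groups need >= 2 replicates")
    alpha = np.broadcast_to(np.asarray(dispersion, dtype=float), (trt.shape[0],))
    mt, mc = trt.mean(axis=1), ctl.mean(axis=1)
    lfc = np.log2((mt + pseudocount) / (mc + pseudocount))
    # delta method: Var(log2 mean) ~= (mu + alpha mu^2) / (n mu^2 ln(2)^2)
    ln2sq = np.log(2.0) ** 2
    vt = (mt + alpha * mt**2) / (trt.shape[1] * (mt + pseudocount) ** 2 * ln2sq)
    vc = (mc + alpha * mc**2) / (ctl.shape[1] * (mc + pseudocount) ** 2 * ln2sq)
    se = np.sqrt(vt + vc)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(se > 0, p, 1.0)
    if lfc.shape[0] == 1 and np.ndim(dispersion) == 0:
        return float(lfc[0]), float(se[0]), float(p[0])
    return lfc, se, p


def two_group_test(
    trt,
    ctl,
    pseudocount: float = 0.5,
    dispersion_floor: float = DISPERSION_FLOOR,
):
    """The DE caller's full two-group path: moderated dispersion + Wald.

    ``trt``/``ctl`` are genes x replicates arrays of normalized counts.
    Returns (log2fc, se, p) arrays.
    """
    trt = np.atleast_2d(np.asarray(trt, dtype=float))
    ctl = np.atleast_2d(np.asarray(ctl, dtype=float))
    disp = _dispersion_vector(trt, ctl, dispersion_floor, moderate=True)
    return nb_wald_test(trt, ctl, disp, pseudocount)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_de(
    counts: CountMatrix,
    sheet: SampleSheet,
    species: str,
    alpha_de: float = 0.05,
    lfc_threshold: float = 0.0,
    pseudocount: float = 0.5,
    dispersion_floor: float = DISPERSION_FLOOR,
    contrasts=CONTRASTS,
) -> pd.DataFrame:
    """Test every contrast for one species; returns the full DE table."""
    factors = size_factors(counts)
    norm = normalized_counts(counts, factors).values
    frames = []
    for name, trt_cond, ctl_cond in contrasts:
        trt_ids = sheet.samples_for(species, trt_cond)
        ctl_ids = sheet.samples_for(species, ctl_cond)
        if len(trt_ids) < 2 or len(ctl_ids) < 2:
            raise ValidationError(
                f"contrast {name}: need >= 2 replicates per group for species {species}"
            )
        trt = norm[trt_ids].to_numpy()
        ctl = norm[ctl_ids].to_numpy()
        lfc, se, p = two_group_test(trt, ctl, pseudocount, dispersion_floor)
        untestable = (trt.sum(axis=1) == 0) & (ctl.sum(axis=1) == 0)
        p = np.where(untestable, 1.0, p)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": counts.gene_ids,
                    "contrast": name,
                    "log2fc": lfc,
                    "se": se,
                    "p": p,
                    "q": bh_adjust(p),
                    "untestable": untestable,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return call_degs(table, alpha_de, lfc_threshold)


def call_degs(de_table: pd.DataFrame, alpha_de: float, lfc_threshold: float = 0.0) -> pd.DataFrame:
    """Attach up/down/ns status per gene x contrast (q <= alpha inclusive)."""
    t = de_table.copy()
    sig = (t["q"] <= alpha_de) & ~t.get("untestable", False)
    up = sig & (t["log2fc"] > lfc_threshold)
    down = sig & (t["log2fc"] < -lfc_threshold)
    t["status"] = np.where(up, "up", np.where(down, "down", "ns"))
    return t


def deg_union(de_table: pd.DataFrame, contrasts=HEAT_CONTRASTS) -> set:
    """Genes DE (any direction) in at least one of the listed contrasts."""
    if not len(tuple(contrasts)):
        raise ValidationError("empty contrast list")
    sel = de_table["contrast"].isin(tuple(contrasts)) & (de_table["status"] != "ns")
    return set(de_table.loc[sel, "gene_id"])


def union_status(de_table: pd.DataFrame, contrasts=HEAT_CONTRASTS) -> pd.Series:
    """Signed per-gene status over the heat contrasts.

    A gene's union status is the status of its most significant (smallest q,
    ties by larger |log2fc|) non-ns heat contrast, or "ns" if none.
    """
    t = de_table[de_table["contrast"].isin(tuple(contrasts))].copy()
    genes = t["gene_id"].unique()
    hits = t[t["status"] != "ns"].copy()
    hits = hits.sort_values(
        ["gene_id", "q", "log2fc"],
        ascending=[True, True, False],
        key=lambda s: s.abs() if s.name == "log2fc" else s,
        kind="mergesort",
    )
    best = hits.drop_duplicates("gene_id").set_index("gene_id")["status"]
    return pd.Series(best.reindex(genes, fill_value="ns"), name="status")


def deg_percentages(de_table: pd.DataFrame, n_total_genes: int) -> pd.DataFrame:
    """Per-contrast DEG counts and percentage of all protein-coding genes."""
    rows = []
    for name in de_table["contrast"].unique():
        sub = de_table[de_table["contrast"] == name]
        n_up = int((sub["status"] == "up").sum())
        n_down = int((sub["status"] == "down").sum())
        rows.append((name, n_up, n_down, n_up + n_down,
                     100.0 * (n_up + n_down) / n_total_genes))
    union = deg_union(de_table)
    rows.append(("Union", 0, 0, len(union), 100.0 * len(union) / n_total_genes))
    return pd.DataFrame(
        rows, columns=["contrast", "n_up", "n_down", "n_de", "pct_of_genes"]
    )
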