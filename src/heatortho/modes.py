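"""Five-mode classification of ortholog-pair heat responses.

Each one-to-one ortholog pair is assigned one of the idealized response
modes — shared (up/down), unique to one species, opposite, no response, or
"stress-ready" — from two kinds of evidence:

* per-species DE status over the union of the four heat contrasts
  (up / down / ns), and
* cross-species level-equivalence t-tests on TPM values, comparing one
  species' control level with the other species' extreme (max for
  up-regulation, min for down-regulation) heat level, and the two
  species' control levels with each other.

A pair is "stress-ready" in species X when X does not respond to heat,
the other species Y does, X's control level already equals Y's stressed
extreme (equivalence: p > alpha), and X's control differs from Y's
control (p <= alpha).  The last two gates keep stress-ready distinct from
a mere unique response; both are switchable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import HEAT_CONDITIONS, OrthologMap, SampleSheet, ValidationError
from .quantify import ExpressionMatrix

MODE_NAMES = (
    "stress_ready_A",
    "stress_ready_B",
    "shared_up",
    "shared_down",
    "unique_A",
    "unique_B",
    "opposite",
    "no_response",
    "unassigned",
)


@dataclass
class LevelTest:
    """Two-sample t comparison of replicate TPM levels."""

    t_stat: float
    p: float


def level_equivalence_test(x, y, welch: bool = True) -> LevelTest:
    """Two-sided two-sample t-test; p > alpha is read as 'equal levels'."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("level test needs >= 2 replicates per side")
    if x.std() == 0 and y.std() == 0:
        # degenerate but well-defined: identical constants are equal
        equal = np.allclose(x.mean(), y.mean())
        return LevelTest(0.0 if equal else np.inf, 1.0 if equal else 0.0)
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return LevelTest(float(res.statistic), float(res.pvalue))


def min_max_expression(
    tpm: ExpressionMatrix,
    sheet: SampleSheet,
    species: str,
    gene: str,
    heat_conditions=HEAT_CONDITIONS,
):
    """Per-replicate min and max TPM across the heat conditions.

    Returns (min_values, max_values, min_condition, max_condition); the
    attaining conditions are identified from per-condition replicate means.
    """
    if not len(tuple(heat_conditions)):
        raise ValidationError("heat_conditions must be non-empty")
    if gene not in tpm.values.index:
        raise ValidationError(f"gene not in TPM matrix: {gene!r}")
    cols = {c: sheet.samples_for(species, c) for c in heat_conditions}
    mat = np.array([tpm.values.loc[gene, ids].to_numpy() for c, ids in cols.items()])
    mins = mat.min(axis=0)
    maxs = mat.max(axis=0)
    cond_means = mat.mean(axis=1)
    conds = list(cols)
    return mins, maxs, conds[int(cond_means.argmin())], conds[int(cond_means.argmax())]


def classify_mode(
    status_A: str,
    status_B: str,
    p_ctl_vs_ctl: float | None = None,
    p_ctl_vs_heat: float | None = None,
    alpha: float = 0.05,
    require_control_difference: bool = True,
) -> str:
    """Decision table mapping DE statuses plus level tests to a mode.

    ``p_ctl_vs_heat`` compares the non-responsive species' control level
    with the responsive species' heat extreme; ``p_ctl_vs_ctl`` compares
    the two control levels.  Both are required only on the one-species-
    responsive branch.
    """
    for s in (status_A, status_B):
        if s not in ("up", "down", "ns"):
            raise ValidationError(f"unknown DE status: {s!r}")
    a_resp, b_resp = status_A != "ns", status_B != "ns"
    if a_resp and b_resp:
        if status_A == status_B:
            return "shared_up" if status_A == "up" else "shared_down"
        return "opposite"
    if a_resp or b_resp:
        if p_ctl_vs_heat is None or (require_control_difference and p_ctl_vs_ctl is None):
            raise ValidationError("level tests required for one-responsive pairs")
        level_equal = p_ctl_vs_heat > alpha
        ctl_differ = (p_ctl_vs_ctl is not None) and p_ctl_vs_ctl <= alpha
        if level_equal and (ctl_differ or not require_control_difference):
            return "stress_ready_B" if a_resp else "stress_ready_A"
        return "unique_A" if a_resp else "unique_B"
    return "no_response"


def _control_values(tpm: ExpressionMatrix, sheet: SampleSheet, species: str, genes):
    ids = sheet.samples_for(species, "CM") + sheet.samples_for(species, "CN")
    return tpm.values.loc[genes, ids].to_numpy()


def _extreme_values(
    tpm: ExpressionMatrix, sheet: SampleSheet, species: str, genes, direction: str
):
    cols = [sheet.samples_for(species, c) for c in HEAT_CONDITIONS]
    stack = np.stack([tpm.values.loc[genes, ids].to_numpy() for ids in cols])
    return stack.max(axis=0) if direction == "up" else stack.min(axis=0)


def _vector_t_p(x: np.ndarray, y: np.ndarray, welch: bool) -> np.ndarray:
    if x.shape[0] == 0:
        return np.empty(0)
    res = stats.ttest_ind(x, y, axis=1, equal_var=not welch)
    p = np.asarray(res.pvalue, dtype=float)
    # identical constant rows yield nan; identical constants are 'equal'
    same = (x.std(axis=1) == 0) & (y.std(axis=1) == 0)
    p = np.where(np.isnan(p) & same & np.isclose(x.mean(axis=1), y.mean(axis=1)), 1.0, p)
    p = np.where(np.isnan(p), 0.0, p)
    return p


def classify_pairs(
    orthologs: OrthologMap,
    status_A: pd.Series,
    status_B: pd.Series,
    tpm_A: ExpressionMatrix,
    tpm_B: ExpressionMatrix,
    sheet: SampleSheet,
    alpha_level_test: float = 0.05,
    welch: bool = True,
    require_control_difference: bool = True,
    modules_A: pd.Series | None = None,
    modules_B: pd.Series | None = None,
) -> pd.DataFrame:
    """Classify every ortholog pair; returns the mode-call table.

    Pairs whose genes are missing from the DE statuses or TPM matrices are
    "unassigned".  Optional per-species module labels are carried through
    as a consistency annotation.
    """
    pairs = orthologs.pairs
    n = len(pairs)
    gene_A = pairs["gene_A"].to_numpy()
    gene_B = pairs["gene_B"].to_numpy()

    testable = (
        pd.Series(gene_A).isin(status_A.index).to_numpy()
        & pd.Series(gene_B).isin(status_B.index).to_numpy()
        & pd.Series(gene_A).isin(tpm_A.values.index).to_numpy()
        & pd.Series(gene_B).isin(tpm_B.values.index).to_numpy()
    )
    sA = pd.Series("ns", index=range(n))
    sB = pd.Series("ns", index=range(n))
    sA[testable] = status_A.reindex(gene_A[testable]).to_numpy()
    sB[testable] = status_B.reindex(gene_B[testable]).to_numpy()

    mode = np.full(n, "unassigned", dtype=object)
    p_cc = np.full(n, np.nan)
    p_ch = np.full(n, np.nan)

    a_resp = (sA != "ns").to_numpy() & testable
    b_resp = (sB != "ns").to_numpy() & testable

    both = testable & a_resp & b_resp
    same = both & (sA == sB).to_numpy()
    mode[same & (sA == "up").to_numpy()] = "shared_up"
    mode[same & (sA == "down").to_numpy()] = "shared_down"
    mode[both & ~same] = "opposite"
    mode[testable & ~a_resp & ~b_resp] = "no_response"

    # one-responsive pairs: level tests, grouped by responsive species/direction
    one = testable & (a_resp ^ b_resp)
    if one.any():
        idx = np.where(one)[0]
        ctlA = _control_values(tpm_A, sheet, "A", gene_A[idx])
        ctlB = _control_values(tpm_B, sheet, "B", gene_B[idx])
        p_cc[idx] = _vector_t_p(ctlA, ctlB, welch)
        for resp_species, direction in (
            ("A", "up"), ("A", "down"), ("B", "up"), ("B", "down"),
        ):
            resp_status = sA if resp_species == "A" else sB
            sel = one & (resp_status == direction).to_numpy()
            if resp_species == "A":
                sel &= ~b_resp
            else:
                sel &= ~a_resp
            if not sel.any():
                continue
            j = np.where(sel)[0]
            if resp_species == "A":
                extreme = _extreme_values(tpm_A, sheet, "A", gene_A[j], direction)
                ready_ctl = _control_values(tpm_B, sheet, "B", gene_B[j])
            else:
                extreme = _extreme_values(tpm_B, sheet, "B", gene_B[j], direction)
                ready_ctl = _control_values(tpm_A, sheet, "A", gene_A[j])
            p_ch[j] = _vector_t_p(ready_ctl, extreme, welch)
            level_equal = p_ch[j] > alpha_level_test
            ctl_differ = p_cc[j] <= alpha_level_test
            ready = level_equal & (ctl_differ | (not require_control_difference))
            ready_mode = "stress_ready_B" if resp_species == "A" else "stress_ready_A"
            uniq_mode = "unique_A" if resp_species == "A" else "unique_B"
            mode[j[ready]] = ready_mode
            mode[j[~ready]] = uniq_mode

    out = pd.DataFrame(
        {
            "gene_A": gene_A,
            "gene_B": gene_B,
            "mode": mode,
            "status_A": sA.to_numpy(),
            "status_B": sB.to_numpy(),
            "p_ctl_vs_ctl": p_cc,
            "p_ctl_vs_heat": p_ch,
        }
    )
    if modules_A is not None:
        out["module_A"] = modules_A.reindex(gene_A).to_numpy()
    if modules_B is not None:
        out["module_B"] = modules_B.reindex(gene_B).to_numpy()
    return out


def mode_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per mode over pairs assigned a response mode."""
    assigned = calls[calls["mode"] != "unassigned"]
    if assigned.empty:
        raise ValidationError("no assignable pairs")
    counts = assigned["mode"].value_counts()
    total = int(counts.sum())
    rows = [
        (m, int(counts.get(m, 0)), 100.0 * counts.get(m, 0) / total)
        for m in MODE_NAMES
        if m != "unassigned"
    ]
    rows.append(("unassigned", int((calls["mode"] == "unassigned").sum()), np.nan))
    return pd.DataFrame(rows, columns=["mode", "n_pairs", "pct_of_assigned"])
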