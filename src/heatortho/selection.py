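"""Statistical layer of the branch-site positive-selection screen.

The screen consumes per-ortholog-group log-likelihoods of a nested pair of
codon models (null without positive selection, alternative allowing
foreground omega = dN/dS > 1) as produced by a codeml-style optimizer, plus
the foreground omega estimate and per-site empirical-Bayes posteriors.  It
performs the likelihood-ratio test against a chi-squared reference,
Benjamini-Yekutieli FDR correction (valid under arbitrary dependence), and
calls positively selected genes (PSGs) as q < 0.05 with foreground
omega > 1; selected sites are those with posterior > 0.95.  Codon-model
likelihood optimization itself is out of scope — only summaries enter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ValidationError

NESTING_TOLERANCE = 1e-6


def lrt(lnl_null: float, lnl_alt: float, df: int = 1):
    """Likelihood-ratio statistic max(0, 2*(lnL_alt - lnL_null)) and chi2 p."""
    if df < 1:
        raise ValidationError("df must be >= 1")
    delta = lnl_alt - lnl_null
    if delta < -NESTING_TOLERANCE:
        raise ValidationError(
            f"non-nested likelihoods: lnL_alt ({lnl_alt}) < lnL_null ({lnl_null})"
        )
    stat = max(0.0, 2.0 * delta)
    return stat, float(stats.chi2.sf(stat, df))


def by_adjust(pvals) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values (harmonic-sum penalty)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def screen(records: pd.DataFrame, df_default: int = 1) -> pd.DataFrame:
    """Run LRT + BY over a table with columns ortholog_id, lnL_null, lnL_alt.

    Optional columns: df (per-record degrees of freedom), omega_fg,
    site_posteriors (comma-separated string or list).
    """
    t = records.copy()
    dfs = t["df"] if "df" in t.columns else pd.Series(df_default, index=t.index)
    stats_p = [lrt(r, a, int(d)) for r, a, d in zip(t["lnL_null"], t["lnL_alt"], dfs)]
    t["lrt_stat"] = [s for s, _ in stats_p]
    t["p"] = [p for _, p in stats_p]
    t["q"] = by_adjust(t["p"].to_numpy())
    return t


def _parse_posteriors(value) -> list[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return []
    if isinstance(value, str):
        value = [float(v) for v in value.split(",") if v.strip()]
    return list(value)


def call_psgs(
    records: pd.DataFrame,
    q_cut: float = 0.05,
    omega_gate: float = 1.0,
    site_posterior_gate: float = 0.95,
) -> pd.DataFrame:
    """Flag PSGs: q < q_cut AND foreground omega > omega_gate.

    q-passing records without an omega estimate are excluded and flagged.
    Selected sites (posterior > gate) are reported as 0-based indices.
    """
    t = records.copy()
    if "q" not in t.columns:
        raise ValidationError("records need a q column; run screen() first")
    omega = t["omega_fg"] if "omega_fg" in t.columns else pd.Series(np.nan, index=t.index)
    q_pass = t["q"] < q_cut
    missing = q_pass & omega.isna()
    t["flag"] = np.where(missing, "missing_omega", "")
    t["psg"] = q_pass & (omega > omega_gate) & ~missing
    sites = []
    for i, row in t.iterrows():
        if t.loc[i, "psg"]:
            post = _parse_posteriors(row.get("site_posteriors"))
            sites.append(
                ",".join(str(j) for j, pp in enumerate(post) if pp > site_posterior_gate)
            )
        else:
            sites.append("")
    t["selected_sites"] = sites
    return t


def simulate_lrt_null(
    n: int,
    df: int = 1,
    mixture_weight_point_mass: float = 0.0,
    seed: int = 0,
    noncentrality: float = 0.0,
    frac_alternative: float = 0.0,
) -> pd.DataFrame:
    """Synthetic selection records with a known null/alternative split.

    Null statistics follow chi2_df, optionally mixed with a point mass at
    zero (the boundary case of branch-site practice); alternative records
    (fraction ``frac_alternative``) draw a noncentral chi2 and get a
    foreground omega > 1.  Log-likelihood pairs are reconstructed so that
    2*(lnL_alt - lnL_null) equals the drawn statistic.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not 0 <= mixture_weight_point_mass <= 1:
        raise ValidationError("mixture weight must be in [0, 1]")
    rng = np.random.default_rng(seed)
    is_alt = rng.random(n) < frac_alternative
    stat = rng.chisquare(df, size=n)
    at_zero = rng.random(n) < mixture_weight_point_mass
    stat = np.where(at_zero, 0.0, stat)
    if is_alt.any():
        stat[is_alt] = rng.noncentral_chisquare(df, noncentrality, size=int(is_alt.sum()))
    lnl_null = -2000.0 - rng.random(n) * 100.0
    omega = np.where(is_alt, 1.0 + rng.gamma(2.0, 1.0, size=n), rng.uniform(0.05, 1.0, n))
    return pd.DataFrame(
        {
            "ortholog_id": [f"og{i:05d}" for i in range(n)],
            "lnL_null": lnl_null,
            "lnL_alt": lnl_null + stat / 2.0,
            "df": df,
            "omega_fg": omega,
            "is_alternative": is_alt,
        }
    )


def read_selection_records(path) -> pd.DataFrame:
    """Read a flat TSV of codeml-style summaries (permissive on extras)."""
    t = pd.read_csv(path, sep="\t")
    required = {"ortholog_id", "lnL_null", "lnL_alt"}
    missing = required - set(t.columns)
    if missing:
        raise ValidationError(f"selection table missing columns: {sorted(missing)}")
    return t
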