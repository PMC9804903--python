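"""Two-species negative-binomial count simulator with known response modes.

The simulated experiment mirrors a three-day heat-wave design on two related
plant species: nine conditions (controls CM/CN/CR2N, heat waves HW1M, HW1N,
HW2N, HW3N, recovery R1N/R2N) with three biological replicates each, per
species.  Every ortholog pair draws one baseline mean shared by both species
and is assigned a ground-truth response mode that determines per-condition
expected means:

* ``shared_up`` / ``shared_down`` — both orthologs respond to heat with the
  same sign (|log2FC| = ``effect_lfc``).
* ``unique_A`` / ``unique_B`` — only the named species responds.
* ``opposite`` — the two orthologs respond with opposite signs.
* ``no_response`` — neither responds.
* ``stress_ready_A`` / ``stress_ready_B`` — the named species sits
  constitutively at the level the *other* species only reaches under heat
  (offset ``stress_ready_offset_lfc``) and does not itself respond; the
  other species is heat-responsive.

Heat effects apply to the four heat-wave conditions; recovery conditions
revert to baseline, emulating transcriptomes that return to the pre-stress
state.  Counts are drawn NB(mean, dispersion) with Var = mu + alpha * mu^2,
after multiplying means by per-sample library size factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    CONDITIONS,
    HEAT_CONDITIONS,
    CountMatrix,
    GeneLengths,
    OrthologMap,
    SampleSheet,
    ValidationError,
)

MODES = (
    "stress_ready_A",
    "stress_ready_B",
    "shared_up",
    "shared_down",
    "unique_A",
    "unique_B",
    "opposite",
    "no_response",
)

#: Mode frequencies of the size reported for Arabidopsis/Anastatica heat
#: studies: 82% shared, 4.5% stress-ready in the extremophyte (species B),
#: 1.9% in the mesophyte (species A), ~5% unique, 2.1% opposite, 4.4% none.
OBSERVED_MODE_PROPORTIONS = {
    "shared_up": 0.41,
    "shared_down": 0.41,
    "stress_ready_B": 0.045,
    "stress_ready_A": 0.019,
    "unique_A": 0.025,
    "unique_B": 0.025,
    "opposite": 0.021,
    "no_response": 0.044,
}


def expand_mode_proportions(proportions: dict) -> dict:
    """Expand aggregate keys (``shared``, ``unique``) into the full mode set."""
    out: dict[str, float] = {}
    for key, p in proportions.items():
        if key == "shared":
            out["shared_up"] = out.get("shared_up", 0.0) + p / 2
            out["shared_down"] = out.get("shared_down", 0.0) + p / 2
        elif key == "unique":
            out["unique_A"] = out.get("unique_A", 0.0) + p / 2
            out["unique_B"] = out.get("unique_B", 0.0) + p / 2
        elif key in MODES:
            out[key] = out.get(key, 0.0) + p
        else:
            raise ValidationError(f"unknown mode: {key!r}")
    return out


@dataclass
class SimulationConfig:
    n_orthologs: int = 5000
    mode_proportions: dict = field(
        default_factory=lambda: dict(OBSERVED_MODE_PROPORTIONS)
    )
    base_mean_log_range: tuple = (3.0, 11.0)  # log2 scale
    effect_lfc: float = 2.0
    stress_ready_offset_lfc: float = 2.0
    #: multiplier on species B's heat fold-changes (shared/unique/opposite
    #: modes), for simulating a species whose responsive genes react more
    #: strongly than their orthologs (1.0 = symmetric species)
    effect_lfc_scale_B: float = 1.0
    dispersion: float = 0.05
    dispersion_jitter: float = 0.0  # gamma CV of per-gene dispersions; 0 = global
    #: probability that a responsive gene responds in each individual heat
    #: condition (>= 1 condition always responds).  Real heat-wave series
    #: mix early- and late-response genes, so most genes respond in only a
    #: subset of samplings; modelling this also keeps the per-sample
    #: fraction of shifted genes below the breakdown point of
    #: median-of-ratios normalization, as on real data.
    heat_response_prob: float = 0.75
    library_size_factors: dict | None = None  # sample_id -> factor
    n_replicates: int = 3
    gene_length_range: tuple = (500, 5000)
    #: relative length difference between the two orthologs of a pair
    #: (uniform +/- this fraction).  Orthologous transcripts are nearly
    #: length-conserved, which is what licenses direct cross-species TPM
    #: comparison; the jitter keeps the two length files genuinely
    #: different so length correction is still exercised.
    ortholog_length_jitter: float = 0.10
    stress_ready_down: bool = False  # down-regulation polarity variant
    seed: int = 0

    def __post_init__(self) -> None:
        self.mode_proportions = expand_mode_proportions(self.mode_proportions)
        total = sum(self.mode_proportions.values())
        # published mode tables are rounded percentages; renormalize small
        # rounding slack but reject anything grossly off
        if abs(total - 1.0) > 5e-3:
            raise ValidationError(f"mode_proportions sum to {total}, not 1")
        self.mode_proportions = {k: v / total for k, v in self.mode_proportions.items()}
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if self.base_mean_log_range[0] > self.base_mean_log_range[1]:
            raise ValidationError("base_mean_log_range must be ordered")
        if self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValidationError("gene_length_range must be ordered")
        if self.n_replicates < 2:
            raise ValidationError("need at least 2 replicates")


@dataclass
class SimulatedExperiment:
    counts_A: CountMatrix
    counts_B: CountMatrix
    lengths_A: GeneLengths
    lengths_B: GeneLengths
    orthologs: OrthologMap
    sample_sheet: SampleSheet
    truth: pd.DataFrame  # pair_id, gene_A, gene_B, true_mode, true_lfc_A/B, base_mean
    mean_A: pd.DataFrame  # expected means per sample (diagnostics / oracles)
    mean_B: pd.DataFrame


def sample_nb_counts(mean, dispersion: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` NB counts with Var = mean + dispersion * mean^2.

    ``dispersion == 0`` degenerates to Poisson.  ``mean`` may be a scalar or
    an array broadcastable against ``n`` draws.
    """
    mean = np.asarray(mean, dtype=float)
    if np.any(mean <= 0):
        raise ValidationError("NB mean must be positive")
    if dispersion < 0:
        raise ValidationError("NB dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mean, size=n if mean.ndim == 0 else None)
    size = 1.0 / dispersion  # NB number-of-successes parameter
    p = size / (size + mean)
    return rng.negative_binomial(size, p, size=n if mean.ndim == 0 else None)


def _mode_multipliers(mode: str, cfg: SimulationConfig, sign: float):
    """Per-species (constitutive_log2_offset_A, heat_lfc_A, offset_B, lfc_B).

    ``sign`` carries the per-gene polarity of unique/opposite responses
    (randomized so neither species' transcriptome shifts predominantly one
    way, which would defeat median-of-ratios normalization — as it would on
    real data).  Stress-ready polarity is a global switch: constitutively
    high by default, constitutively low with ``stress_ready_down``.
    """
    e = cfg.effect_lfc
    off = cfg.stress_ready_offset_lfc
    sr = -1.0 if cfg.stress_ready_down else 1.0
    eb = e * cfg.effect_lfc_scale_B
    table = {
        "shared_up": (0.0, e, 0.0, eb),
        "shared_down": (0.0, -e, 0.0, -eb),
        "unique_A": (0.0, sign * e, 0.0, 0.0),
        "unique_B": (0.0, 0.0, 0.0, sign * eb),
        "opposite": (0.0, sign * e, 0.0, -sign * eb),
        "no_response": (0.0, 0.0, 0.0, 0.0),
        # the responsive species' heat level must reach the ready species'
        # constitutive level, so its fold-change equals the offset
        "stress_ready_A": (sr * off, 0.0, 0.0, sr * off),
        "stress_ready_B": (0.0, sr * off, sr * off, 0.0),
    }
    return table[mode]


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate paired two-species count matrices with ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_orthologs

    genes_A = [f"gA{i:05d}" for i in range(n)]
    genes_B = [f"gB{i:05d}" for i in range(n)]

    modes = list(config.mode_proportions)
    probs = np.array([config.mode_proportions[m] for m in modes])
    mode_idx = rng.choice(len(modes), size=n, p=probs)
    true_modes = [modes[i] for i in mode_idx]

    lo, hi = config.base_mean_log_range
    base_mean = 2.0 ** rng.uniform(lo, hi, size=n)

    # sample layout (identical replicate structure in both species)
    rows = []
    for sp in ("A", "B"):
        for cond in CONDITIONS:
            for rep in range(1, config.n_replicates + 1):
                rows.append((f"{sp}_{cond}_{rep}", sp, cond, rep))
    sheet = SampleSheet(
        pd.DataFrame(rows, columns=["sample_id", "species", "condition", "replicate"])
    )

    heat = set(HEAT_CONDITIONS)
    signs = rng.choice([-1.0, 1.0], size=n)
    offsets = np.array(
        [_mode_multipliers(m, config, s) for m, s in zip(true_modes, signs)]
    )
    const_A, lfc_A, const_B, lfc_B = offsets.T

    def response_indicators() -> np.ndarray:
        ind = rng.random((n, len(HEAT_CONDITIONS))) < config.heat_response_prob
        silent = ~ind.any(axis=1)
        ind[silent, rng.integers(0, len(HEAT_CONDITIONS), size=int(silent.sum()))] = True
        return ind.astype(float)

    resp = {"A": response_indicators(), "B": response_indicators()}

    # per-gene dispersions (optional gamma jitter around the global value)
    if config.dispersion_jitter > 0 and config.dispersion > 0:
        cv = config.dispersion_jitter
        shape = 1.0 / cv**2
        disp = rng.gamma(shape, config.dispersion / shape, size=n)
    else:
        disp = np.full(n, config.dispersion)

    sf = config.library_size_factors or {}

    def build_species(sp: str, const_off: np.ndarray, lfc: np.ndarray):
        cols, mean_cols, ids = [], [], []
        for cond in CONDITIONS:
            if cond in heat:
                cond_lfc = lfc * resp[sp][:, HEAT_CONDITIONS.index(cond)]
            else:
                cond_lfc = np.zeros(n)
            mu = base_mean * 2.0 ** (const_off + cond_lfc)
            for rep in range(1, config.n_replicates + 1):
                sid = f"{sp}_{cond}_{rep}"
                factor = float(sf.get(sid, 1.0))
                mu_s = mu * factor
                if config.dispersion == 0 and config.dispersion_jitter == 0:
                    draws = rng.poisson(mu_s)
                else:
                    size = 1.0 / np.maximum(disp, 1e-12)
                    p = size / (size + mu_s)
                    draws = rng.negative_binomial(size, p)
                cols.append(draws)
                mean_cols.append(mu_s)
                ids.append(sid)
        genes = genes_A if sp == "A" else genes_B
        counts = pd.DataFrame(np.column_stack(cols), index=genes, columns=ids)
        means = pd.DataFrame(np.column_stack(mean_cols), index=genes, columns=ids)
        return CountMatrix(counts), means

    counts_A, mean_A = build_species("A", const_A, lfc_A)
    counts_B, mean_B = build_species("B", const_B, lfc_B)

    lmin, lmax = config.gene_length_range
    len_a = rng.integers(lmin, lmax + 1, size=n)
    jitter = rng.uniform(
        1.0 - config.ortholog_length_jitter, 1.0 + config.ortholog_length_jitter, size=n
    )
    len_b = np.maximum(1, np.round(len_a * jitter)).astype(np.int64)
    lengths_A = GeneLengths(pd.Series(len_a, index=genes_A))
    lengths_B = GeneLengths(pd.Series(len_b, index=genes_B))

    truth = pd.DataFrame(
        {
            "pair_id": [f"pair{i:05d}" for i in range(n)],
            "gene_A": genes_A,
            "gene_B": genes_B,
            "true_mode": true_modes,
            "true_lfc_A": lfc_A,
            "true_lfc_B": lfc_B,
            "const_offset_A": const_A,
            "const_offset_B": const_B,
            "base_mean": base_mean,
            "resp_conditions_A": [
                ",".join(c for c, f in zip(HEAT_CONDITIONS, row) if f and l != 0)
                for row, l in zip(resp["A"], lfc_A)
            ],
            "resp_conditions_B": [
                ",".join(c for c, f in zip(HEAT_CONDITIONS, row) if f and l != 0)
                for row, l in zip(resp["B"], lfc_B)
            ],
        }
    )

    orthologs = OrthologMap(pd.DataFrame({"gene_A": genes_A, "gene_B": genes_B}))
    return SimulatedExperiment(
        counts_A, counts_B, lengths_A, lengths_B, orthologs, sheet, truth,
        mean_A, mean_B,
    )
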