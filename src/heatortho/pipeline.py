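"""End-to-end orchestration: simulate/load -> normalize -> DE -> modules ->
mode classification -> reactivity -> selection screen.

Every stage writes its table under the run directory with a fixed name, and
a machine-readable ``summary.json`` collects the headline quantities
(per-contrast DEG percentages, mode proportions, reactive-set size, PSG
count).  Runs are fully deterministic: one global seed fans out to
per-stage child seeds through a stage-name hash, so adding a stage never
perturbs the draws of earlier stages, and all outputs are byte-stable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import coexpr as coexpr_mod
from . import de as de_mod
from . import modes as modes_mod
from . import reactivity as react_mod
from . import selection as sel_mod
from .io import (
    CountMatrix,
    GeneLengths,
    OrthologMap,
    RunConfig,
    SampleSheet,
    read_counts,
    read_lengths,
    read_orthologs,
    read_sample_sheet,
    write_counts,
    write_table,
)
from .quantify import normalized_counts, rlog_like, size_factors, tpm
from .simulate import SimulatedExperiment, SimulationConfig, simulate_experiment

INPUT_FILES = {
    "counts_A": "counts_A.tsv",
    "counts_B": "counts_B.tsv",
    "lengths_A": "lengths_A.tsv",
    "lengths_B": "lengths_B.tsv",
    "orthologs": "orthologs.tsv",
    "samples": "samples.tsv",
}


def child_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed (stable, < 2^31)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunReport:
    config_hash: str
    seed: int
    deg_percentages: dict
    mode_counts: dict
    mode_percentages: dict
    n_reactive_higher_in_B: int
    n_psg: int
    n_orthologs: int
    housekeeping_ratio: dict
    warnings: list

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True, indent=2) + "\n"


def write_experiment(exp: SimulatedExperiment, outdir) -> None:
    """Write a simulated experiment as the pipeline's input tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts(exp.counts_A, outdir / INPUT_FILES["counts_A"])
    write_counts(exp.counts_B, outdir / INPUT_FILES["counts_B"])
    for sp, gl in (("A", exp.lengths_A), ("B", exp.lengths_B)):
        t = gl.lengths.rename("length_bp").rename_axis("gene_id").reset_index()
        write_table(t, outdir / INPUT_FILES[f"lengths_{sp}"])
    write_table(exp.orthologs.pairs, outdir / INPUT_FILES["orthologs"])
    write_table(exp.sample_sheet.table, outdir / INPUT_FILES["samples"])
    write_table(exp.truth, outdir / "truth.tsv")


def load_inputs(indir):
    indir = Path(indir)
    for key, name in INPUT_FILES.items():
        if not (indir / name).exists():
            raise FileNotFoundError(f"missing input file: {indir / name}")
    return (
        read_counts(indir / INPUT_FILES["counts_A"]),
        read_counts(indir / INPUT_FILES["counts_B"]),
        read_lengths(indir / INPUT_FILES["lengths_A"]),
        read_lengths(indir / INPUT_FILES["lengths_B"]),
        read_orthologs(indir / INPUT_FILES["orthologs"]),
        read_sample_sheet(indir / INPUT_FILES["samples"]),
    )


def run_pipeline(
    config: RunConfig,
    outdir,
    sim_config: SimulationConfig | None = None,
    inputs_dir=None,
    selection_records: pd.DataFrame | None = None,
    run_coexpr: bool = True,
) -> RunReport:
    """Execute every stage and write all outputs under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    # ---- inputs -----------------------------------------------------------
    if inputs_dir is not None:
        counts_A, counts_B, lengths_A, lengths_B, orthologs, sheet = load_inputs(inputs_dir)
    else:
        if sim_config is None:
            sim_config = SimulationConfig(seed=child_seed(config.seed, "simulate"))
        exp = simulate_experiment(sim_config)
        write_experiment(exp, outdir)
        counts_A, counts_B = exp.counts_A, exp.counts_B
        lengths_A, lengths_B = exp.lengths_A, exp.lengths_B
        orthologs, sheet = exp.orthologs, exp.sample_sheet

    # ---- quantify ---------------------------------------------------------
    expr = {}
    for sp, counts, lengths in (("A", counts_A, lengths_A), ("B", counts_B, lengths_B)):
        factors = size_factors(counts)
        expr[sp] = {
            "factors": factors,
            "tpm": tpm(counts, lengths),
            "rlog": rlog_like(counts, factors, config.pseudocount),
            "counts": counts,
        }
        write_table(
            factors.rename("size_factor").rename_axis("sample_id").reset_index(),
            outdir / f"size_factors_{sp}.tsv",
        )

    # ---- differential expression -----------------------------------------
    de_tables, union_status = {}, {}
    deg_pct = {}
    for sp in ("A", "B"):
        table = de_mod.run_de(
            expr[sp]["counts"], sheet, sp,
            alpha_de=config.alpha_de,
            lfc_threshold=config.lfc_threshold,
            pseudocount=config.de_pseudocount,
            dispersion_floor=config.dispersion_floor,
        )
        de_tables[sp] = table
        union_status[sp] = de_mod.union_status(table)
        write_table(table, outdir / f"de_results_{sp}.tsv")
        pct = de_mod.deg_percentages(table, len(expr[sp]["counts"].gene_ids))
        write_table(pct, outdir / f"deg_summary_{sp}.tsv")
        deg_pct[sp] = {
            row.contrast: round(row.pct_of_genes, 4) for row in pct.itertuples()
        }

    # ---- co-expression modules -------------------------------------------
    module_labels = {"A": None, "B": None}
    if run_coexpr:
        for sp in ("A", "B"):
            assignment = coexpr_mod.detect_modules(
                expr[sp]["rlog"],
                power_grid=config.soft_power_grid,
                r2_target=config.scale_free_r2_target,
                signed=config.signed_network,
                min_module_size=config.min_module_size,
                cut_height_fraction=config.cut_height_fraction,
                merge_corr_threshold=config.merge_corr_threshold,
                max_genes=config.coexpr_max_genes,
            )
            module_labels[sp] = assignment.labels
            write_table(
                assignment.labels.rename("module").rename_axis("gene_id").reset_index(),
                outdir / f"modules_{sp}.tsv",
            )

    # ---- mode classification ---------------------------------------------
    calls = modes_mod.classify_pairs(
        orthologs,
        union_status["A"],
        union_status["B"],
        expr["A"]["tpm"],
        expr["B"]["tpm"],
        sheet,
        alpha_level_test=config.alpha_level_test,
        welch=config.welch,
        require_control_difference=config.require_nonresponsive_ready,
        modules_A=module_labels["A"],
        modules_B=module_labels["B"],
    )
    write_table(calls, outdir / "mode_calls.tsv")
    summary = modes_mod.mode_summary(calls)
    write_table(summary, outdir / "mode_summary.tsv")
    mode_counts = dict(zip(summary["mode"], summary["n_pairs"].astype(int)))
    mode_pct = {
        m: round(p, 4)
        for m, p in zip(summary["mode"], summary["pct_of_assigned"])
        if m != "unassigned"
    }

    # ---- reactivity -------------------------------------------------------
    status_a = calls.set_index("gene_A")["status_A"]
    status_b = calls.set_index("gene_A")["status_B"]
    direction = status_a.where(status_a != "ns", status_b)
    react_expr = "rlog" if config.percent_change_scale == "rlog" else "tpm"
    react = react_mod.compare_reactivity(
        orthologs, expr["A"][react_expr], expr["B"][react_expr], sheet,
        direction, alpha=config.alpha_de, welch=config.welch,
    )
    write_table(react, outdir / "reactivity.tsv")
    n_reactive = int((react["verdict"] == "higher_in_B").sum())

    hk = calls.loc[calls["mode"] == "no_response", ["gene_A", "gene_B"]]
    hk = hk.sort_values("gene_A", kind="mergesort").head(15)
    hk_summary = {}
    if len(hk):
        mean_ratio, sd_ratio = react_mod.housekeeping_ratio(
            normalized_counts(counts_A, expr["A"]["factors"]),
            normalized_counts(counts_B, expr["B"]["factors"]),
            sheet, hk,
        )
        hk_summary = {"mean": round(mean_ratio, 4), "sd": round(sd_ratio, 4)}
    else:
        warnings.append("no non-responsive pairs for the housekeeping control")

    # ---- selection screen -------------------------------------------------
    if selection_records is None:
        selection_records = sel_mod.simulate_lrt_null(
            n=1000, df=1, seed=child_seed(config.seed, "selection"),
            frac_alternative=0.1, noncentrality=15.0,
        )
    screened = sel_mod.screen(selection_records)
    psg = sel_mod.call_psgs(screened)
    write_table(psg, outdir / "psg_calls.tsv")
    n_psg = int(psg["psg"].sum())

    report = RunReport(
        config_hash=config.config_hash(),
        seed=config.seed,
        deg_percentages=deg_pct,
        mode_counts=mode_counts,
        mode_percentages=mode_pct,
        n_reactive_higher_in_B=n_reactive,
        n_psg=n_psg,
        n_orthologs=len(orthologs),
        housekeeping_ratio=hk_summary,
        warnings=warnings,
    )
    (outdir / "summary.json").write_text(report.to_json())
    (outdir / "run_log.txt").write_text(
        f"seed={config.seed}\nconfig_hash={config.config_hash()}\n"
        + "".join(f"warning: {w}\n" for w in warnings)
    )
    return report
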