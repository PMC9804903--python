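"""Tabular input/output, validation and run configuration.

All pipeline tables are tab-separated UTF-8 text with a header row and '.'
as the decimal separator.  The condition vocabulary is closed: two controls
(CM morning, CN afternoon), four heat-wave samplings (HW1M, HW1N, HW2N,
HW3N), two recovery samplings (R1N, R2N) and the recovery-matched control
CR2N.  Unknown condition codes are hard errors so that contrasts can never
be silently misassigned.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("heatortho")

#: Closed vocabulary of experimental conditions.
CONDITIONS = ("CM", "CN", "HW1M", "HW1N", "HW2N", "HW3N", "R1N", "CR2N", "R2N")

#: Conditions counted as "heat" for the DEG union and extreme-level logic.
HEAT_CONDITIONS = ("HW1M", "HW1N", "HW2N", "HW3N")

#: Control condition matched to each non-control condition.
MATCHED_CONTROL = {
    "HW1M": "CM",
    "HW1N": "CN",
    "HW2N": "CN",
    "HW3N": "CN",
    "R1N": "CN",
    "R2N": "CR2N",
}

SPECIES = ("A", "B")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class CountMatrix:
    """Integer gene x sample read counts for a single species."""

    counts: pd.DataFrame  # index: gene ids, columns: sample ids, dtype int

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise ValidationError("non-integer count")
            self.counts = df.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            gene = df.index[np.where(values < 0)[0][0]]
            raise ValidationError(f"negative count for gene {gene!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy()


@dataclass
class SampleSheet:
    """Maps each sample id to (species, condition, replicate)."""

    table: pd.DataFrame  # columns: sample_id, species, condition, replicate

    def __post_init__(self) -> None:
        t = self.table
        required = {"sample_id", "species", "condition", "replicate"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
        bad = set(t["condition"]) - set(CONDITIONS)
        if bad:
            raise ValidationError(f"unknown condition: {sorted(bad)}")
        bad_sp = set(t["species"]) - set(SPECIES)
        if bad_sp:
            raise ValidationError(f"unknown species: {sorted(bad_sp)}")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        key = t[["species", "condition", "replicate"]].apply(tuple, axis=1)
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValidationError(f"duplicate replicate: {dup}")
        if (t["replicate"].astype(int) < 1).any():
            raise ValidationError("replicate index must be >= 1")
        self.table = t.reset_index(drop=True)

    def samples_for(self, species: str, condition: str) -> list[str]:
        t = self.table
        sel = (t["species"] == species) & (t["condition"] == condition)
        sub = t.loc[sel].sort_values("replicate")
        return list(sub["sample_id"])

    def species_samples(self, species: str) -> list[str]:
        t = self.table
        return list(t.loc[t["species"] == species, "sample_id"])


@dataclass
class OrthologMap:
    """One-to-one ortholog pairs between species A and B."""

    pairs: pd.DataFrame  # columns: gene_A, gene_B

    def __post_init__(self) -> None:
        p = self.pairs
        if not {"gene_A", "gene_B"} <= set(p.columns):
            raise ValidationError("ortholog map needs columns gene_A, gene_B")
        for col in ("gene_A", "gene_B"):
            if p[col].duplicated().any():
                dup = p.loc[p[col].duplicated(), col].iloc[0]
                raise ValidationError(f"gene in multiple pairs: {dup!r}")
        self.pairs = p.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class GeneLengths:
    """Per-gene transcript lengths in base pairs (for TPM)."""

    lengths: pd.Series  # index gene_id, values int bp

    def __post_init__(self) -> None:
        if (self.lengths < 1).any():
            gene = self.lengths.index[np.where(self.lengths < 1)[0][0]]
            raise ValidationError(f"non-positive length for gene {gene!r}")

    def covers(self, gene_ids) -> bool:
        return set(gene_ids) <= set(self.lengths.index)


@dataclass
class RunConfig:
    """All thresholds and knobs of a pipeline run, serialisable to YAML."""

    alpha_de: float = 0.05
    alpha_level_test: float = 0.05
    lfc_threshold: float = 0.0
    pseudocount: float = 1.0
    de_pseudocount: float = 0.5
    dispersion_floor: float = 0.01
    soft_power_grid: tuple = (1, 2, 3, 4, 5, 6, 8, 10, 12, 14, 16)
    scale_free_r2_target: float = 0.8
    min_module_size: int = 30
    merge_corr_threshold: float = 0.85
    cut_height_fraction: float | None = None  # None = largest-gap static cut
    signed_network: bool = False
    coexpr_max_genes: int = 1000
    welch: bool = True
    require_nonresponsive_ready: bool = True
    percent_change_scale: str = "rlog"  # or "linear"
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("alpha_de", "alpha_level_test"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if self.lfc_threshold < 0:
            raise ValidationError("lfc_threshold must be non-negative")
        if self.pseudocount <= 0 or self.de_pseudocount <= 0:
            raise ValidationError("pseudocounts must be positive")
        if not 0 < self.scale_free_r2_target < 1:
            raise ValidationError("scale_free_r2_target must be in (0, 1)")
        if not 0 < self.merge_corr_threshold < 1:
            raise ValidationError("merge_corr_threshold must be in (0, 1)")
        if self.min_module_size < 1:
            raise ValidationError("min_module_size must be positive")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["soft_power_grid"] = list(self.soft_power_grid)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "soft_power_grid" in d:
            d["soft_power_grid"] = tuple(d["soft_power_grid"])
        return cls(**d)

    def config_hash(self) -> str:
        d = asdict(self)
        d["soft_power_grid"] = list(self.soft_power_grid)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(path) -> CountMatrix:
    """Read a genes x samples TSV of integer read counts."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"counts file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric count in {path}: {exc}") from exc
    if not np.all(np.equal(np.mod(values, 1), 0)):
        raise ValidationError(f"non-integer count in {path}")
    if (values < 0).any():
        raise ValidationError(f"negative count in {path}")
    return CountMatrix(df.astype(np.int64))


def read_sample_sheet(path) -> SampleSheet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sample sheet not found: {path}")
    t = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "species": str, "condition": str})
    sheet = SampleSheet(t)
    counts = sheet.table.groupby(["species", "condition"]).size()
    logger.info("sample sheet: %d samples, replicates per group: %s",
                len(sheet.table), counts.to_dict())
    return sheet


def read_orthologs(path) -> OrthologMap:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ortholog map not found: {path}")
    return OrthologMap(pd.read_csv(path, sep="\t", dtype=str))


def read_lengths(path) -> GeneLengths:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"lengths file not found: {path}")
    t = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if not {"gene_id", "length_bp"} <= set(t.columns):
        raise ValidationError("lengths file needs columns gene_id, length_bp")
    s = t.set_index("gene_id")["length_bp"].astype(np.int64)
    return GeneLengths(s)


def write_table(records: pd.DataFrame, path) -> None:
    """Write a TSV deterministically: sorted by the first column, 10-digit floats.

    Read-back with :func:`pandas.read_csv` reproduces the table, and two
    writes of the same table are byte-identical.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = records.copy()
    if len(df) and len(df.columns):
        df = df.sort_values(df.columns[0], kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def write_counts(cm: CountMatrix, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = cm.counts.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", lineterminator="\n")
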