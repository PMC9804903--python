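"""Normalization: TPM, median-of-ratios size factors and a log transform.

TPM (transcripts per kilobase million) divides each gene's counts by its
length in kilobases and rescales every sample to one million, making
absolute levels comparable across genes and samples within a species.
Size factors follow the median-of-ratios construction: each sample's
factor is the median, over genes expressed in every sample, of the ratio
of its count to the gene's geometric-mean reference.  The log transform is
log2(count / size_factor + pseudocount) — a monotone, variance-taming
stand-in for a regularized log, adequate for the rank- and mean-based
statistics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneLengths, ValidationError


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame  # genes x samples
    kind: str  # "TPM" | "normalized_counts" | "rlog"

    def __post_init__(self) -> None:
        if self.kind not in ("TPM", "normalized_counts", "rlog"):
            raise ValidationError(f"unknown expression kind: {self.kind!r}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("non-finite expression value")


def tpm(counts: CountMatrix, lengths: GeneLengths) -> ExpressionMatrix:
    """Length-normalized expression; every column sums to 1e6."""
    if not lengths.covers(counts.gene_ids):
        missing = set(counts.gene_ids) - set(lengths.lengths.index)
        raise ValidationError(f"lengths missing for genes: {sorted(missing)[:3]}")
    kb = lengths.lengths.reindex(counts.gene_ids).to_numpy() / 1e3
    rate = counts.values / kb[:, None]
    colsum = rate.sum(axis=0)
    zero = np.where(colsum == 0)[0]
    if zero.size:
        raise ValidationError(
            f"all-zero sample, TPM undefined: {counts.sample_ids[zero[0]]!r}"
        )
    vals = rate / colsum * 1e6
    return ExpressionMatrix(
        pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids), "TPM"
    )


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference)."""
    vals = counts.values.astype(float)
    if vals.shape[1] == 1:
        return pd.Series([1.0], index=counts.sample_ids)
    expressed = (vals > 0).all(axis=1)
    if not expressed.any():
        raise ValidationError("no gene expressed in all samples; size factors undefined")
    log_ref = np.log(vals[expressed]).mean(axis=1)
    ratios = np.log(vals[expressed]) - log_ref[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.sample_ids)


def normalized_counts(counts: CountMatrix, factors: pd.Series) -> ExpressionMatrix:
    f = factors.reindex(counts.sample_ids).to_numpy()
    if np.any(f <= 0) or np.any(~np.isfinite(f)):
        raise ValidationError("size factors must be positive and finite")
    vals = counts.values / f
    return ExpressionMatrix(
        pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids),
        "normalized_counts",
    )


def rlog_like(counts: CountMatrix, factors: pd.Series, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(normalized count + pseudocount); monotone in counts, finite."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    norm = normalized_counts(counts, factors)
    vals = np.log2(norm.values.to_numpy() + pseudocount)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids), "rlog"
    )
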