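"""Intensity-to-beta conversion, probe QC, blacklisting, quantile normalization.

Consumes matrices (probes x samples); raw IDAT parsing is out of scope.
Beta values follow the standard offset formula beta = M / (M + U + 100):
the +100 regularizer keeps low-intensity probes away from the extremes, so
finite intensities can never produce beta = 1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "compute_beta",
    "detection_filter",
    "drop_blacklisted",
    "quantile_normalize",
    "read_annotation",
]


def compute_beta(
    methylated: pd.DataFrame, unmethylated: pd.DataFrame, offset: float = 100.0
) -> pd.DataFrame:
    """Element-wise beta = M / (M + U + offset).

    Both matrices are probes x samples with non-negative entries; output is
    in [0, 1) for any positive offset.
    """
    if methylated.shape != unmethylated.shape:
        raise ValueError(
            f"shape mismatch: M {methylated.shape} vs U {unmethylated.shape}"
        )
    m = methylated.to_numpy(dtype=float)
    u = unmethylated.to_numpy(dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise ValueError("intensities must be non-negative")
    if offset < 0:
        raise ValueError("offset must be non-negative")
    with np.errstate(invalid="ignore"):
        beta = m / (m + u + offset)
    beta = np.nan_to_num(beta, nan=0.0)  # only 0/0 with offset == 0
    return pd.DataFrame(beta, index=methylated.index, columns=methylated.columns)


def detection_filter(
    p: pd.DataFrame, alpha: float = 0.05, max_fail_frac: float = 0.05
) -> pd.Series:
    """Keep-mask over probes from detection p-values.

    A probe is removed when its detection p-value exceeds ``alpha`` in
    strictly more than ``max_fail_frac`` of samples ("p > 0.05 in over 5%
    of samples"); a probe failing in exactly that fraction is kept.
    """
    if p.size == 0:
        raise ValueError("empty detection p-value matrix")
    values = p.to_numpy(dtype=float)
    if (values < 0).any() or (values > 1).any():
        raise ValueError("detection p-values must lie in [0, 1]")
    fail_frac = (values > alpha).mean(axis=1)
    return pd.Series(fail_frac <= max_fail_frac, index=p.index, name="keep")


def drop_blacklisted(beta: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Remove sex-chromosome and SNP-overlapping probes.

    ``annotation`` needs columns (probe_id, chr, snp_flag) and must cover
    every probe in ``beta``; surviving probe order is preserved.
    """
    ann = annotation.set_index("probe_id")
    missing = beta.index.difference(ann.index)
    if len(missing) > 0:
        raise KeyError(
            f"{len(missing)} probes missing from annotation, e.g. "
            f"{list(missing[:5])}"
        )
    ann = ann.loc[beta.index]
    chrom = ann["chr"].astype(str).str.upper().str.replace("CHR", "", regex=False)
    bad = chrom.isin(["X", "Y"]) | ann["snp_flag"].astype(bool)
    kept = beta.loc[~bad.to_numpy()]
    if kept.shape[0] == 0:
        raise ValueError("all probes blacklisted; downstream stages need >= 1 probe")
    return kept


def quantile_normalize(x: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common mean-of-sorted-columns distribution.

    After normalization each column's sorted values equal the row-wise mean
    of the per-column sorted inputs, and within-column ranks are preserved.
    Ties are resolved by averaging the target values over the tied ranks
    (so identical input values stay identical).  A single-column matrix is
    returned unchanged.
    """
    if x.isna().to_numpy().any():
        raise ValueError("quantile normalization requires a complete matrix")
    if x.shape[1] <= 1:
        return x.copy()
    values = x.to_numpy(dtype=float)
    target = np.sort(values, axis=0).mean(axis=1)
    n = values.shape[0]
    out = np.empty_like(values)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, target)
    return pd.DataFrame(out, index=x.index, columns=x.columns)


def read_annotation(path) -> pd.DataFrame:
    """Read a probe annotation TSV with columns (probe_id, chr, gene, snp_flag)."""
    ann = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chr": str, "gene": str})
    required = {"probe_id", "chr", "gene", "snp_flag"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    if ann["probe_id"].duplicated().any():
        warnings.warn("duplicate probe ids in annotation; keeping first occurrence")
        ann = ann.drop_duplicates("probe_id")
    ann["gene"] = ann["gene"].fillna("")
    ann["snp_flag"] = ann["snp_flag"].astype(bool)
    return ann
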