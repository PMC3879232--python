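"""Expression-matrix preprocessing: merge, quantile-normalize, variance-filter
with a seed-preserving threshold, and row standardization.

The fixed stage order is merge -> quantile normalization -> IQR filter ->
row z-scaling; :func:`preprocess_pipeline` enforces it.  The variance filter
keeps a probe when its interquartile range across conditions is at least the
threshold, and the seed-preserving threshold is the largest cutoff under that
rule which retains every seed probe — in closed form, the minimum IQR over the
seed probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "IqrThreshold",
    "merge_datasets",
    "quantile_normalize",
    "probe_iqr",
    "select_seed_preserving_threshold",
    "filter_low_variability",
    "standardize_rows",
    "preprocess_pipeline",
]


@dataclass
class IqrThreshold:
    """A variance-filter cutoff together with the seed probes it retains."""

    value: float
    retained_seed_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("threshold value must be nonnegative")


def _validate_matrix(m: pd.DataFrame, name: str = "matrix") -> None:
    if m.index.has_duplicates:
        dups = m.index[m.index.duplicated()].unique().tolist()
        raise ValueError(f"{name} has duplicate row ids: {dups[:5]}")
    if m.columns.has_duplicates:
        dups = m.columns[m.columns.duplicated()].unique().tolist()
        raise ValueError(f"{name} has duplicate column ids: {dups[:5]}")
    if not np.isfinite(m.to_numpy(dtype=float)).all():
        raise ValueError(f"{name} contains non-finite values")


def merge_datasets(matrices: list[pd.DataFrame]) -> pd.DataFrame:
    """Inner-join a list of probe x condition matrices on probe ids.

    Rows are the intersection of probe ids, in lexicographic order; columns
    are the concatenation of all condition columns.  Condition ids must be
    globally unique (prefix them with a dataset id upstream).
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    for i, m in enumerate(matrices):
        _validate_matrix(m, f"matrix {i}")

    common = set(matrices[0].index)
    for m in matrices[1:]:
        common &= set(m.index)
    if not common:
        sizes = [len(m.index) for m in matrices]
        raise ValueError(
            f"probe intersection across the {len(matrices)} datasets is empty "
            f"(per-dataset probe counts: {sizes})"
        )
    rows = sorted(common)
    dropped = sum(len(m.index) - len(rows) for m in matrices)
    if dropped:
        logger.info("merge dropped %d probe rows outside the intersection", dropped)

    merged = pd.concat([m.loc[rows] for m in matrices], axis=1)
    if merged.columns.has_duplicates:
        dups = merged.columns[merged.columns.duplicated()].unique().tolist()
        raise ValueError(f"condition ids collide across datasets: {dups[:5]}")
    return merged


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common distribution of mean order statistics.

    Each column's sorted values are replaced by the across-column mean of the
    order statistics; within-column rank order is preserved, and tied values
    receive the mean of the reference values at the tied ranks.
    """
    _validate_matrix(m)
    if m.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 columns")
    x = m.to_numpy(dtype=float)
    reference = np.sort(x, axis=0).mean(axis=1)

    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # ties: average the reference values over the tied rank positions
        _, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        if (counts > 1).any():
            sums = np.bincount(inv, weights=assigned)
            assigned = sums[inv] / counts[inv]
        out[:, j] = assigned
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def probe_iqr(m: pd.DataFrame, interpolation: str = "linear") -> pd.Series:
    """Per-row interquartile range (Q3 - Q1) across conditions.

    The quantile rule defaults to linear interpolation; pass any numpy
    quantile ``method`` to change it.
    """
    if m.shape[1] < 2:
        raise ValueError("IQR needs at least 2 columns")
    x = m.to_numpy(dtype=float)
    q1, q3 = np.quantile(x, [0.25, 0.75], axis=1, method=interpolation)
    return pd.Series(q3 - q1, index=m.index, name="iqr")


def select_seed_preserving_threshold(
    iqrs: pd.Series, seed_probe_ids: list[str]
) -> IqrThreshold:
    """Largest keep-if-IQR>=t cutoff that retains every seed probe.

    That maximum is attained at the minimum IQR over the seed probes.
    """
    if not seed_probe_ids:
        raise ValueError("seed probe list is empty")
    missing = [s for s in seed_probe_ids if s not in iqrs.index]
    if missing:
        raise ValueError(f"seed probes absent from IQR table: {missing}")
    value = float(iqrs.loc[list(seed_probe_ids)].min())
    return IqrThreshold(value=value, retained_seed_ids=list(seed_probe_ids))


def filter_low_variability(m: pd.DataFrame, t: IqrThreshold) -> pd.DataFrame:
    """Drop rows whose IQR falls below ``t.value`` (keep when IQR >= t)."""
    iqrs = probe_iqr(m)
    keep = iqrs >= t.value
    if not keep.any():
        raise ValueError(
            f"IQR filter at threshold {t.value} would remove every row"
        )
    logger.info(
        "IQR filter at %.4g kept %d of %d rows", t.value, int(keep.sum()), len(keep)
    )
    return m.loc[keep]


def standardize_rows(m: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Scale each row to mean 0 and standard deviation 1.

    Population convention (``ddof=0``) by default.  Constant rows cannot be
    scaled and raise, listing the offending ids.
    """
    x = m.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        bad = m.index[constant].tolist()
        raise ValueError(f"constant rows cannot be standardized: {bad[:10]}")
    return pd.DataFrame((x - mu) / sd, index=m.index, columns=m.columns)


def preprocess_pipeline(
    matrices: list[pd.DataFrame] | pd.DataFrame,
    seed_probe_ids: list[str],
) -> tuple[pd.DataFrame, IqrThreshold]:
    """Run merge -> quantile-normalize -> seed-preserving IQR filter -> z-scale.

    Returns the processed matrix and the threshold report.
    """
    if isinstance(matrices, pd.DataFrame):
        matrices = [matrices]
    merged = merge_datasets(matrices)
    missing = [s for s in seed_probe_ids if s not in merged.index]
    if missing:
        raise ValueError(f"seed probes absent from merged matrix: {missing}")
    normed = quantile_normalize(merged)
    threshold = select_seed_preserving_threshold(probe_iqr(normed), seed_probe_ids)
    filtered = filter_low_variability(normed, threshold)
    return standardize_rows(filtered), threshold
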