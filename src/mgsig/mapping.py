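"""Probe-to-gene mapping: match-count filtering of alignments and collapsing
probe-level values to gene-level values."""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["filter_probe_alignments", "collapse_to_genes", "DEFAULT_MATCH_FRACTION"]

# the 57-of-60 rule for 60-mer probes
DEFAULT_MATCH_FRACTION = 57 / 60

_REQUIRED = ["probe_id", "gene_id", "probe_length", "match_count"]


def filter_probe_alignments(
    alignments: pd.DataFrame,
    min_match_fraction: float = DEFAULT_MATCH_FRACTION,
) -> pd.DataFrame:
    """Keep probe-gene associations whose alignment matches at least
    ``ceil(min_match_fraction * probe_length)`` bases.

    The default fraction reproduces the 57-matches-of-60 rule for 60-mers.
    Returns the mapping as a DataFrame with probe_id / gene_id columns.
    """
    if not (0.0 < min_match_fraction <= 1.0):
        raise ValueError("min_match_fraction must be in (0, 1]")
    missing = [c for c in _REQUIRED if c not in alignments.columns]
    if missing:
        raise ValueError(f"alignment table lacks columns: {missing}")
    lengths = alignments["probe_length"].to_numpy()
    counts = alignments["match_count"].to_numpy()
    if (counts < 0).any() or (counts > lengths).any():
        raise ValueError("match_count must lie in [0, probe_length]")
    # small epsilon so e.g. ceil((57/60) * 60) is not derailed by binary rounding
    thresholds = np.ceil(min_match_fraction * lengths - 1e-9)
    kept = alignments.loc[counts >= thresholds, ["probe_id", "gene_id"]]
    multi = kept.groupby("probe_id")["gene_id"].nunique()
    n_multi = int((multi > 1).sum())
    if n_multi:
        logger.warning(
            "%d probes map to multiple genes; kept for all targets", n_multi
        )
    return kept.reset_index(drop=True)


def collapse_to_genes(
    values: pd.Series,
    mapping: pd.DataFrame,
    rule: str = "max",
) -> pd.Series:
    """Aggregate per-probe values to one value per gene (default: max).

    Probes mapping to several genes contribute to each; probes absent from
    the mapping are logged and dropped.
    """
    if rule not in ("max", "mean"):
        raise ValueError("rule must be 'max' or 'mean'")
    if mapping.empty:
        raise ValueError("probe-gene mapping is empty")
    unmapped = values.index.difference(mapping["probe_id"])
    if len(unmapped):
        logger.info("%d probes have no gene mapping and are dropped", len(unmapped))
    joined = mapping.merge(
        values.rename("value"), left_on="probe_id", right_index=True
    )
    agg = joined.groupby("gene_id")["value"].agg(rule)
    agg.name = values.name
    return agg


def math_ceil_threshold(min_match_fraction: float, probe_length: int) -> int:
    """Integer match-count cutoff implied by a fraction for one probe length."""
    return int(math.ceil(min_match_fraction * probe_length - 1e-9))
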