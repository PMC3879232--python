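"""Promoter sequence characterization of a gene set.

Given gene models, a repeat annotation and genome sequence, this module
measures (i) the fraction of strand-aware windows around each gene's
5' terminus covered by a repeat class (LTR, SINE, LINE), comparing the target
set's coverage to an empirical null built from random same-size gene sets, and
(ii) the GC percentage of a (typically symmetric) window around the
5' terminus, comparing target vs background genes with a Welch t-test.

Conventions: coordinates are 0-based half-open throughout; the default
repeat window spans 2.0 kb upstream to 0.5 kb downstream of the transcription
start, the GC window 1.0 kb either side; the empirical p-value uses the
(r + 1) / (n + 1) correction and so never reaches zero.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "EnrichmentResult",
    "GCResult",
    "five_prime_window",
    "repeat_coverage",
    "window_table",
    "permutation_enrichment",
    "gc_percent",
    "gene_gc_percents",
    "gc_comparison_test",
    "plot_null_distribution",
]

REPEAT_WINDOW = (2000, 500)  # bp upstream, downstream of the 5' terminus
GC_WINDOW = (1000, 1000)


@dataclass(frozen=True)
class WindowSpec:
    """Strand-aware window around the 5' terminus (bp upstream / downstream)."""

    upstream: int = 2000
    downstream: int = 500

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("window extents must be nonnegative")
        if self.upstream + self.downstream <= 0:
            raise ValueError("window must have positive total extent")


@dataclass
class EnrichmentResult:
    """Observed coverage vs an empirical null from random gene sets."""

    observed: float
    null_values: np.ndarray
    p_value: float
    direction: str
    n_sets: int
    rng_seed: int | None = None
    repeat_class: str | None = None

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "p_value": self.p_value,
            "direction": self.direction,
            "n_sets": self.n_sets,
            "null_mean": float(np.mean(self.null_values)),
            "rng_seed": self.rng_seed,
            "repeat_class": self.repeat_class,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class GCResult:
    """Welch t-test comparison of per-gene promoter GC percentages."""

    target_gc: list[float] = field(default_factory=list)
    background_gc: list[float] = field(default_factory=list)
    t_statistic: float = float("nan")
    p_value: float = float("nan")
    direction: str = "none"

    def to_dict(self) -> dict:
        return {
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "direction": self.direction,
            "target_mean_gc": float(np.mean(self.target_gc)),
            "background_mean_gc": float(np.mean(self.background_gc)),
            "n_target": len(self.target_gc),
            "n_background": len(self.background_gc),
        }


def five_prime_window(
    gene: pd.Series | dict,
    w: WindowSpec,
    chrom_length: int | None = None,
) -> tuple[int, int, bool]:
    """Window around a gene's 5' terminus, strand-aware and clipped.

    For a + strand gene the 5' terminus is ``start`` and the window is
    ``[start - upstream, start + downstream)``; for a - strand gene it is
    ``end`` with the mirrored window ``[end - downstream, end + upstream)``.
    Returns ``(lo, hi, clipped)`` after clipping to ``[0, chrom_length)``.
    """
    strand = gene["strand"]
    if strand not in ("+", "-"):
        raise ValueError(f"gene {gene.get('gene_id', '?')} has undefined strand")
    if strand == "+":
        lo, hi = gene["start"] - w.upstream, gene["start"] + w.downstream
    else:
        lo, hi = gene["end"] - w.downstream, gene["end"] + w.upstream
    clipped_lo = max(lo, 0)
    clipped_hi = hi if chrom_length is None else min(hi, chrom_length)
    clipped = (clipped_lo, clipped_hi) != (lo, hi)
    if clipped_hi <= clipped_lo:
        logger.warning(
            "window of gene %s empty after clipping", gene.get("gene_id", "?")
        )
        return clipped_lo, clipped_lo, True
    return clipped_lo, clipped_hi, clipped


def _merged_intervals(repeats: pd.DataFrame, cls: str) -> dict[str, np.ndarray]:
    """Union of same-class repeat intervals per chromosome, as sorted
    (start, end) arrays with cumulative covered lengths for fast queries."""
    sel = repeats[repeats["repeat_class"] == cls] if cls != "all" else repeats
    merged: dict[str, np.ndarray] = {}
    for chrom, grp in sel.groupby("chrom"):
        iv = grp[["start", "end"]].sort_values("start").to_numpy()
        out = []
        for s, e in iv:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.asarray(out, dtype=float).reshape(-1, 2)
    return merged


def _overlap_bp(intervals: np.ndarray, lo: int, hi: int) -> float:
    if intervals.size == 0 or hi <= lo:
        return 0.0
    s, e = intervals[:, 0], intervals[:, 1]
    return float(np.clip(np.minimum(e, hi) - np.maximum(s, lo), 0, None).sum())


def window_table(
    genes: pd.DataFrame,
    repeats: pd.DataFrame,
    w: WindowSpec,
    cls: str,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-gene window bounds, window length, and class-covered bp."""
    if genes.empty:
        raise ValueError("no genes supplied")
    merged = _merged_intervals(repeats, cls)
    rows = []
    for _, g in genes.iterrows():
        clen = None if chrom_lengths is None else chrom_lengths.get(g["chrom"])
        lo, hi, clipped = five_prime_window(g, w, clen)
        iv = merged.get(g["chrom"], np.empty((0, 2)))
        rows.append(
            {
                "gene_id": g["gene_id"],
                "chrom": g["chrom"],
                "window_start": lo,
                "window_end": hi,
                "window_bp": hi - lo,
                "covered_bp": _overlap_bp(iv, lo, hi),
                "clipped": clipped,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def repeat_coverage(
    genes: pd.DataFrame,
    repeats: pd.DataFrame,
    w: WindowSpec,
    cls: str,
    chrom_lengths: dict[str, int] | None = None,
    per_gene_mean: bool = False,
) -> float:
    """Overall fraction of the genes' 5'-terminus windows covered by class
    ``cls`` repeats.

    The default aggregates base pairs (total covered bp / total window bp);
    ``per_gene_mean=True`` instead averages per-gene fractions.  Overlapping
    repeats count once per base.  Empty (fully clipped) windows are excluded
    with a warning.
    """
    tab = window_table(genes, repeats, w, cls, chrom_lengths)
    tab = tab[tab["window_bp"] > 0]
    if tab.empty:
        raise ValueError("all windows empty after clipping")
    if per_gene_mean:
        return float((tab["covered_bp"] / tab["window_bp"]).mean())
    return float(tab["covered_bp"].sum() / tab["window_bp"].sum())


def permutation_enrichment(
    target: list[str],
    universe: list[str],
    genes: pd.DataFrame,
    repeats: pd.DataFrame,
    w: WindowSpec | None = None,
    cls: str = "LTR",
    n_sets: int = 5000,
    direction: str = "greater",
    rng_seed: int | None = 0,
    exclude_target: bool = False,
    chrom_lengths: dict[str, int] | None = None,
) -> EnrichmentResult:
    """Empirical coverage enrichment of ``target`` against random gene sets.

    Each null value is the coverage of a uniform random subset of ``universe``
    of size ``len(target)`` (drawn without replacement; by default the draw
    may include target genes).  The empirical p-value is
    ``(#{null >= observed} + 1) / (n_sets + 1)`` for direction "greater",
    mirrored for "less".
    """
    w = w or WindowSpec(*REPEAT_WINDOW)
    if n_sets < 1:
        raise ValueError("n_sets must be at least 1")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    target = list(target)
    universe = list(universe)
    missing = set(target) - set(universe)
    if missing:
        raise ValueError(f"target genes outside the universe: {sorted(missing)[:5]}")
    if len(target) > len(universe):
        raise ValueError("target larger than universe")

    gsub = genes.set_index("gene_id", drop=False)
    tab = window_table(gsub.loc[universe], repeats, w, cls, chrom_lengths)
    covered = tab["covered_bp"].to_numpy()
    length = tab["window_bp"].to_numpy()
    idx_of = {g: i for i, g in enumerate(tab.index)}

    def cov(idx: np.ndarray) -> float:
        tot = length[idx].sum()
        if tot == 0:
            return 0.0
        return float(covered[idx].sum() / tot)

    t_idx = np.array([idx_of[g] for g in target])
    observed = cov(t_idx)

    pool = np.arange(len(universe))
    if exclude_target:
        pool = np.setdiff1d(pool, t_idx)
        if len(pool) < len(target):
            raise ValueError("universe minus target smaller than target size")
    rng = np.random.default_rng(rng_seed)
    null = np.empty(n_sets)
    for i in range(n_sets):
        draw = rng.choice(pool, size=len(target), replace=False)
        null[i] = cov(draw)

    if direction == "greater":
        r = int((null >= observed).sum())
    else:
        r = int((null <= observed).sum())
    p = (r + 1) / (n_sets + 1)
    return EnrichmentResult(
        observed=observed,
        null_values=null,
        p_value=p,
        direction=direction,
        n_sets=n_sets,
        rng_seed=rng_seed,
        repeat_class=cls,
    )


def gc_percent(sequences, chrom: str, lo: int, hi: int) -> float:
    """GC percentage of ``[lo, hi)`` on ``chrom``.

    ``sequences`` may be a dict of strings or an indexed FASTA handle
    (e.g. ``pyfaidx.Fasta``).  G and C are counted case-insensitively;
    ambiguous bases enter the denominator only, matching the semantics of
    sequence-composition counters like faCount.
    """
    if hi <= lo or lo < 0:
        raise ValueError(f"invalid interval [{lo}, {hi})")
    seq = sequences[chrom][lo:hi]
    seq = str(seq)
    if len(seq) < hi - lo:
        raise ValueError(
            f"interval [{lo}, {hi}) extends beyond {chrom} (length {lo + len(seq)})"
        )
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    return 100.0 * gc / len(s)


def gene_gc_percents(
    genes: pd.DataFrame,
    sequences,
    w: WindowSpec | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.Series:
    """GC% of each gene's 5'-terminus window (default 1.0 kb either side)."""
    w = w or WindowSpec(*GC_WINDOW)
    out = {}
    for _, g in genes.iterrows():
        clen = None if chrom_lengths is None else chrom_lengths.get(g["chrom"])
        lo, hi, _ = five_prime_window(g, w, clen)
        if hi <= lo:
            continue
        out[g["gene_id"]] = gc_percent(sequences, g["chrom"], lo, hi)
    return pd.Series(out, name="gc_percent")


def gc_comparison_test(
    target_gc,
    background_gc,
    alternative: str = "two-sided",
) -> GCResult:
    """Welch two-sample t-test of promoter GC% between gene groups.

    The reported direction comes from the sign of the mean difference
    (target minus background).  Two zero-variance groups with equal means
    give t = 0, p = 1 by convention.
    """
    target_gc = list(map(float, target_gc))
    background_gc = list(map(float, background_gc))
    if len(target_gc) < 2 or len(background_gc) < 2:
        raise ValueError("each group needs at least 2 values")
    diff = np.mean(target_gc) - np.mean(background_gc)
    if np.std(target_gc) == 0 and np.std(background_gc) == 0 and diff == 0:
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_ind(
            target_gc, background_gc, equal_var=False, alternative=alternative
        )
    direction = "higher" if diff > 0 else ("lower" if diff < 0 else "equal")
    return GCResult(
        target_gc=target_gc,
        background_gc=background_gc,
        t_statistic=float(t_stat),
        p_value=float(p),
        direction=direction,
    )


def plot_null_distribution(result: EnrichmentResult, path, title: str = "") -> None:
    """Histogram of the null coverage distribution with the observed value."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(result.null_values, bins=40, color="0.6")
    ax.axvline(result.observed, color="crimson", lw=2)
    ax.set_xlabel("window coverage fraction")
    ax.set_ylabel("random gene sets")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
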