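"""Synthetic data generators.

Three generators replace the external inputs the analysis would otherwise
need: a microarray-style expression compendium with a planted co-expressed
module around a seed cohort, a probe-to-genome alignment table, and a toy
genome (gene models, repeat annotation, sequence) in which repeat density and
promoter GC content are controllable per gene group.

The expression model is a single latent factor: module rows (seeds included)
are ``gain * (z + sigma * eps) + offset`` where ``z`` is one shared profile
across conditions and ``eps`` is row-specific white noise.  The population
pairwise correlation between two module rows is ``1 / (1 + sigma**2)``, so
``sigma = sqrt(1/r - 1)`` calibrates the module to a target correlation ``r``.
Background rows are independent noise with probe-specific gain and offset.
Conditions are grouped into dataset blocks that each receive a distinct affine
distortion (scale, offset) emulating inter-experiment variability — the
structure quantile normalization is meant to remove.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimExpressionSpec",
    "SimGenomeSpec",
    "generate_expression_dataset",
    "generate_probe_alignments",
    "generate_genome",
    "split_by_dataset",
]


@dataclass
class SimExpressionSpec:
    """Parameters of the planted-module expression simulation.

    Parameters
    ----------
    n_probes : int
        Total rows of the matrix.
    n_conditions : int
        Columns; default 56 to match the size of a typical merged ESC
        microarray compendium.
    n_seed : int
        Number of seed (known positive) rows; default 8.
    module_size : int
        Size of the planted co-expressed module, seeds included.
    module_correlation : float
        Target pairwise Pearson correlation within the module, in (0, 1].
    noise_sd : float or None
        Standard deviation of the row-specific noise added to the shared
        module profile.  ``None`` (default) calibrates it from
        ``module_correlation``; an explicit value overrides the calibration.
    n_datasets : int
        Number of dataset blocks with distinct affine distortions.
    block_scale_range : (float, float)
        Per-block multiplicative distortion is drawn log-uniformly from this
        interval.
    block_offset_sd : float
        Per-block additive distortion is drawn from N(0, this**2).
    rng_seed : int
        Seed for all randomness in the generator.
    """

    n_probes: int
    n_conditions: int = 56
    n_seed: int = 8
    module_size: int = 30
    module_correlation: float = 0.8
    noise_sd: float | None = None
    n_datasets: int = 8
    block_scale_range: tuple[float, float] = (0.8, 1.25)
    block_offset_sd: float = 0.25
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_probes < 1:
            raise ValueError("n_probes must be positive")
        if self.n_conditions < 2:
            raise ValueError("n_conditions must be at least 2")
        if self.n_seed < 1:
            raise ValueError("n_seed must be positive")
        if not (self.n_seed <= self.module_size <= self.n_probes):
            raise ValueError(
                "module_size must satisfy n_seed <= module_size <= n_probes"
            )
        if not (0.0 < self.module_correlation <= 1.0):
            raise ValueError("module_correlation must be in (0, 1]")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be at least 1")
        if self.n_datasets > self.n_conditions:
            raise ValueError("n_datasets cannot exceed n_conditions")


@dataclass
class SimGenomeSpec:
    """Parameters of the toy-genome simulation.

    Each gene owns a 6 kb slot on a single chromosome; its transcription
    start sits far enough from the slot edges that the default repeat window
    (2.0 kb upstream / 0.5 kb downstream) and GC window (1.0 kb / 1.0 kb)
    never leave the slot, so per-gene densities are independent.
    """

    n_genes: int = 200
    chrom_length: int | None = None  # default: exactly n_genes slots
    target_set_size: int = 20
    repeat_density_target: float = 0.6
    repeat_density_background: float = 0.3
    gc_target: float = 0.46
    gc_background: float = 0.51
    gc_sd: float = 0.02  # per-gene spread of window GC around the group mean
    repeat_class: str = "LTR"
    repeat_window: tuple[int, int] = (2000, 500)  # upstream, downstream bp
    gc_window: tuple[int, int] = (1000, 1000)
    rng_seed: int = 0

    SLOT: int = field(default=6000, repr=False)

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not (0 <= self.target_set_size <= self.n_genes):
            raise ValueError("target_set_size must be in [0, n_genes]")
        for name in (
            "repeat_density_target",
            "repeat_density_background",
            "gc_target",
            "gc_background",
            "gc_sd",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        length = self.chrom_length
        if length is not None and length < self.n_genes * self.SLOT:
            raise ValueError(
                f"chrom_length {length} too small to place {self.n_genes} genes "
                f"(needs at least {self.n_genes * self.SLOT})"
            )


def _probe_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i + 1:0{width}d}" for i in range(n)]


def generate_expression_dataset(
    spec: SimExpressionSpec,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a probe x condition matrix with a planted seed-correlated module.

    Returns
    -------
    matrix : pandas.DataFrame
        ``n_probes`` rows x ``n_conditions`` columns.  Column names encode the
        dataset block (``d01:c001`` ...).
    truth : pandas.Series
        Row id -> label in {"seed", "module", "background"}.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)

    n, p = spec.n_probes, spec.n_conditions
    ids = _probe_ids(n)
    labels = np.array(
        ["seed"] * spec.n_seed
        + ["module"] * (spec.module_size - spec.n_seed)
        + ["background"] * (n - spec.module_size)
    )

    if spec.noise_sd is None:
        r = spec.module_correlation
        sigma = math.sqrt(1.0 / r - 1.0)
    else:
        sigma = spec.noise_sd

    # shared latent profile, standardized empirically so the realized
    # signal-to-noise ratio (hence the module correlation) hits the target
    z = rng.normal(size=p)
    z = (z - z.mean()) / z.std()
    gain = rng.uniform(0.8, 1.25, size=n)
    offset = rng.normal(scale=0.5, size=n)

    x = np.empty((n, p))
    m = spec.module_size
    eps = rng.normal(size=(m, p))
    # remove each noise vector's component along z and rescale to unit sd,
    # so corr(row_i, row_j) concentrates tightly on 1 / (1 + sigma^2)
    eps = eps - (eps @ z)[:, None] * z[None, :] / (z @ z)
    eps = eps / eps.std(axis=1, keepdims=True)
    x[:m] = z[None, :] + sigma * eps
    x[m:] = rng.normal(size=(n - m, p))

    # dataset blocks: contiguous condition groups, distinct affine distortion.
    # Applied before the probe-specific gain/offset so that at zero noise the
    # module rows stay exact affine copies of one (distorted) shared profile.
    bounds = np.linspace(0, p, spec.n_datasets + 1).astype(int)
    lo, hi = spec.block_scale_range
    cols = []
    for b in range(spec.n_datasets):
        s = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        o = rng.normal(scale=spec.block_offset_sd)
        sl = slice(bounds[b], bounds[b + 1])
        x[:, sl] = s * x[:, sl] + o
        cols.extend(
            f"d{b + 1:02d}:c{j + 1:03d}" for j in range(bounds[b], bounds[b + 1])
        )
    x = gain[:, None] * x + offset[:, None]

    matrix = pd.DataFrame(x, index=ids, columns=cols)
    truth = pd.Series(labels, index=ids, name="label")
    return matrix, truth


def split_by_dataset(matrix: pd.DataFrame) -> list[pd.DataFrame]:
    """Split a simulated matrix back into its per-dataset blocks.

    Uses the ``<dataset>:<condition>`` column naming of
    :func:`generate_expression_dataset`; useful for exercising the merge step.
    """
    blocks = {}
    for col in matrix.columns:
        ds = col.split(":", 1)[0]
        blocks.setdefault(ds, []).append(col)
    return [matrix[cols] for cols in blocks.values()]


def generate_probe_alignments(
    gene_ids,
    probes_per_gene: int,
    match_count_distribution=60,
    probe_length: int = 60,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Build a synthetic probe-to-genome alignment table.

    ``match_count_distribution`` may be a constant, a sequence cycled per gene
    (e.g. ``[60, 56]`` gives each gene one passing and one failing probe at the
    57-of-60 rule), or a callable ``f(rng, size) -> int array``.
    """
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise ValueError("gene_ids must be non-empty")
    if probes_per_gene < 1:
        raise ValueError("probes_per_gene must be at least 1")
    rng = np.random.default_rng(rng_seed)

    n = len(gene_ids) * probes_per_gene
    if callable(match_count_distribution):
        counts = np.asarray(match_count_distribution(rng, n), dtype=int)
    elif np.isscalar(match_count_distribution):
        counts = np.full(n, int(match_count_distribution))
    else:
        cycle = list(match_count_distribution)
        counts = np.array([cycle[k % len(cycle)] for k in range(n)])
    if (counts < 0).any() or (counts > probe_length).any():
        raise ValueError("match counts must lie in [0, probe_length]")

    rows = []
    k = 0
    for i, gid in enumerate(gene_ids):
        for j in range(probes_per_gene):
            start = 10_000 * i + 100 * j
            rows.append(
                {
                    "probe_id": f"{gid}_p{j + 1}",
                    "gene_id": gid,
                    "chrom": "chrS",
                    "start": start,
                    "end": start + probe_length,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "probe_length": probe_length,
                    "match_count": counts[k],
                }
            )
            k += 1
    return pd.DataFrame(rows)


def _gc_tile(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """Sequence of `length` bases whose GC count is floor-exact for `gc`.

    Positions where ``floor((i+1)*gc)`` increments get a G or C, the rest A or
    T, so gc=0.5 yields a strict GC/AT alternation and the realized fraction
    never deviates from the target by more than 1/length.
    """
    i = np.arange(length)
    is_gc = np.floor((i + 1) * gc) > np.floor(i * gc)
    out = np.empty(length, dtype="<U1")
    gc_choices = rng.choice(list("GC"), size=length)
    at_choices = rng.choice(list("AT"), size=length)
    out[is_gc] = gc_choices[is_gc]
    out[~is_gc] = at_choices[~is_gc]
    return out


def generate_genome(
    spec: SimGenomeSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str], pd.Series]:
    """Simulate gene models, repeat features and sequence on one chromosome.

    Repeat features of ``spec.repeat_class`` are laid down in each gene's
    5'-terminus repeat window as 50 bp tiles kept with probability equal to the
    gene's group density, so the expected window coverage equals the density
    exactly (1.0 covers every base, 0.0 none).  The GC window sequence realizes
    the group GC fraction by construction.  Genes outside the target set use
    the background parameters.

    Returns ``(genes, repeats, sequences, truth)`` where ``genes`` and
    ``repeats`` are BED-like DataFrames (0-based half-open), ``sequences`` maps
    chromosome name to string, and ``truth`` labels each gene "target" or
    "background".
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    slot = spec.SLOT
    chrom = "chrS"
    chrom_length = spec.chrom_length or spec.n_genes * slot

    width = max(4, len(str(spec.n_genes)))
    ids = [f"gene{i + 1:0{width}d}" for i in range(spec.n_genes)]
    target_ids = set(rng.choice(ids, size=spec.target_set_size, replace=False))

    up_r, down_r = spec.repeat_window
    up_g, down_g = spec.gc_window

    seq = rng.choice(list("ACGT"), size=chrom_length)
    genes = []
    repeats = []
    tile = 50
    for i, gid in enumerate(ids):
        slot_start = i * slot
        start = slot_start + 2500
        length = int(rng.integers(500, 1501))
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            {
                "gene_id": gid,
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": strand,
            }
        )
        is_target = gid in target_ids
        density = (
            spec.repeat_density_target if is_target else spec.repeat_density_background
        )
        gc = spec.gc_target if is_target else spec.gc_background
        if spec.gc_sd > 0:
            gc = float(np.clip(rng.normal(gc, spec.gc_sd), 0.0, 1.0))

        tss = start if strand == "+" else end
        if strand == "+":
            r_lo, r_hi = tss - up_r, tss + down_r
            g_lo, g_hi = tss - up_g, tss + down_g
        else:
            r_lo, r_hi = tss - down_r, tss + up_r
            g_lo, g_hi = tss - down_g, tss + up_g

        for t0 in range(r_lo, r_hi, tile):
            t1 = min(t0 + tile, r_hi)
            if rng.random() < density:
                repeats.append(
                    {
                        "chrom": chrom,
                        "start": t0,
                        "end": t1,
                        "repeat_class": spec.repeat_class,
                    }
                )
        seq[g_lo:g_hi] = _gc_tile(g_hi - g_lo, gc, rng)

    genes_df = pd.DataFrame(genes)
    repeats_df = pd.DataFrame(
        repeats, columns=["chrom", "start", "end", "repeat_class"]
    )
    sequences = {chrom: "".join(seq)}
    truth = pd.Series(
        ["target" if g in target_ids else "background" for g in ids],
        index=ids,
        name="label",
    )
    return genes_df, repeats_df, sequences, truth
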