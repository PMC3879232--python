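# Methods

## The ranking model

The core statistic is a bagged positive-unlabeled (PU) SVM score. The only
labeled examples are the seed genes, a small cohort known to co-fluctuate
with the marker of interest; there is no principled negative set. Each of
the `n_classifiers` rounds therefore samples provisional negatives uniformly
from the unlabeled genes (without replacement, disjoint from the seeds) and
trains a soft-margin SVM on seed rows vs sampled rows, features being the
standardized expression values across all conditions. Averaging the signed
decision values over rounds integrates out the arbitrariness of any single
negative draw; most random draws are true negatives, so genes resembling the
seeds accumulate consistently positive margins.

Assumptions worth stating:

- *Seed coherence.* The seeds share an expression program strong enough to
  be linearly separable (in most rounds) from random gene vectors. If the
  seeds are heterogeneous the average margin flattens and the ranking loses
  power; no attempt is made to detect this.
- *Contamination tolerance.* A random negative draw occasionally contains a
  true signature gene. This biases single rounds, not the average; the
  exclusion rule below removes the most direct form of the bias.
- *Row exchangeability after preprocessing.* Quantile normalization followed
  by per-row z-scaling makes rows comparable; the SVM sees shape, not level.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `n_classifiers` | 1000 | ensemble rounds; the mean score's Monte-Carlo error shrinks as 1/√B |
| `negatives_per_run` | = #seeds | balanced training; larger sets shrink the positive class's influence |
| `kernel`, `C` | linear, 1.0 | few training points in ~56 dimensions: a linear margin is conventional, and makes the single-run geometry checkable in closed form |
| `exclude_negative_runs_from_average` | on | a gene's rounds as provisional negative do not enter its own mean (standard bagging-PU practice; a flag restores the all-rounds average) |
| `k` | 100 | signature size; ties broken lexicographically, seeds excluded from the output (they are the query) |

The decision value (signed margin distance), not a calibrated probability,
is averaged: only the ordering matters and Platt scaling would add a second
fitted model per round. Ranking operates on probe rows; when several probes
map one gene, `collapse_to_genes` aggregates scores (default `max`,
optimistic for discovery; `mean` available).

## Preprocessing

Stage order is fixed: merge → quantile normalization → IQR filter →
row standardization; the orchestrator enforces it.

- *Merge*: inner join on probe ids, condition columns concatenated,
  rows sorted lexicographically. Collections on one platform lose little to
  the intersection; dropped rows are logged.
- *Quantile normalization*: each column's sorted values are replaced by the
  across-column mean of order statistics. Tied values receive the mean of
  the reference values at the tied ranks; with ties present, the exact
  "identical sorted vector" property and idempotence hold only up to this
  averaging.
- *IQR filter*: keep a row when IQR ≥ threshold. The seed-preserving
  threshold is the minimum seed IQR — the maximum of all cutoffs that retain
  every seed under the ≥ rule (with a strict > rule the maximum would not
  exist, which is why ≥ was chosen). Quantiles use linear interpolation
  (type 7), configurable.
- *Standardization*: per row, population convention (divisor *n*),
  configurable; constant rows raise with their ids.

## Synthetic data

The expression generator plants a module of `module_size` rows (the first
`n_seed` are the seeds) as `gain · (block_affine(z + σ·ε)) + offset`, one
shared latent profile `z` per simulation. σ is calibrated as √(1/r − 1) so
pairwise module correlation concentrates on the target `r`; the realized
`z` is standardized empirically and each row's noise is orthogonalized
against it, which tightens the realized correlation to within a few
hundredths of the target. Background rows are independent noise with the
same probe-level gain/offset. Conditions fall into `n_datasets` contiguous
blocks, each distorted by its own affine map (scale log-uniform on
[0.8, 1.25], offset N(0, 0.25)) — mild batch structure of the kind quantile
normalization removes. Defaults (56 conditions, 8 seeds, module 30, r = 0.8,
8 blocks) mirror a merged single-platform compendium of 8 experiment series;
seed-cohort effect sizes in real data are unknown, so r is a free parameter
of the simulation, not a calibration to any real compendium.

The toy genome gives each gene a 6 kb slot on one chromosome, so the repeat
window (2.0/0.5 kb) and GC window (1.0/1.0 kb) around the 5′ terminus never
overlap between genes and group densities are independent. Repeat coverage
is planted by tiling each window with 50 bp segments kept with probability
equal to the gene's group density — expected coverage equals the density,
with the extremes 0 and 1 exact. Window GC is realized by a deterministic
tiling that hits a per-gene GC fraction drawn as N(group mean, `gc_sd`,
default 0.02, clipped to [0, 1]); `gc_sd = 0` gives the exact alternating
construction (50% GC is a strict GC/AT alternation). What the generator does
*not* emulate: probe-level hybridization physics, overlapping or nested gene
models, chromosome-scale repeat clustering, and isochore GC structure — so
green tests certify the pipeline's statistics and bookkeeping, not its
behavior on those complications.

## Promoter statistics

Coordinates are 0-based half-open throughout; BED is native, RepeatMasker
`.out` (1-based inclusive) is converted on read, and class/family strings
map to {LTR, SINE, LINE, other} by class prefix (SINE/Alu → SINE). The 5′
window for a + strand gene [s, e) is [s − up, s + down); for − strand,
[e − down, e + up); windows are clipped to the chromosome and empty windows
are excluded with a warning. "Overall coverage" aggregates base pairs
(Σ covered / Σ window length) — identical to the mean per-gene fraction when
windows share one unclipped length; the per-gene-mean variant is a flag.

The permutation null draws `n_sets` (default 5000) uniform same-size subsets
of the universe, by default allowed to overlap the target (an
`exclude_target` flag is provided); the p-value is (r + 1)/(n + 1), so its
floor is 1/(n + 1) and it is never zero. The GC comparison is a Welch
t-test, two-sided by default with the direction reported from the sign of
the mean difference — the directional hypothesis is surfaced rather than
presumed. Two zero-variance groups with equal means give t = 0, p = 1 by
convention.

One operational caveat: the genome generator and the permutation test must
not share a literal RNG seed — an identical generator state would replay,
as the first null draw, the very index sequence that selected the target
set. Derived stage seeds (as in the pipeline orchestrator and the
acceptance script) avoid this.

## Family clustering

Identity clustering forms connected components over pairs with identity
strictly above the threshold (default 0.90, "above" read strictly); missing
pairs count as identity 0, and raising the threshold only refines the
partition. The hierarchical variant represents each gene by its row of the
distance table (the one reading under which "Euclidean distance + Ward
linkage" on a precomputed distance file is well-defined), builds the Ward
dendrogram, and cuts at `cut_fraction` × maximum merge height (default
0.90). "Cut level of 90%" admits other readings (similarity level, cluster
count); height fraction was chosen and is configurable. In the fully
degenerate case of equal pairwise distances all merge heights tie at the
maximum, so any cut strictly below it yields singletons — degenerate inputs
deserve the component-based rule instead.

## Problem sizes

The shipped drivers and tests use 2000-probe × 56-condition simulations with
200–1000 classifiers, 200-gene toy genomes, 5000-set nulls, and a 200-replicate
calibration check of the permutation test (null rejection at α = 0.05 stays
within the binomial band around the nominal rate). These sizes exercise every
code path at full default constants while each stage completes in seconds.

## Known limitations

- The negative-set size and SVM hyperparameters are conventions, not fitted;
  on real data they deserve a sensitivity sweep.
- Probe-to-gene mapping consumes precomputed alignment tables; running the
  aligner (blat) or vendor annotation pipelines is out of scope.
- The headline numbers of the motivating study (probe counts before/after
  filtering, the 52-gene annotated signature, mm10 repeat enrichments,
  46% vs 51% GC) require the original GEO series and mouse genome; the
  package accepts such inputs but ships no downloads, and the synthetic
  results certify the machinery, not those values.
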