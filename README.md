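# mgsig

Discovery of a **main gene signature** (MGS) functionally related to a small
cohort of co-fluctuating marker genes — the *seed* — from a heterogeneous
collection of expression experiments, followed by sequence characterization
of the signature's promoters.

The motivating setting is the transient, high-pluripotency metastate of
mouse embryonic stem cells marked by *Zscan4*: a handful of genes are known
to co-fluctuate with the marker, and the task is to rank every other gene by
how much its expression behaves like that cohort across many perturbation
experiments, without any labeled negative examples.

## Method

**Positive-unlabeled ensemble ranking.** Given a probe × condition matrix
*X* (rows standardized after quantile normalization and a variance filter)
and a seed set *S*, the ranker trains *B* = 1000 soft-margin SVM classifiers.
Round *b* fixes *S* as positives and draws a fresh uniform random set
*N_b* ⊂ (genes ∖ *S*), |*N_b*| = |*S*|, as provisional negatives; every gene
*g* receives the signed decision value *f_b(g)*. The final score is

    score(g) = mean over { b : g ∉ N_b } of f_b(g)

(the rounds in which *g* itself served as a provisional negative are excluded
from its own average), and the MGS hypothesis is the top *k* = 100 unlabeled
genes. Preprocessing keeps a probe when its interquartile range across
conditions is ≥ *t*\*, where *t*\* = min over seeds of IQR — the largest
cutoff that loses no seed probe.

**Promoter characterization.** For a gene set *T*, the fraction of
strand-aware windows around the 5′ terminus (2.0 kb upstream / 0.5 kb
downstream) covered by a retroelement class (LTR, SINE, LINE) is compared to
5000 random gene sets of size |*T*|, giving the empirical p-value
(r + 1)/(n + 1); promoter GC% (1.0 kb either side of the 5′ terminus) is
compared target-vs-background with a Welch t-test.

Because the original microarray collections and genome are external
downloads, a first-class synthetic-data module generates the inputs with the
structure the analysis assumes: a planted co-expressed module at a
calibrated correlation inside a multi-dataset compendium, probe-alignment
tables for the 57-of-60 match filter, and a toy genome with controllable
per-group repeat density and promoter GC.

## Worked example

The numbered drivers under `analysis/` run the whole study at desk scale and
write their tables under `results/`:

```
$ python analysis/01_simulate_expression.py
simulated 2000 probes x 56 conditions
planted module: 30 genes (8 seeds), mean pairwise correlation 0.799 (target 0.8)

$ python analysis/02_preprocess.py
merged 8 dataset blocks into (2000, 56) matrix
seed-preserving IQR threshold: 1.1942
probes kept after variance filter: 1483 of 2000

$ python analysis/03_rank_signature.py
trained 1000 SVM classifiers on 1483 probes
signature: top 100 genes (score range 0.951 to -0.377)
planted-module recovery: 19/19 non-seed module genes in the top 100

$ python analysis/04_cluster_families.py
100 signature transcripts clustered into 39 families at identity > 0.90 (39 families planted)

$ python analysis/05_promoter_features.py
LTR coverage of target windows: 0.600 (null mean 0.321); empirical p = 2.00e-04 over 5000 random sets
promoter GC: targets 47.0% vs background 50.9%; Welch t = -7.83, p = 5.93e-08 (lower)
```

Reading the output: the variance filter keeps every seed probe by
construction; all 19 surviving planted module genes are recovered inside the
top-100 signature; the target promoters' LTR coverage (0.60) exceeds all
5000 random-set coverages, so the empirical p-value is at its floor
1/5001 ≈ 2×10⁻⁴; and target promoters are significantly GC-poorer than
background, as the generator planted.

The same stages are exposed as a CLI (`mgsig simulate-expression`,
`preprocess`, `rank`, `signature`, `families`, `enrich-repeats`,
`enrich-gc`, `run-all`; see `mgsig --help`), which also accepts real data:
expression TSVs, gene models as BED6, repeats as BED6 or RepeatMasker
`.out`, genomes as FASTA, and probe alignments as TSV or PSL.

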