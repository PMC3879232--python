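"""Positive-unlabeled gene ranking with a bagged SVM ensemble.

With only a small cohort of known positives (the seed genes) and no labeled
negatives, each of ``n_classifiers`` rounds trains a soft-margin SVM with the
seeds fixed as positives and a fresh uniform sample of unlabeled genes as
provisional negatives, then records the signed decision value of every gene.
A gene's final score is the mean of its decision values — by default over the
rounds in which it did not itself serve as a negative, which avoids the
self-labeling bias of letting a gene's own provisional negative rounds drag
its average down.  The ranked top-``k`` unlabeled genes form the signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleConfig",
    "sample_negatives",
    "score_single_run",
    "ensemble_scores",
    "select_signature",
]

_RETRY_CAP = 5


@dataclass
class EnsembleConfig:
    """Ensemble hyperparameters.

    ``negatives_per_run=None`` means balanced training (as many negatives as
    seeds).  The linear kernel with C=1 is the default: expression rows are
    few training points in a moderate-dimensional condition space, where a
    linear margin is the conventional and most interpretable choice.
    """

    n_classifiers: int = 1000
    negatives_per_run: int | None = None
    kernel: str = "linear"
    C: float = 1.0
    exclude_negative_runs_from_average: bool = True
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_classifiers < 1:
            raise ValueError("n_classifiers must be at least 1")
        if self.negatives_per_run is not None and self.negatives_per_run < 1:
            raise ValueError("negatives_per_run must be at least 1")
        if self.kernel not in ("linear", "rbf"):
            raise ValueError("kernel must be 'linear' or 'rbf'")
        if self.C <= 0:
            raise ValueError("regularization constant C must be positive")


def _validate_seeds(m: pd.DataFrame, seeds: list[str]) -> list[str]:
    seeds = list(seeds)
    if not seeds:
        raise ValueError("seed set is empty")
    if len(set(seeds)) != len(seeds):
        raise ValueError("seed set contains duplicate ids")
    missing = [s for s in seeds if s not in m.index]
    if missing:
        raise ValueError(f"seed ids absent from matrix: {missing}")
    return seeds


def sample_negatives(
    universe: list[str],
    seeds: list[str],
    size: int,
    rng: np.random.Generator,
) -> list[str]:
    """Uniform sample (without replacement) of provisional negatives from the
    unlabeled genes, i.e. the universe minus the seeds."""
    pool = [g for g in universe if g not in set(seeds)]
    if size > len(pool):
        raise ValueError(
            f"cannot draw {size} negatives from {len(pool)} unlabeled genes"
        )
    idx = rng.choice(len(pool), size=size, replace=False)
    return [pool[i] for i in idx]


def score_single_run(
    m: pd.DataFrame,
    positives: list[str],
    negatives: list[str],
    config: EnsembleConfig | None = None,
) -> pd.Series:
    """Train one SVM (positives vs provisional negatives) and return the signed
    decision value for every gene row; higher means more seed-like."""
    config = config or EnsembleConfig()
    config.validate()
    if not positives or not negatives:
        raise ValueError("positives and negatives must each be non-empty")
    overlap = set(positives) & set(negatives)
    if overlap:
        raise ValueError(f"positives and negatives overlap: {sorted(overlap)}")

    x_train = m.loc[list(positives) + list(negatives)].to_numpy(dtype=float)
    y_train = np.r_[np.ones(len(positives)), -np.ones(len(negatives))]
    clf = SVC(kernel=config.kernel, C=config.C)
    clf.fit(x_train, y_train)
    scores = clf.decision_function(m.to_numpy(dtype=float))
    return pd.Series(scores, index=m.index, name="score")


def ensemble_scores(
    m: pd.DataFrame,
    seeds: list[str],
    config: EnsembleConfig | None = None,
) -> pd.DataFrame:
    """Run the full bagged ensemble and average each gene's decision values.

    Returns a DataFrame indexed by gene id with columns ``mean_score`` and
    ``n_contributing_runs``.  With the default exclusion flag a gene's rounds
    as a provisional negative do not enter its own average.
    """
    config = config or EnsembleConfig()
    config.validate()
    seeds = _validate_seeds(m, seeds)
    rng = np.random.default_rng(config.rng_seed)
    n_neg = config.negatives_per_run or len(seeds)
    universe = list(m.index)

    sums = np.zeros(len(universe))
    counts = np.zeros(len(universe), dtype=int)
    n_done = 0
    for _ in range(config.n_classifiers):
        for attempt in range(_RETRY_CAP + 1):
            negatives = sample_negatives(universe, seeds, n_neg, rng)
            try:
                run = score_single_run(m, seeds, negatives, config)
                break
            except Exception:
                if attempt == _RETRY_CAP:
                    raise
                logger.warning("degenerate training draw; resampling negatives")
        vals = run.to_numpy()
        if config.exclude_negative_runs_from_average:
            mask = np.ones(len(universe), dtype=bool)
            mask[m.index.get_indexer(negatives)] = False
        else:
            mask = np.ones(len(universe), dtype=bool)
        sums[mask] += vals[mask]
        counts[mask] += 1
        n_done += 1
    logger.info("ensemble completed %d train/score rounds", n_done)

    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    out = pd.DataFrame(
        {"mean_score": means, "n_contributing_runs": counts}, index=m.index
    )
    out.attrs["n_classifiers_run"] = n_done
    out.attrs["seed_ids"] = seeds
    # never true with the defaults, but a tiny ensemble plus exclusion can
    # leave a gene with no contributing run
    if (counts == 0).any():
        logger.warning(
            "%d genes were negatives in every run and have no score",
            int((counts == 0).sum()),
        )
    return out


def select_signature(
    scores: pd.DataFrame,
    k: int = 100,
    seeds: list[str] | None = None,
) -> pd.DataFrame:
    """Top-``k`` unlabeled genes by mean ensemble score.

    Seeds are the query and are excluded from the output.  Ties are broken
    lexicographically by gene id; if fewer than ``k`` unlabeled genes exist,
    all are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    seeds = list(seeds or scores.attrs.get("seed_ids", []))
    unlabeled = scores.drop(index=[s for s in seeds if s in scores.index])
    unlabeled = unlabeled.dropna(subset=["mean_score"])
    if k > len(unlabeled):
        logger.warning(
            "requested top %d but only %d unlabeled genes scored; returning all",
            k,
            len(unlabeled),
        )
        k = len(unlabeled)
    order = np.lexsort(
        (unlabeled.index.to_numpy(), -unlabeled["mean_score"].to_numpy())
    )
    return unlabeled.iloc[order].head(k)
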