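"""End-to-end orchestration of the signature-discovery workflow.

Stage order is fixed: merge -> quantile normalization -> seed-preserving IQR
filter -> row standardization -> ensemble ranking -> top-k signature, with
optional downstream steps (probe-to-gene collapse, identity clustering,
promoter repeat enrichment and GC comparison on a genome).  All defaults are
the study constants: 1000 classifiers, top 100 genes, 5000 random gene sets,
identity threshold 0.90, dendrogram cut 0.90, probe-match fraction 57/60,
repeat window 2.0 kb / 0.5 kb and GC window 1.0 kb / 1.0 kb around the
5' terminus.  Every stage seed is derived deterministically from the global
seed, so a manifest replays bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mgsig import enrichment, ensemble, io, preprocess, simulate
from mgsig.enrichment import WindowSpec
from mgsig.ensemble import EnsembleConfig
from mgsig.simulate import SimExpressionSpec, SimGenomeSpec

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunArtifacts", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    Either ``expression_spec`` (synthetic) or ``expression_paths`` (TSV files)
    must be provided; the genome block is optional and enables the promoter
    characterization stages.
    """

    expression_spec: SimExpressionSpec | None = None
    expression_paths: list[str] = field(default_factory=list)
    seed_ids: list[str] = field(default_factory=list)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    k: int = 100
    genome_spec: SimGenomeSpec | None = None
    repeat_window: WindowSpec = field(default_factory=lambda: WindowSpec(2000, 500))
    gc_window: WindowSpec = field(default_factory=lambda: WindowSpec(1000, 1000))
    n_random_sets: int = 5000
    repeat_class: str = "LTR"
    identity_threshold: float = 0.90
    cut_fraction: float = 0.90
    min_match_fraction: float = 57 / 60
    rng_seed: int = 0

    def derived_seed(self, stage: str) -> int:
        """Stage seed derived deterministically from the global seed."""
        tag = zlib.crc32(stage.encode()) % (2**31)
        ss = np.random.SeedSequence([self.rng_seed, tag])
        return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunArtifacts:
    matrix: pd.DataFrame
    threshold: preprocess.IqrThreshold
    scores: pd.DataFrame
    signature: pd.DataFrame
    truth: pd.Series | None = None
    enrichment_result: enrichment.EnrichmentResult | None = None
    gc_result: enrichment.GCResult | None = None
    manifest: dict = field(default_factory=dict)


def _spec_dict(spec) -> dict | None:
    if spec is None:
        return None
    d = dataclasses.asdict(spec)
    return {k: v for k, v in d.items() if k != "SLOT"}


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> RunArtifacts:
    """Execute the workflow and (optionally) write artifacts and a manifest."""
    if config.expression_spec is None and not config.expression_paths:
        raise ValueError("provide expression_spec or expression_paths")

    truth = None
    spec = None
    if config.expression_spec is not None:
        spec = dataclasses.replace(
            config.expression_spec,
            rng_seed=config.expression_spec.rng_seed
            if config.expression_spec.rng_seed
            else config.derived_seed("expression"),
        )
        matrix, truth = simulate.generate_expression_dataset(spec)
        matrices = simulate.split_by_dataset(matrix)
        seed_ids = config.seed_ids or truth.index[truth == "seed"].tolist()
    else:
        matrices = [io.read_expression_tsv(p) for p in config.expression_paths]
        seed_ids = config.seed_ids
        if not seed_ids:
            raise ValueError("seed_ids required with file inputs")

    try:
        processed, threshold = preprocess.preprocess_pipeline(matrices, seed_ids)
    except ValueError as err:
        raise ValueError(f"preprocessing failed: {err}") from err

    ens = dataclasses.replace(
        config.ensemble,
        rng_seed=config.ensemble.rng_seed
        if config.ensemble.rng_seed
        else config.derived_seed("ensemble"),
    )
    scores = ensemble.ensemble_scores(processed, seed_ids, ens)
    signature = ensemble.select_signature(scores, k=config.k, seeds=seed_ids)

    enr = None
    gc_res = None
    if config.genome_spec is not None:
        genes, repeats, sequences, gtruth = simulate.generate_genome(config.genome_spec)
        target = gtruth.index[gtruth == "target"].tolist()
        chrom_lengths = {c: len(s) for c, s in sequences.items()}
        enr = enrichment.permutation_enrichment(
            target,
            list(genes["gene_id"]),
            genes,
            repeats,
            config.repeat_window,
            cls=config.repeat_class,
            n_sets=config.n_random_sets,
            rng_seed=config.derived_seed("permutation"),
            chrom_lengths=chrom_lengths,
        )
        gcs = enrichment.gene_gc_percents(
            genes, sequences, config.gc_window, chrom_lengths
        )
        bg = gtruth.index[gtruth == "background"].tolist()
        gc_res = enrichment.gc_comparison_test(gcs.loc[target], gcs.loc[bg])

    manifest = {
        "package": "mgsig",
        "rng_seed": config.rng_seed,
        "k": config.k,
        "n_random_sets": config.n_random_sets,
        "identity_threshold": config.identity_threshold,
        "cut_fraction": config.cut_fraction,
        "min_match_fraction": config.min_match_fraction,
        "ensemble": dataclasses.asdict(ens),
        "expression_spec": _spec_dict(spec),
        "genome_spec": _spec_dict(config.genome_spec),
        "seed_ids": list(seed_ids),
        "iqr_threshold": threshold.value,
        "n_probes_after_filter": int(processed.shape[0]),
    }

    artifacts = RunArtifacts(
        matrix=processed,
        threshold=threshold,
        scores=scores,
        signature=signature,
        truth=truth,
        enrichment_result=enr,
        gc_result=gc_res,
        manifest=manifest,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_expression_tsv(processed, out / "normalized_matrix.tsv")
        scores.to_csv(out / "gene_scores.tsv", sep="\t", index_label="gene_id")
        signature.to_csv(out / "signature.tsv", sep="\t", index_label="gene_id")
        if enr is not None:
            enr.to_json(out / "repeat_enrichment.json")
            pd.Series(enr.null_values, name="coverage").to_csv(
                out / "repeat_null_distribution.tsv", sep="\t", index=False
            )
        if gc_res is not None:
            import json

            (out / "gc_comparison.json").write_text(
                json.dumps(gc_res.to_dict(), indent=2)
            )
        io.write_manifest(manifest, out / "manifest.yaml")
        logger.info("artifacts written to %s", out)
    return artifacts
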