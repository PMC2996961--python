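"""End-to-end pipeline: score -> seeds -> top-k test -> enrichment ->
mask -> re-test -> miRNA match.

Each stage writes its table under the output directory and contributes
to a JSON summary; a failure aborts with an error naming the stage,
leaving the outputs of completed stages on disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, gsea_preranked, io, masking, mirna_match
from .multiplicity_test import empirical_p, sample_null
from .screen_core import score_screen
from .seed_tools import build_seed_index
from .io import library_records

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    library: str
    measurements: str
    out_dir: str
    mirna_fasta: str | None = None
    gene_set: list[str] = field(default_factory=list)
    k: int = 20
    n_iter: int = 5000
    n_perm: int = 1000
    fwer_threshold: float = 0.05
    seed_lengths: tuple[int, ...] = (6, 7)
    mask_mode: str = "seed_position"
    mirna_match_mode: str = "both"
    viability_fraction: float = 0.2
    mad_scope: str = "replicate"
    p_weight: float = 1.0
    min_set_size: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fwer_threshold <= 1:
            raise ValueError("fwer_threshold must lie in (0, 1]")
        for path, stage in ((self.library, "library"), (self.measurements, "measurements")):
            if not Path(path).is_file():
                raise FileNotFoundError(f"{stage} file not found: {path}")
        if self.mirna_fasta and not Path(self.mirna_fasta).is_file():
            raise FileNotFoundError(f"miRNA FASTA not found: {self.mirna_fasta}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        return cls(**raw)


def _stage(name):
    def wrap(func):
        def inner(*args, **kwargs):
            try:
                return func(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(name, exc) from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the JSON-serializable summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "rng_seed": config.rng_seed,
        "config": {k: v for k, v in asdict(config).items()},
    }

    library, scores = _score_stage(config, out)
    ranked, indexes, seed_maps = _seed_stage(config, out, library, scores)
    summary["n_sirnas"] = len(library)
    summary["n_ranked"] = len(ranked)

    summary["topk_test"] = _topk_stage(config, ranked, seed_maps, indexes)
    enriched, gsea_results = _gsea_stage(config, out, ranked, indexes)
    summary["enriched_seeds"] = {
        str(length): sorted(seeds) for length, seeds in enriched.items()
    }
    summary["n_enriched"] = {
        str(length): len(seeds) for length, seeds in enriched.items()
    }

    mask_report = _mask_stage(config, out, ranked, library, enriched)
    summary["n_masked"] = len(mask_report.removed)

    if config.gene_set:
        summary["known_gene_enrichment"] = _retest_stage(
            config, ranked, mask_report.retained, library
        )
    if config.mirna_fasta:
        summary["mirna_matches"] = _mirna_stage(config, out, enriched)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete; summary written to %s", out / "summary.json")
    return summary


@_stage("score")
def _score_stage(config: PipelineConfig, out: Path):
    library = io.read_library(config.library)
    measurements = io.read_measurements(config.measurements)
    scores = score_screen(
        library, measurements,
        viability_fraction=config.viability_fraction,
        mad_scope=config.mad_scope,
    )
    io.write_score_table(scores, out / "scores.tsv")
    return library, scores


@_stage("seeds")
def _seed_stage(config: PipelineConfig, out: Path, library, scores):
    records = library_records(library)
    ranked = gsea_preranked.make_ranked(
        scores.loc[scores["score"].notna(), "sirna_id"],
        scores.loc[scores["score"].notna(), "score"],
    )
    indexes, seed_maps = {}, {}
    for length in config.seed_lengths:
        idx = build_seed_index(records, length)
        io.write_seed_index(idx, out / f"seed_index_{length}.tsv")
        indexes[length] = idx
        seed_maps[length] = idx.seed_of()
    return ranked, indexes, seed_maps


@_stage("topk_test")
def _topk_stage(config: PipelineConfig, ranked, seed_maps, indexes):
    from .seed_tools import top_k_seed_multiplicity

    results = {}
    ranked_ids = ranked["item_id"].tolist()
    for length, seed_of in seed_maps.items():
        mult = top_k_seed_multiplicity(ranked_ids, seed_of, config.k)
        library_seeds = [seed_of[s] for s in seed_of]
        entry = {"k": config.k}
        for stat, observed in (
            ("n_repeated", mult.n_repeated),
            ("max_count", mult.max_count),
        ):
            null = sample_null(
                library_seeds, k=config.k, n_iter=config.n_iter,
                statistic=stat, rng_seed=config.rng_seed,
            )
            res = empirical_p(null, observed)
            entry[stat] = {
                "observed": observed,
                "p": res.p,
                "convention": res.convention,
                "n_iter": res.n_iter,
            }
        results[str(length)] = entry
    return results


@_stage("gsea")
def _gsea_stage(config: PipelineConfig, out: Path, ranked, indexes):
    universe = set(ranked["item_id"])
    enriched, all_results = {}, {}
    for length, idx in indexes.items():
        sets = {
            seed: [m for m in members if m in universe]
            for seed, members in idx.members.items()
        }
        sets = {s: m for s, m in sets.items() if len(m) >= config.min_set_size}
        results = gsea_preranked.calibrate(
            ranked, sets,
            n_perm=config.n_perm, p_weight=config.p_weight,
            min_size=config.min_set_size, rng_seed=config.rng_seed + length,
        )
        results = results.rename(columns={"set": "seed"})
        results.to_csv(out / f"enrichment_{length}.tsv", sep="\t", index=False)
        hits = gsea_preranked.select_enriched(results, config.fwer_threshold)
        enriched[length] = hits["seed"].tolist() if len(hits) else []
        io.write_seed_list(enriched[length], out / f"enriched_seeds_{length}.txt")
        all_results[length] = results
    return enriched, all_results


@_stage("mask")
def _mask_stage(config: PipelineConfig, out: Path, ranked, library, enriched):
    guide_of = dict(zip(library["sirna_id"], library["guide_seq"]))
    report = masking.mask_enriched(
        ranked, guide_of,
        enriched_hexamers=enriched.get(6, []),
        enriched_heptamers=enriched.get(7, []),
        mode=config.mask_mode,
    )
    gene_of = dict(zip(library["sirna_id"], library["gene_id"]))
    masked = report.retained.assign(
        gene=[gene_of[s] for s in report.retained["item_id"]]
    )[["item_id", "gene", "score", "rank"]].rename(columns={"item_id": "sirna_id"})
    masked.to_csv(out / "masked_ranking.tsv", sep="\t", index=False)
    return report


@_stage("rerank_test")
def _retest_stage(config: PipelineConfig, ranked, retained, library):
    gene_of = dict(zip(library["sirna_id"], library["gene_id"]))
    result = {}
    for label, ranking in (("before", ranked), ("after", retained[["item_id", "score"]])):
        row = masking.known_gene_enrichment(
            ranking.reset_index(drop=True), gene_of, config.gene_set,
            n_perm=config.n_perm, p_weight=config.p_weight,
            rng_seed=config.rng_seed,
        )
        result[label] = {
            "size": int(row["size"]),
            "es": float(row["es"]),
            "nes": float(row["nes"]),
            "p_nominal": float(row["p_nominal"]),
            "p_upper": float(row["p_upper"]),
        }
    result["improved"] = result["after"]["p_upper"] < result["before"]["p_upper"]
    return result


@_stage("mirna")
def _mirna_stage(config: PipelineConfig, out: Path, enriched):
    mirnas = mirna_match.read_mature_fasta(config.mirna_fasta)
    frames = []
    for length, seeds in enriched.items():
        if not seeds:
            continue
        frames.append(
            mirna_match.match_seeds(
                seeds, mirnas, seed_length=length, mode=config.mirna_match_mode
            )
        )
    pairs = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["seed", "mirna_name", "orientation"])
    )
    pairs.to_csv(out / "mirna_matches.tsv", sep="\t", index=False)
    return pairs.to_dict(orient="records")
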