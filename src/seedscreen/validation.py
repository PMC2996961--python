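"""Statistical validation experiments on synthetic screens.

The screens these methods were designed for ship no reusable raw data,
so the package validates itself on simulation: does the full pipeline
recover a planted off-target seed while leaving decoy seeds alone, does
masking detected seeds rescue the enrichment of genes with genuine
effects, and do the Monte Carlo machinery's collision rates match
closed-form expectations?  Tests and the reproduction script both run
the experiments defined here.

Experiment conditions (library sizes, effect sizes, carrier counts)
are fixed study conditions, not tuning knobs; they are documented in
the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import gsea_preranked as gp
from . import masking
from .io import library_records
from .multiplicity_test import sample_null
from .screen_core import score_screen
from .seed_tools import build_seed_index
from .synthetic_screen import PlantedSeed, SimulationConfig, simulate_screen

__all__ = [
    "decoy_hexamers",
    "recovery_experiment",
    "rescue_experiment",
    "birthday_experiment",
]

PLANTED_SEED = "ACTTGA"


def decoy_hexamers(n: int = 100, exclude: str = PLANTED_SEED, rng_seed: int = 123456):
    """n distinct random hexamers, none equal to the planted seed."""
    rng = np.random.default_rng(rng_seed)
    seen, out = {exclude}, []
    while len(out) < n:
        s = "".join(rng.choice(list("ACGT"), 6))
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def _seed_sets(library, ranked, min_size: int = 5):
    idx = build_seed_index(library_records(library), 6)
    universe = set(ranked["item_id"])
    sets = {
        s: [m for m in mem if m in universe] for s, mem in idx.members.items()
    }
    return {s: m for s, m in sets.items() if len(m) >= min_size}


@dataclass(frozen=True)
class RecoveryResult:
    n_runs: int
    power: float  # fraction of runs recovering the planted seed
    decoy_run_rate: float  # fraction of runs flagging >= 1 decoy


def recovery_experiment(
    n_runs: int = 50,
    base_seed: int = 0,
    delta: float = 2.0,
    n_carriers: int = 30,
    n_decoys: int = 100,
    decoy_carriers: int = 10,
    n_genes: int = 1500,
    n_perm: int = 1000,
    fwer_threshold: float = 0.05,
) -> RecoveryResult:
    """Planted-seed recovery with decoy false-flag control.

    Each run simulates a screen with one effective planted hexamer
    (``delta`` z-units on ``n_carriers`` guides) and ``n_decoys``
    effect-free decoy hexamers forced onto ``decoy_carriers`` guides
    each (so the decoys form real, testable seed sets), scores it, runs
    the seed-set enrichment analysis and selects seeds at the FWER
    threshold.
    """
    decoys = decoy_hexamers(n_decoys)
    hits = flags = 0
    for run in range(n_runs):
        planted = [PlantedSeed(PLANTED_SEED, delta, n_carriers)] + [
            PlantedSeed(d, 0.0, decoy_carriers) for d in decoys
        ]
        cfg = SimulationConfig(
            n_genes=n_genes, planted_seeds=planted,
            rng_seed=base_seed * 1009 + run,
        )
        library, _, measurements = simulate_screen(cfg)
        scores = score_screen(library, measurements)
        scored = scores[scores["score"].notna()]
        ranked = gp.make_ranked(scored["sirna_id"], scored["score"])
        results = gp.calibrate(
            ranked, _seed_sets(library, ranked), n_perm=n_perm,
            rng_seed=base_seed * 1013 + run,
        )
        selected = set(gp.select_enriched(results, fwer_threshold)["set"])
        hits += PLANTED_SEED in selected
        flags += bool(selected & set(decoys))
    return RecoveryResult(
        n_runs=n_runs, power=hits / n_runs, decoy_run_rate=flags / n_runs
    )


@dataclass(frozen=True)
class RescueResult:
    n_runs: int
    improved_rate: float  # fraction of runs with p_after < p_before
    median_p_before: float
    median_p_after: float


INTERFERING_SEEDS = ("ACTTGA", "TAATAA", "CCTTAA", "AATTAA", "TAGGAA")


def rescue_experiment(
    n_runs: int = 50,
    base_seed: int = 0,
    n_genes: int = 500,
    n_known_genes: int = 12,
    gene_delta: float = 1.0,
    seed_delta: float = 2.0,
    carriers_per_seed: int = 40,
    interfering_seeds: tuple[str, ...] = INTERFERING_SEEDS,
    n_perm_detect: int = 500,
    n_perm_test: int = 1999,
) -> RescueResult:
    """False-negative rescue: mask detected seeds, re-test known genes.

    Known genes carry a genuine protective effect; several interfering
    seeds (planted on other genes' siRNAs, mirroring the multi-seed
    interference real screens show) crowd the top of the ranking and
    bury the known-gene enrichment signal.  Enriched seeds are detected
    from the data, their carriers masked, and the known-gene set
    re-tested on the re-ranked list with the directional enrichment p.
    """
    known = [f"G{i + 1:05d}" for i in range(n_known_genes)]
    improved = 0
    before_ps, after_ps = [], []
    for run in range(n_runs):
        cfg = SimulationConfig(
            n_genes=n_genes,
            planted_seeds=[
                PlantedSeed(s, seed_delta, carriers_per_seed)
                for s in interfering_seeds
            ],
            planted_gene_effects={g: gene_delta for g in known},
            rng_seed=base_seed * 2003 + run,
        )
        library, _, measurements = simulate_screen(cfg)
        scores = score_screen(library, measurements)
        scored = scores[scores["score"].notna()]
        ranked = gp.make_ranked(scored["sirna_id"], scored["score"])
        results = gp.calibrate(
            ranked, _seed_sets(library, ranked), n_perm=n_perm_detect,
            rng_seed=base_seed * 2011 + run,
        )
        enriched = gp.select_enriched(results, 0.05)["set"].tolist()
        guide_of = dict(zip(library["sirna_id"], library["guide_seq"]))
        gene_of = dict(zip(library["sirna_id"], library["gene_id"]))
        report = masking.mask_enriched(ranked, guide_of, enriched_hexamers=enriched)
        before = masking.known_gene_enrichment(
            ranked, gene_of, known, n_perm=n_perm_test,
            rng_seed=base_seed * 2017 + run,
        )
        after = masking.known_gene_enrichment(
            report.retained[["item_id", "score"]].reset_index(drop=True),
            gene_of, known, n_perm=n_perm_test, rng_seed=base_seed * 2017 + run,
        )
        before_ps.append(float(before["p_upper"]))
        after_ps.append(float(after["p_upper"]))
        improved += after_ps[-1] < before_ps[-1]
    return RescueResult(
        n_runs=n_runs,
        improved_rate=improved / n_runs,
        median_p_before=float(np.median(before_ps)),
        median_p_after=float(np.median(after_ps)),
    )


@dataclass(frozen=True)
class BirthdayResult:
    k: int
    n_iter: int
    mc_estimate: float  # Monte Carlo P(any repeated seed among k)
    analytic: float  # birthday-collision closed form
    se: float  # Monte Carlo standard error at the analytic rate


def birthday_experiment(
    n_sirnas: int = 12190,
    n_seed_kinds: int = 4096,
    k: int = 20,
    n_iter: int = 5000,
    rng_seed: int = 0,
) -> BirthdayResult:
    """Collision rate of the multiplicity sampler vs the birthday bound.

    A library of ``n_sirnas`` guides with uniform random hexamers is
    sampled k at a time; the chance that any seed repeats should match
    1 - prod_{i<k}(1 - i/4096).
    """
    rng = np.random.default_rng(rng_seed)
    seeds = [f"H{v:04d}" for v in rng.integers(0, n_seed_kinds, n_sirnas)]
    null = sample_null(
        seeds, k=k, n_iter=n_iter, statistic="n_repeated", rng_seed=rng_seed + 1
    )
    mc = float((null.samples >= 1).mean())
    analytic = 1.0 - float(
        np.prod(1.0 - np.arange(1, k) / n_seed_kinds)
    )
    se = float(np.sqrt(analytic * (1 - analytic) / n_iter))
    return BirthdayResult(k=k, n_iter=n_iter, mc_estimate=mc, analytic=analytic, se=se)
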