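"""Synthetic arrayed RNAi screens with planted seed-driven off-targets.

The generator emulates the structure of a genome-scale viability
screen: a library of ~2 siRNAs per gene with random 21-nt guides,
96-well plates carrying positive, negative and transfection controls,
two replicates, lognormal pre-treatment fluorescence, and a latent
log-survival per well decomposing into

    baseline + gene effect + seed effect + Normal(0, noise_sd).

"Seed effects" are planted by forcing a chosen hexamer into the seed
position (nt 2-7) of a chosen number of carrier guides; every siRNA
whose seed position carries a planted hexamer — forced or by chance —
receives that seed's effect, mimicking sequence-driven off-target
phenotypes.  Ground truth (per-siRNA gene, seed and total latent
effects) is emitted alongside so recovery can be scored exactly.

Positive-control wells receive a strong protective effect and the
transfection control a strong lethal one, so assay-quality metrics
(Z') are exercised.  Spatial plate artifacts and edge effects are not
modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .seed_tools import normalize_sequence

__all__ = ["PlantedSeed", "SimulationConfig", "simulate_library",
           "simulate_measurements", "simulate_screen", "load_config"]

_BASES = np.array(list("ACGT"))

# per-96-well-plate control layout: two duplicates each of three
# protective positive controls, two transfection-control wells, four
# negative-control wells
N_POS, N_TRANSFECT, N_NEG = 6, 2, 4
N_CONTROLS = N_POS + N_TRANSFECT + N_NEG


@dataclass(frozen=True)
class PlantedSeed:
    """A hexamer forced into the seed position of n_carriers guides."""

    seed: str
    delta: float  # latent log-survival shift, z-units
    n_carriers: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "seed", normalize_sequence(self.seed))
        if len(self.seed) != 6:
            raise ValueError(f"planted seed must be a hexamer, got {self.seed!r}")
        if not np.isfinite(self.delta):
            raise ValueError("planted seed effect must be finite")
        if self.n_carriers < 0:
            raise ValueError("n_carriers must be >= 0")


@dataclass
class SimulationConfig:
    n_genes: int = 500
    sirnas_per_gene: int = 2
    guide_length: int = 21
    planted_seeds: list[PlantedSeed] = field(default_factory=list)
    planted_gene_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    n_replicates: int = 2
    plate_size: int = 96
    baseline_log_survival: float = float(np.log(0.3))
    pos_ctrl_delta: float = 3.0  # strongly protective
    transfection_ctrl_delta: float = -3.0  # cell-lethal transfection control
    pre_fluor_meanlog: float = 10.0
    pre_fluor_sdlog: float = 0.25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.sirnas_per_gene, self.n_replicates) < 1:
            raise ValueError("counts must be positive")
        if self.guide_length < 8:
            raise ValueError("guide_length must be >= 8")
        if self.plate_size <= N_CONTROLS:
            raise ValueError("plate_size must exceed the control layout")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for g in self.planted_gene_effects.values():
            if not np.isfinite(g):
                raise ValueError("gene effects must be finite")

    @property
    def n_sirnas(self) -> int:
        return self.n_genes * self.sirnas_per_gene


def load_config(path) -> SimulationConfig:
    """Read a SimulationConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    planted = [PlantedSeed(**p) for p in raw.pop("planted_seeds", [])]
    return SimulationConfig(planted_seeds=planted, **raw)


def simulate_library(config: SimulationConfig):
    """Random siRNA library plus per-siRNA ground truth.

    Returns (library, truth): library has sirna_id, gene_id, guide_seq;
    truth adds hexamer, forced_carrier, gene_effect, seed_effect and
    latent_effect (their sum).  Carrier guides are drawn disjointly
    across planted seeds and only from genes without a planted gene
    effect, so seed-driven interference lands on "other" genes; chance
    carriers (guides that happen to read a planted hexamer at nt 2-7)
    also receive the seed effect and are distinguishable via
    forced_carrier.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_sirnas
    total_forced = sum(p.n_carriers for p in config.planted_seeds)
    if total_forced > n:
        raise ValueError(
            f"requested {total_forced} planted carriers exceed library size {n}"
        )
    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    genes = np.repeat(gene_ids, config.sirnas_per_gene)
    sirna_ids = [
        f"si{gene}_{j + 1}"
        for gene in gene_ids
        for j in range(config.sirnas_per_gene)
    ]
    guides = rng.choice(_BASES, size=(n, config.guide_length))

    forced = np.full(n, "", dtype=object)
    # forced carriers come from genes with no planted gene effect, so the
    # two planted effect sources stay disjoint in the ground truth (seed
    # interference lands on "other" genes); chance carriers may overlap
    eligible = np.flatnonzero(
        ~pd.Series(genes).isin(config.planted_gene_effects).to_numpy()
    )
    total_forced = sum(p.n_carriers for p in config.planted_seeds)
    if total_forced > len(eligible):
        raise ValueError(
            f"requested {total_forced} planted carriers exceed the "
            f"{len(eligible)} siRNAs of genes without planted gene effects"
        )
    pool = rng.permutation(eligible)
    start = 0
    for planted in config.planted_seeds:
        take = pool[start : start + planted.n_carriers]
        start += planted.n_carriers
        guides[take, 1:7] = list(planted.seed)
        forced[take] = planted.seed

    guide_strs = ["".join(row) for row in guides]
    hexamers = [g[1:7] for g in guide_strs]
    seed_delta = {p.seed: p.delta for p in config.planted_seeds}
    seed_effect = np.array([seed_delta.get(h, 0.0) for h in hexamers])
    gene_effect = np.array(
        [config.planted_gene_effects.get(g, 0.0) for g in genes]
    )

    library = pd.DataFrame(
        {"sirna_id": sirna_ids, "gene_id": genes, "guide_seq": guide_strs}
    )
    truth = library.assign(
        hexamer=hexamers,
        forced_carrier=forced,
        gene_effect=gene_effect,
        seed_effect=seed_effect,
        latent_effect=gene_effect + seed_effect,
    )
    return library, truth


def simulate_measurements(
    library: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Plate measurements for a simulated library.

    Plates are filled in library order, each with the fixed control
    layout; pre-treatment fluorescence is lognormal and post = pre *
    exp(latent log-survival).  Returns the long measurement table the
    scoring pipeline consumes.
    """
    rng = np.random.default_rng(config.rng_seed + 1)
    latent_of = dict(zip(truth["sirna_id"], truth["latent_effect"]))
    samples_per_plate = config.plate_size - N_CONTROLS
    n = len(library)
    n_plates = -(-n // samples_per_plate)

    n_cols = 12 if config.plate_size == 96 else config.plate_size
    def well_name(i: int) -> str:
        return f"{chr(ord('A') + i // n_cols)}{i % n_cols + 1:02d}"

    control_slots = (
        [("pos_ctrl", config.pos_ctrl_delta)] * N_POS
        + [("transfection_ctrl", config.transfection_ctrl_delta)] * N_TRANSFECT
        + [("neg_ctrl", 0.0)] * N_NEG
    )

    rows = []
    for rep in range(1, config.n_replicates + 1):
        for plate_i in range(n_plates):
            plate = f"P{plate_i + 1:03d}"
            chunk = library.iloc[
                plate_i * samples_per_plate : (plate_i + 1) * samples_per_plate
            ]
            wells: list[tuple[str, str | None, float | None]] = [
                ("sample", sid, latent_of[sid]) for sid in chunk["sirna_id"]
            ]
            wells += [(role, None, delta) for role, delta in control_slots]
            while len(wells) < config.plate_size:
                wells.append(("empty", None, None))
            for i, (role, sid, delta) in enumerate(wells):
                well = well_name(i)
                if role == "empty":
                    continue
                pre = float(
                    rng.lognormal(config.pre_fluor_meanlog, config.pre_fluor_sdlog)
                )
                latent = (
                    config.baseline_log_survival
                    + delta
                    + rng.normal(0.0, config.noise_sd)
                )
                post = pre * float(np.exp(latent))
                for phase, fluor in (("pre", pre), ("post", post)):
                    rows.append(
                        (plate, well, rep, phase, fluor, role, sid)
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "plate", "well", "replicate", "phase", "fluorescence", "role", "sirna_id",
        ],
    )


def simulate_screen(config: SimulationConfig):
    """Convenience wrapper: (library, truth, measurements)."""
    library, truth = simulate_library(config)
    measurements = simulate_measurements(library, truth, config)
    return library, truth, measurements
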