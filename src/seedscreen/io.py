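"""Readers and writers for the pipeline's tabular interfaces.

All files are plain TSV/CSV.  Schemas:

- library: sirna_id, gene_id, guide_seq (guide 5'->3', DNA or RNA);
- measurements: plate, well, replicate, phase, fluorescence, role,
  sirna_id (blank for controls);
- score table: sirna_id, gene_id, z_rep*, score, rank;
- seed index: seed, length, size, comma-joined sirna_ids;
- seed list: one seed per line (for mask inputs);
- enrichment results: set/seed, size, es, nes, p_nominal, fwer_p.
"""

from __future__ import annotations

import pandas as pd

from .screen_core import MEASUREMENT_COLUMNS
from .seed_tools import SeedIndex, SiRNARecord, normalize_sequence

__all__ = [
    "read_library",
    "read_measurements",
    "library_records",
    "write_score_table",
    "read_score_table",
    "write_seed_index",
    "read_seed_list",
    "write_seed_list",
]


def read_library(path) -> pd.DataFrame:
    """Library TSV -> DataFrame with normalized guide sequences."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sirna_id", "gene_id", "guide_seq"} - set(df.columns)
    if missing:
        raise ValueError(f"library file {path} missing columns {sorted(missing)}")
    if df["sirna_id"].duplicated().any():
        dups = df.loc[df["sirna_id"].duplicated(), "sirna_id"].tolist()
        raise ValueError(f"duplicate sirna_id(s) in library: {dups[:5]}")
    df["guide_seq"] = [
        normalize_sequence(s, name) for s, name in zip(df["guide_seq"], df["sirna_id"])
    ]
    return df


def library_records(library: pd.DataFrame) -> list[SiRNARecord]:
    return [
        SiRNARecord(sirna_id=r.sirna_id, gene_id=r.gene_id, guide_seq=r.guide_seq)
        for r in library.itertuples(index=False)
    ]


def read_measurements(path) -> pd.DataFrame:
    """Measurement CSV/TSV (separator sniffed from the extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement file {path} missing columns {sorted(missing)}")
    return df


def write_score_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_score_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_seed_index(index: SeedIndex, path) -> None:
    rows = [
        {
            "seed": seed,
            "length": index.length,
            "size": len(ids),
            "sirna_ids": ",".join(ids),
        }
        for seed, ids in index.members.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_seed_list(path) -> list[str]:
    """One seed per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        return [
            normalize_sequence(line.strip())
            for line in fh
            if line.strip() and not line.startswith("#")
        ]


def write_seed_list(seeds, path) -> None:
    with open(path, "w") as fh:
        for s in seeds:
            fh.write(f"{s}\n")
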