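"""Packaged reference fixtures.

Small published result tables shipped with the package so the counting,
thresholding and matching logic is testable without any external
download:

- ``table1.tsv`` — the top-20 screen siRNAs with scores, hexamer and
  heptamer seeds, confirmation status (Hit / OTE / Unconfirmed /
  False +ve) and an enriched-seed flag ('+' carries an enriched seed,
  '*' repeated seed not in the enriched set, '-' neither);
- ``table2.tsv`` — seeds enriched in high-scoring siRNAs, with set
  size, normalized enrichment score and FWER p;
- ``table3.tsv`` — enriched seeds present in human miRNAs;
- ``known_trail_genes.txt`` — twelve genes previously associated with
  TRAIL-induced apoptosis, used for the masking rescue analysis;
- ``mirna_mature.fa`` — mature sequences of the three matched human
  miRNAs (miRBase accessions in the headers).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "fixture_path",
    "load_table1",
    "load_table2",
    "load_table3",
    "load_known_trail_genes",
    "mirna_fasta_path",
]


def fixture_path(name: str):
    """Filesystem path of a packaged fixture file."""
    path = resources.files(__package__).joinpath(name)
    if not path.is_file():
        raise FileNotFoundError(f"no packaged fixture named {name!r}")
    return path


def load_table1() -> pd.DataFrame:
    """Top-20 siRNA table: seeds, confirmation status, enriched flag."""
    return pd.read_csv(fixture_path("table1.tsv"), sep="\t")


def load_table2() -> pd.DataFrame:
    """Enriched-seed table: seed, seed_length, size, nes, fwer_p."""
    return pd.read_csv(fixture_path("table2.tsv"), sep="\t")


def load_table3() -> pd.DataFrame:
    """Seed-to-miRNA pairs."""
    return pd.read_csv(fixture_path("table3.tsv"), sep="\t")


def load_known_trail_genes() -> list[str]:
    """The 12-gene known-TRAIL-pathway list."""
    text = fixture_path("known_trail_genes.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def mirna_fasta_path():
    """Path of the packaged 3-miRNA mature FASTA."""
    return fixture_path("mirna_mature.fa")
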