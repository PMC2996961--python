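"""Matching enriched screen seeds to mature miRNA seeds.

A transfected siRNA behaves like an over-expressed miRNA with the same
seed, so a seed enriched among high-scoring screen siRNAs may point at
an endogenous miRNA regulating the assayed pathway.  This module parses
a miRBase-style mature-sequence FASTA and reports miRNAs whose seed
(nucleotides 2..k+1 of the mature sequence) matches an enriched seed.

Orientation is subtle: depending on whether the screen library file
lists guide or passenger strands, a biologically equivalent match shows
up either as an identical seed or as its reverse complement.  Both
modes are provided and the default reports the union with an
orientation label.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

from .seed_tools import normalize_sequence, revcomp

__all__ = ["MiRNARecord", "read_mature_fasta", "mirna_seed", "match_seeds"]

logger = logging.getLogger(__name__)

_RNA = set("ACGU")


@dataclass(frozen=True)
class MiRNARecord:
    """A mature miRNA: name (e.g. hsa-miR-26a), optional accession, RNA 5'->3'."""

    name: str
    mature_seq: str
    accession: str | None = None

    def __post_init__(self) -> None:
        seq = str(self.mature_seq).strip().upper().replace("T", "U")
        bad = set(seq) - _RNA
        if bad:
            raise ValueError(f"illegal character(s) {sorted(bad)} in {self.name}")
        if len(seq) < 8:
            raise ValueError(f"mature sequence of {self.name} shorter than 8 nt")
        object.__setattr__(self, "mature_seq", seq)


def read_mature_fasta(path, human_only: bool = True) -> list[MiRNARecord]:
    """Parse a miRBase mature.fa-style file.

    Headers are expected to start with the miRNA name token, optionally
    followed by an accession.  With ``human_only`` (default) only
    ``hsa-`` prefixed names are retained.  Empty files, duplicate names
    and illegal characters raise.
    """
    records: list[MiRNARecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = rec.description.split()
        name = tokens[0]
        accession = tokens[1] if len(tokens) > 1 else None
        if len(rec.seq) == 0:
            raise ValueError(f"miRNA {name} has an empty sequence")
        if human_only and not name.startswith("hsa-"):
            continue
        if name in seen:
            raise ValueError(f"duplicate miRNA name {name!r}")
        seen.add(name)
        records.append(MiRNARecord(name=name, mature_seq=str(rec.seq), accession=accession))
    if not records:
        raise ValueError(f"no miRNA records parsed from {path}")
    return records


def mirna_seed(record: MiRNARecord, length: int = 6) -> str:
    """Seed of a mature miRNA: positions 2..length+1, returned as DNA."""
    if len(record.mature_seq) < length + 1:
        raise ValueError(
            f"{record.name}: mature sequence too short for a {length}-mer seed"
        )
    return normalize_sequence(record.mature_seq[1 : length + 1])


def match_seeds(
    enriched_seeds,
    mirnas: list[MiRNARecord],
    seed_length: int = 6,
    mode: str = "both",
) -> pd.DataFrame:
    """Pair enriched screen seeds with miRNAs sharing a seed.

    A pair (seed, miRNA) is emitted when the enriched seed equals the
    miRNA seed (``identical``) or its reverse complement (``revcomp``);
    ``both`` unions the two with an ``orientation`` label.  miRNAs too
    short for the seed length are skipped with a warning.  Returns a
    DataFrame (seed, mirna_name, orientation) with unique rows.
    """
    if mode not in {"identical", "revcomp", "both"}:
        raise ValueError("mode must be 'identical', 'revcomp' or 'both'")
    seeds = []
    for s in enriched_seeds:
        s = normalize_sequence(s)
        if len(s) != seed_length:
            raise ValueError(f"enriched seed {s!r} is not a {seed_length}-mer")
        seeds.append(s)
    seed_set = set(seeds)

    rows = []
    for rec in mirnas:
        try:
            mseed = mirna_seed(rec, seed_length)
        except ValueError as exc:
            warnings.warn(str(exc), RuntimeWarning, stacklevel=2)
            continue
        if mode in {"identical", "both"} and mseed in seed_set:
            rows.append((mseed, rec.name, "identical"))
        if mode in {"revcomp", "both"}:
            rc = revcomp(mseed)
            if rc in seed_set:
                rows.append((rc, rec.name, "revcomp"))
    out = pd.DataFrame(rows, columns=["seed", "mirna_name", "orientation"])
    return out.drop_duplicates().sort_values(
        ["seed", "mirna_name", "orientation"]
    ).reset_index(drop=True)
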