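"""Seed extraction and k-mer indexing for siRNA guide strands.

The "seed" of an siRNA (or miRNA) is the stretch of nucleotides 2-7
(hexamer) or 2-8 (heptamer) counted from the 5' end of the guide strand.
Complementarity between this seed and sites in 3'UTRs drives miRNA-like
repression of unintended transcripts, the dominant source of off-target
phenotypes in RNAi screens.  Everything downstream of screen scoring —
multiplicity testing, set enrichment, masking, miRNA matching — operates
on seeds extracted here.

Sequences are normalized to uppercase DNA (U -> T) so that siRNA tables
written as DNA and miRNA FASTA written as RNA interoperate.
"""

from __future__ import annotations

from collections import Counter, OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

__all__ = [
    "SeedConfig",
    "SiRNARecord",
    "SeedIndex",
    "MultiplicitySummary",
    "normalize_sequence",
    "extract_seed",
    "build_seed_index",
    "top_k_seed_multiplicity",
    "swap_seed",
    "revcomp",
]

_DNA = frozenset("ACGT")


def normalize_sequence(seq: str, name: str | None = None) -> str:
    """Uppercase, map U to T, and validate against the DNA alphabet."""
    s = str(seq).strip().upper().replace("U", "T")
    bad = set(s) - _DNA
    if bad:
        who = f" in {name}" if name else ""
        raise ValueError(
            f"illegal nucleotide(s) {sorted(bad)}{who}: {seq!r}"
        )
    return s


@dataclass(frozen=True)
class SeedConfig:
    """Where seeds live on a guide strand.

    start is 1-based; the canonical seed starts at nucleotide 2.
    lengths are the seed sizes considered (hexamer and heptamer by
    default).
    """

    start: int = 2
    lengths: frozenset[int] = frozenset({6, 7})

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("seed start must be >= 1 (1-based)")
        if not set(self.lengths) <= set(range(5, 9)):
            raise ValueError("seed lengths must lie in 5..8")


DEFAULT_SEED_CONFIG = SeedConfig()


@dataclass(frozen=True)
class SiRNARecord:
    """One library entry: identifier, intended target gene, guide 5'->3'."""

    sirna_id: str
    gene_id: str
    guide_seq: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "guide_seq", normalize_sequence(self.guide_seq, self.sirna_id)
        )
        if len(self.guide_seq) < 8:
            raise ValueError(
                f"guide of {self.sirna_id} shorter than 8 nt: {self.guide_seq!r}"
            )


def extract_seed(
    guide_seq: str,
    length: int = 6,
    config: SeedConfig = DEFAULT_SEED_CONFIG,
    name: str | None = None,
) -> str:
    """Return the seed (positions start..start+length-1, 1-based) of a guide.

    U is mapped to T.  Raises ValueError, naming the offending siRNA when
    ``name`` is given, for short sequences or illegal characters.
    """
    seq = normalize_sequence(guide_seq, name)
    end = config.start + length - 1
    if len(seq) < end:
        who = f" ({name})" if name else ""
        raise ValueError(
            f"guide{who} of length {len(seq)} too short for a {length}-mer "
            f"seed at position {config.start}"
        )
    return seq[config.start - 1 : end]


@dataclass
class SeedIndex:
    """Partition of a library by seed: the 'gene sets' of the enrichment step.

    Every siRNA appears under exactly one seed per seed length, so the
    per-seed sizes sum to the library size.
    """

    length: int
    members: "OrderedDict[str, list[str]]" = field(default_factory=OrderedDict)

    @property
    def sizes(self) -> dict[str, int]:
        return {seed: len(ids) for seed, ids in self.members.items()}

    @property
    def n_sirnas(self) -> int:
        return sum(len(ids) for ids in self.members.values())

    def seed_of(self) -> dict[str, str]:
        """Invert the index: sirna_id -> seed."""
        return {sid: seed for seed, ids in self.members.items() for sid in ids}


def build_seed_index(
    library: Iterable[SiRNARecord],
    length: int = 6,
    config: SeedConfig = DEFAULT_SEED_CONFIG,
) -> SeedIndex:
    """Index a library by seed of the given length.

    Raises on duplicate sirna_id.  Seed order follows first occurrence;
    ids within a seed follow library order.
    """
    index = SeedIndex(length=length)
    seen: set[str] = set()
    for rec in library:
        if rec.sirna_id in seen:
            raise ValueError(f"duplicate sirna_id {rec.sirna_id!r} in library")
        seen.add(rec.sirna_id)
        seed = extract_seed(rec.guide_seq, length, config, name=rec.sirna_id)
        index.members.setdefault(seed, []).append(rec.sirna_id)
    return index


@dataclass(frozen=True)
class MultiplicitySummary:
    """Seed counts among the top-k siRNAs of a ranking."""

    k: int
    counts: Mapping[str, int]
    n_repeated: int  # seeds occurring >= 2 times
    max_count: int

    def n_with_count_ge(self, m: int) -> int:
        return sum(1 for c in self.counts.values() if c >= m)


def top_k_seed_multiplicity(
    ranked_ids: Sequence[str],
    seed_of: Mapping[str, str],
    k: int,
) -> MultiplicitySummary:
    """Count seed occurrences among the top-k ranked siRNAs."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(ranked_ids):
        raise ValueError(f"k={k} exceeds number of ranked siRNAs ({len(ranked_ids)})")
    top = list(ranked_ids[:k])
    missing = [sid for sid in top if sid not in seed_of]
    if missing:
        raise KeyError(f"no seed recorded for ranked siRNA(s) {missing}")
    counts = Counter(seed_of[sid] for sid in top)
    return MultiplicitySummary(
        k=k,
        counts=dict(counts),
        n_repeated=sum(1 for c in counts.values() if c >= 2),
        max_count=max(counts.values()),
    )


def swap_seed(
    sequence: str,
    new_seed: str,
    config: SeedConfig = DEFAULT_SEED_CONFIG,
) -> str:
    """Replace the seed positions of a guide with ``new_seed``.

    This is the in-silico version of the seed-swap construct: grafting a
    candidate seed into an otherwise inert carrier siRNA to test whether
    the seed alone produces a phenotype.
    """
    seq = normalize_sequence(sequence)
    new = normalize_sequence(new_seed)
    if len(new) not in config.lengths:
        raise ValueError(
            f"replacement seed length {len(new)} not in {sorted(config.lengths)}"
        )
    end = config.start + len(new) - 1
    if len(seq) < end:
        raise ValueError("sequence too short for seed replacement")
    return seq[: config.start - 1] + new + seq[end:]


def revcomp(sequence: str) -> str:
    """Reverse complement over the DNA alphabet (U normalized to T first)."""
    return str(Seq(normalize_sequence(sequence)).reverse_complement())
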