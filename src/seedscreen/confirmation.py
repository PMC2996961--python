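"""Rule system classifying screened genes from confirmation-assay evidence.

A top-scoring screen siRNA earns its gene one of four labels once the
confirmation assays (an independent phenotype assay plus qPCR
knockdown measurement for every available siRNA against the gene) are
in:

- FalsePositive: the screen siRNA's phenotype does not reproduce;
- Hit: at least two phenotype-positive siRNAs show real knockdown and
  every such knockdown is stronger (less target mRNA remaining) than
  that of every phenotype-negative siRNA — phenotype tracks on-target
  silencing;
- OffTarget: the phenotype reproduces but knockdown does not explain
  it — some phenotype-negative siRNA silences the target at least as
  well as a phenotype-positive one, or the phenotype-positive siRNAs do
  not knock the target down at all;
- Unconfirmed: reproducible but inconclusive — corroborating siRNAs
  neither phenocopy nor silence as strongly as the active one.

Special case: when the target transcript is undetectable in every
sample, three or more independent phenotype-positive siRNAs still count
as a Hit.

Knockdown comparisons use fraction of target mRNA remaining (lower =
stronger) with an absolute tolerance (default 0.05) so qPCR noise does
not decide a status.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = ["SiRNAEvidence", "GeneStatus", "Classification", "classify_gene",
           "phenotype_significance"]


class GeneStatus(str, Enum):
    HIT = "Hit"
    OFF_TARGET = "OTE"
    UNCONFIRMED = "Unconfirmed"
    FALSE_POSITIVE = "False +ve"


@dataclass(frozen=True)
class SiRNAEvidence:
    """Confirmation evidence for one siRNA against one gene.

    knockdown_fraction is the fraction of target mRNA remaining
    (0 = complete knockdown, 1 = none), or None when unmeasurable.
    """

    sirna_id: str
    gene_id: str
    phenotype_significant: bool
    knockdown_fraction: float | None = None
    expression_detectable: bool = True
    was_screen_sirna: bool = False

    def __post_init__(self) -> None:
        kd = self.knockdown_fraction
        if kd is not None and not 0 <= kd <= 1:
            raise ValueError(
                f"{self.sirna_id}: knockdown_fraction must lie in [0, 1], got {kd}"
            )


@dataclass(frozen=True)
class Classification:
    gene_id: str
    status: GeneStatus
    rationale: str


def classify_gene(
    evidence: Sequence[SiRNAEvidence],
    tolerance: float = 0.05,
    no_knockdown_threshold: float = 0.9,
) -> Classification:
    """Classify one gene from its siRNA confirmation evidence.

    ``tolerance`` is the absolute margin on knockdown-fraction
    comparisons; a phenotype-positive knockdown counts as stronger than
    a phenotype-negative one only if it beats it by more than the
    tolerance.  Fractions at or above ``no_knockdown_threshold`` count
    as "no knockdown".  Order of evidence rows never matters.
    """
    if not evidence:
        raise ValueError("no evidence rows supplied")
    genes = {e.gene_id for e in evidence}
    if len(genes) > 1:
        raise ValueError(f"evidence mixes genes {sorted(genes)}")
    gene = genes.pop()

    by_id: dict[str, SiRNAEvidence] = {}
    for e in evidence:
        prev = by_id.get(e.sirna_id)
        if prev is not None and prev != e:
            raise ValueError(f"contradictory evidence rows for {e.sirna_id}")
        by_id[e.sirna_id] = e
    rows = sorted(by_id.values(), key=lambda e: e.sirna_id)

    screen = [e for e in rows if e.was_screen_sirna]
    if not screen:
        raise ValueError(f"{gene}: no screen siRNA identified in evidence")
    if not any(e.phenotype_significant for e in screen):
        return Classification(
            gene, GeneStatus.FALSE_POSITIVE,
            "screen siRNA phenotype did not reproduce in the secondary assay",
        )

    positives = [e for e in rows if e.phenotype_significant]
    negatives = [e for e in rows if not e.phenotype_significant]

    if all(not e.expression_detectable for e in rows) and len(positives) >= 3:
        return Classification(
            gene, GeneStatus.HIT,
            f"target expression undetectable, but {len(positives)} independent "
            "siRNAs reproduce the phenotype",
        )

    pos_kd = [e.knockdown_fraction for e in positives
              if e.knockdown_fraction is not None]
    pos_real = [kd for kd in pos_kd if kd < no_knockdown_threshold]
    neg_kd = [e.knockdown_fraction for e in negatives
              if e.knockdown_fraction is not None]

    if len(pos_real) >= 2 and all(
        p < q - tolerance for p in pos_real for q in neg_kd
    ):
        return Classification(
            gene, GeneStatus.HIT,
            f"{len(pos_real)} phenotype-positive siRNAs knock down the target "
            "more strongly than every phenotype-negative siRNA",
        )
    if pos_kd and not pos_real:
        return Classification(
            gene, GeneStatus.OFF_TARGET,
            "phenotype-positive siRNAs show no target knockdown",
        )
    if pos_real and neg_kd and min(neg_kd) <= max(pos_real) + tolerance:
        return Classification(
            gene, GeneStatus.OFF_TARGET,
            "a phenotype-negative siRNA silences the target at least as "
            "strongly as a phenotype-positive one",
        )
    return Classification(
        gene, GeneStatus.UNCONFIRMED,
        "phenotype reproduces but corroborating siRNAs neither phenocopy "
        "nor silence the target as strongly",
    )


def phenotype_significance(
    treated: dict[str, Iterable[float]],
    control: Iterable[float],
    alpha: float = 0.05,
) -> dict[str, bool]:
    """Plumbing helper: per-siRNA significance calls from raw assay values.

    Two-sided t-test of log-transformed treated vs control values with
    Bonferroni correction over the tested siRNAs.
    """
    ctrl = np.log(np.asarray(list(control), dtype=float))
    n_tests = len(treated)
    out = {}
    for sid, values in treated.items():
        vals = np.log(np.asarray(list(values), dtype=float))
        p = stats.ttest_ind(vals, ctrl).pvalue
        out[sid] = bool(p * n_tests < alpha)
    return out
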