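# Methods

## Screen scoring model

Each well of an arrayed viability screen is read twice: pre-treatment
fluorescence `F_pre` (a proxy for cell number after transfection) and
post-treatment `F_post`. Survival is `F_post / F_pre`; wells with
`F_pre = 0` or a missing phase are flagged invalid with a reason rather
than silently dropped. The bottom 20% of valid sample wells by
pre-treatment fluorescence are removed per replicate across the whole
screen (not per plate): low pre-treatment signal means poor seeding or
toxic transfection, and a screen-level rank cut is deterministic
(ties broken by plate and well id) and reproducible. The filter
fraction is a parameter; exactly `floor(fraction · n)` wells go.

Log survival (natural log; any base cancels in the z score) is centred
on its plate median to absorb plate-to-plate effects, then converted to
a robust z score per replicate:

    z = (x − median(x)) / (1.4826 · MAD(x))

with median and MAD taken over all sample wells of the replicate
(per-plate MAD is available via `mad_scope="plate"`). The 1.4826 factor
makes the MAD consistent with the standard deviation of a normal
distribution, so z is interpretable in familiar units while staying
insensitive to the heavy tails a screen's genuine hits create. Control
wells never enter the median/MAD estimation; they serve the Z' factor

    Z' = 1 − 3(σ_pos + σ_neg) / |μ_pos − μ_neg|

which is undefined (an error, not a NaN) when control means coincide,
and degenerate plates (MAD = 0, as in a zero-noise simulation) yield
missing z scores with a warning, never ±∞.

An siRNA's score is the **minimum** of its replicate z scores — a
conservative summary requiring the phenotype in every replicate. If any
replicate z is missing (well filtered, MAD degenerate) the score is
missing and the siRNA is excluded from ranking; score tables still list
it. Ranking is descending by score, ties broken by siRNA id. Note the
attenuation this summary implies: the minimum of two standard-normal
replicates has mean ≈ −0.56, so a planted effect of δ z-units surfaces
as a score shift of roughly δ (both carrier and non-carrier scores are
shifted down together), with slightly reduced variance.

## Seeds

Seeds are read from the provided strand at 1-based positions 2..7
(hexamer) and 2..8 (heptamer); `U` is normalized to `T` everywhere so
DNA-written siRNA tables and RNA-written miRNA FASTA interoperate. If a
library file lists sense/target-strand sequences instead of guide
strands, the `--strand sense` option reverse-complements before
extraction. Published seed tables are typically printed in sense
orientation — recognizable because each heptamer there gains its extra
base at the 5' end of the printed string, whereas extraction from one
strand extends the hexamer at the 3' end — and the miRNA matcher's
orientation modes (`identical`, `revcomp`, `both`; default `both` with
an orientation label) cover exactly this ambiguity. The packaged
seed↔miRNA table reproduces under `revcomp`.

The seed index partitions the library: every siRNA falls under exactly
one seed per seed length, sizes sum to the library size, and the
per-seed member lists are the "gene sets" of the enrichment analysis.

## Multiplicity test

Observing the same seed on several top-k siRNAs is only surprising
relative to the library's seed composition. The null is sampled
directly: draw k siRNAs (without replacement by default, preserving
realized seed frequencies; with replacement behind a flag), record a
statistic of their seeds — `n_repeated` (distinct seeds seen ≥ 2
times), `max_count`, or `n_with_count_ge_m` — and repeat (default
5,000 iterations). The empirical p is add-one,
`p = (#{null ≥ obs} + 1)/(n_iter + 1)`, so p is never zero; when no
null sample reaches the observed value the report is the conventional
strict bound `P < 1/n_iter`. The sampler's collision rate on a
uniform-seed library matches the closed-form birthday probability
`1 − Π_{i<k}(1 − i/4096)`, which the validation suite checks within
Monte Carlo error.

## Pre-ranked enrichment of seed sets

The enrichment engine is written from scratch. Walking the ranked list,
members add `|s|^p / Σ_members |s|^p` (p = 1 by default; p = 0 gives
the classic unweighted statistic) and non-members subtract
`1/(N − n_set)`; the ES is the signed extremum of the running sum,
which starts and ends at exactly zero, so ES ∈ [−1, 1]. Only the
running-sum values immediately before and after each member can be
extrema, which the implementation exploits to score whole permutation
batches vectorially; an exact-rational brute-force enumeration verifies
every subset of a small list in the tests. Structural ties between the
positive and negative extremum (e.g. a contiguous member block) resolve
to the positive extreme, with a 1e-9 tolerance so floating-point noise
cannot flip the sign.

For pre-ranked input the only meaningful null is random member sets:
each of `n_perm` (default 1,000) permutations shuffles the universe
once, and every tested set takes its own **disjoint slice** of that
shuffle as its size-matched null set. Disjoint slices of a uniform
shuffle are uniform subsets, and their disjointness mirrors the real
structure of seed sets (a partition of the library); this matters for
the family-wide correction — giving all sets the same shuffle prefix
would make their null scores nearly identical within a permutation and
collapse the max-NES null.

NES divides the ES by the mean same-sign null ES. Three p-values are
reported per set: `p_nominal` (add-one fraction of same-sign null ES at
least as extreme — the usual per-set convention), `p_upper` (add-one
upper-tail fraction of *all* null ES at or above the observed ES — the
directional enrichment p, monotone in enrichment even when a buried set
shows negative ES, and therefore what before/after-masking comparisons
use), and `fwer_p` (fraction of permutations whose maximum same-sign
NES across all tested sets reaches the set's NES). Sets smaller than
`min_size` (default 5) are dropped with a warning; "enriched" means
FWER p ≤ 0.05 with NES > 0.

## Masking and rescue

Masking removes an siRNA when its hexamer or heptamer (seed position,
nt 2–7/2–8) is on the enriched list; a `substring` mode removing on any
occurrence anywhere in the guide exists for sensitivity analysis but
seed-position membership is the default, since the entire analysis is
framed on seed positions. Retained siRNAs keep their relative order and
are renumbered 1..m. The known-gene re-test builds the siRNA-level set
of all siRNAs targeting a supplied gene list (absent genes logged and
skipped) and runs the same enrichment engine on the masked and unmasked
rankings; the comparison statistic is `p_upper`.

## Confirmation rules

Evidence per siRNA: a boolean secondary-assay phenotype call, the
fraction of target mRNA remaining (lower = stronger knockdown; may be
unmeasurable), gene-level expression detectability, and whether the
siRNA was the screen siRNA. A gene is **False +ve** when no screen
siRNA's phenotype reproduces; **Hit** when ≥ 2 phenotype-positive
siRNAs show real knockdown, all stronger than every phenotype-negative
siRNA's; **OTE** when the phenotype reproduces but knockdown does not
explain it (a silent siRNA silences at least as well, or the active
siRNAs do not knock down at all); otherwise **Unconfirmed**. Two edge
rules: phenotype-positive siRNAs with no knockdown (fraction remaining
≥ 0.9) are excluded from the Hit comparison rather than counted
against it, and a gene whose transcript is undetectable in every sample
still counts as a Hit given ≥ 3 independent phenotype-positive siRNAs.
Knockdown comparisons carry an absolute tolerance (default 0.05) so
qPCR noise cannot decide a status; both the tolerance and the
no-knockdown threshold are parameters. The boundary between OTE and
Unconfirmed when knockdown is unmeasured for some siRNAs follows the
worked narrative cases and is deliberately conservative (inconclusive
evidence stays Unconfirmed).

## Synthetic screens

The generator emulates a genome-scale arrayed screen: `n_genes` × 2
random 21-nt guides, 96-well plates filled in library order with 6
positive-control, 2 transfection-control and 4 negative-control wells
each, two replicates, lognormal pre-treatment fluorescence
(meanlog 10, sdlog 0.25 — arbitrary plate-reader units), and latent
log-survival

    baseline + gene effect + seed effect + Normal(0, noise_sd)

with baseline log(0.3) (treatment kills ~70% of control cells),
positive controls at +3 z-units (strongly protective), the transfection
control at −3 (a cell-lethal knockdown), and noise_sd 1.0. Planted
seeds force a hexamer into nt 2–7 of a chosen number of carriers;
carriers are drawn from genes *without* planted gene effects so the two
effect sources stay disjoint in ground truth, and chance carriers
(guides that independently read a planted hexamer) receive the effect
too, flagged separately. Not modelled: spatial plate artifacts, edge
effects, transfection-efficiency gradients, guide-position or
thermodynamic seed-strength variation, and correlated off-target sets —
so passing recovery tests demonstrates the statistics under clean
additive effects, not robustness to those real-data pathologies.

## Validation experiments

Because the screens these methods were developed on ship no reusable raw
data, their published assay-specific numbers (the 0.46 Z', the
library-specific sampling p-values, NES magnitudes) are not
recomputable; the package instead validates the machinery on synthetic
screens with known truth:

- **Recovery**: 50 screens of 3,000 siRNAs, one hexamer planted at
  +2 z-units on 30 carriers, plus 100 effect-free decoy hexamers forced
  onto 10 carriers each so the decoys form genuine testable sets.
  Requirement: the planted seed is flagged at FWER ≤ 0.05 in ≥ 90% of
  runs, some decoy in ≤ 5% of runs. Observed (seed streams 1 and 2):
  power 50/50, decoy runs 2/50 and 1/50.
- **Rescue**: 50 screens of 1,000 siRNAs; 12 known genes at +1 z-unit,
  five interfering hexamers at +2 on 40 carriers each planted on other
  genes (mirroring the multi-seed interference real screens show).
  Enriched seeds are detected from the data (not read from truth),
  masked, and the known-gene set re-tested. Requirement: `p_upper`
  improves in ≥ 80% of runs; observed 1.0/0.98/1.0 across three seed
  streams, median p ≈ 0.18 → 0.002.
- **Calibration**: nominal enrichment p-values of 10,000 random sets on
  a random ranking are uniform (KS distance < 0.05); the multiplicity
  sampler's p-values are super-uniform under resampled nulls; the
  birthday collision rate matches the closed form within 3 Monte Carlo
  standard errors.
- **Determinism**: all randomness flows through explicit integer seeds;
  identical seeds give identical libraries, measurements, enrichment
  tables and pipeline summaries.

Problem sizes (1,000–3,000 siRNAs, 50 runs, 200–2,000 permutations)
were chosen to give the binomial assertions comfortable margins while
keeping a full validation pass in tens of seconds on one CPU.

## Known limitations

- The enrichment null is random-set (gene-tag) permutation only; no
  phenotype permutation, no leading-edge reporting.
- FWER is the only family-wise correction offered; with thousands of
  seed sets an FDR view would be less conservative but is out of scope.
- Seed matching is exact k-mer equality; no GU wobble, no 3'UTR site
  counting, no conservation or context scoring.
- The confirmation rules encode a specific lab workflow; labs with
  different evidence structures will need to map onto the evidence
  schema.
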