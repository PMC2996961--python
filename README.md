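# seedscreen

Seed-sequence off-target analysis for arrayed siRNA screens.

## The problem

siRNAs silence more than their intended targets: loaded into the RNA-induced
silencing complex they behave like microRNAs, repressing any transcript whose
3'UTR matches their *seed* — nucleotides 2–7 (hexamer) or 2–8 (heptamer) at
the 5' end of the guide strand. In phenotypic screens this is not a nuisance
that averages out; selection actively enriches the top of the hit list for
siRNAs whose seeds happen to perturb the assayed pathway. A gene "confirmed"
by two screen siRNAs can still be a seed artifact when both carry an active
seed.

`seedscreen` packages a systematic treatment of this problem:

1. **Robust screen scoring** — per-well survival (post/pre-treatment
   fluorescence), removal of the bottom 20% of wells by pre-treatment
   viability, log transform, plate-median centring, a robust z score
   `z = (x − median x) / (1.4826 · MAD x)` per replicate, and the minimum
   over replicates as the per-siRNA score; assay quality via the Z' factor
   `Z' = 1 − 3(σ₊ + σ₋)/|μ₊ − μ₋|`.
2. **Seed multiplicity testing** — are repeated seeds among the top-k siRNAs
   surprising given the library's seed composition? Monte Carlo samples of k
   siRNAs give an add-one empirical p, `p = (#{null ≥ obs} + 1)/(n + 1)`.
3. **Pre-ranked set enrichment** — a from-scratch weighted
   Kolmogorov–Smirnov-style enrichment analysis over seed-defined siRNA
   sets: enrichment score ES ∈ [−1, 1], normalized enrichment score (NES)
   against size-matched random-set nulls, and a family-wide error rate
   (FWER) p from the permutation distribution of the maximum NES over all
   seed sets. Seeds with FWER p ≤ 0.05 and NES > 0 are "enriched".
4. **Masking and re-analysis** — remove every siRNA carrying an enriched
   seed, re-rank, and re-test a known-pathway gene set; improved enrichment
   after masking reveals true hits previously buried by off-target noise.
5. **miRNA matching** — enriched seeds are matched against mature miRNA
   seeds (miRBase-style FASTA) in both orientations, nominating endogenous
   miRNAs that may regulate the assayed pathway.
6. **Confirmation logic** — the rule system classifying each screened gene
   as Hit / OTE (off-target) / Unconfirmed / False +ve from secondary-assay
   phenotypes and qPCR knockdown levels.
7. **Synthetic screens** — a generator of arrayed 96-well screens with
   planted gene and seed effects, so every stage is testable end to end
   without proprietary screen data.

Packaged fixtures transcribe the published top-20 siRNA table, the
enriched-seed table, the seed↔miRNA table and the 12-gene known-TRAIL-gene
list, so the counting, thresholding and matching logic is verifiable
offline.

## Worked example

Simulate a 600-siRNA screen with the hexamer `ACTTGA` planted at +2 z-units
on 30 guides, then run the full pipeline:

```bash
seedscreen simulate --n-genes 300 --plant ACTTGA:2.0:30 --seed 17 \
    --out-dir demo/sim
seedscreen run --library demo/sim/library.tsv \
    --measurements demo/sim/measurements.tsv \
    --mirna-fasta "$(python -c 'from seedscreen import data; print(data.mirna_fasta_path())')" \
    --out-dir demo/out --n-iter 1000 --n-perm 500 --seed 11
```

prints

```
{"n_sirnas": 600, "n_measurement_rows": 2784}
{"out_dir": "demo/out", "n_enriched": {"6": 1, "7": 2}}
```

and `demo/out/summary.json` contains (excerpt):

```
enriched_seeds:  {"6": ["ACTTGA"], "7": ["ACTTGAC", "ACTTGAT"]}
topk_test["6"]["max_count"]:  {"observed": 14, "convention": "P < 0.001"}
n_masked: 20
mirna_matches: [{"seed": "ACTTGA", "mirna_name": "hsa-miR-26a",
                 "orientation": "revcomp"}]
```

Reading: of the 20 top-scoring siRNAs, 14 share one hexamer — essentially
impossible under random sampling from this library (P < 0.001 at 1,000
iterations). The enrichment analysis flags exactly the planted seed (and its
two heptamer extensions) at FWER ≤ 0.05; 20 carrier siRNAs are masked from
the re-ranked list; and the seed matches the seed region of hsa-miR-26a
under reverse complement. Stage outputs (`scores.tsv`, `seed_index_*.tsv`,
`enrichment_*.tsv`, `masked_ranking.tsv`, `mirna_matches.tsv`) land next to
the summary.

The same analyses are available per stage (`seedscreen score`, `seeds`,
`topk-test`, `gsea`, `mask`, `rerank-test`, `mirna`, `fixtures`), and the
library API mirrors the stages module by module.

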