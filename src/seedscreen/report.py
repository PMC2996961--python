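"""Summary accounting of a confirmed top-k siRNA table.

Works on tables shaped like the packaged top-20 fixture: one row per
top-scoring siRNA with hexamer/heptamer seed columns, a confirmation
``status`` (Hit / OTE / Unconfirmed / False +ve) and an
``enriched_flag`` ('+' = carries an enriched seed).  The counts
summarize how much of a screen's top list is explained by on-target
biology versus seed-driven off-target effects.
"""

from __future__ import annotations

import pandas as pd

from .seed_tools import top_k_seed_multiplicity

__all__ = ["top_hits_report"]

REPRODUCIBLE_STATUSES = {"Hit", "OTE", "Unconfirmed"}


def top_hits_report(table: pd.DataFrame, top_fraction_k: int = 7) -> dict:
    """Count seed multiplicities and status/flag combinations.

    Expects columns symbol, score, hexamer, heptamer, status,
    enriched_flag, sorted by score descending (re-sorted defensively).
    ``top_fraction_k`` controls the "top slice" count (how many of the
    very best k siRNAs carry an enriched seed).
    """
    required = {"symbol", "score", "hexamer", "heptamer", "status", "enriched_flag"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns {sorted(missing)}")
    df = table.sort_values("score", ascending=False, kind="mergesort").reset_index(
        drop=True
    )
    k = len(df)
    ids = df["symbol"].tolist()

    hex_mult = top_k_seed_multiplicity(ids, dict(zip(ids, df["hexamer"])), k)
    hept_mult = top_k_seed_multiplicity(ids, dict(zip(ids, df["heptamer"])), k)

    reproducible = df[df["status"].isin(REPRODUCIBLE_STATUSES)]
    enriched = df["enriched_flag"] == "+"
    off_target = df["status"] == "OTE"
    hit = df["status"] == "Hit"

    repro_enriched = reproducible[reproducible["enriched_flag"] == "+"]
    top_slice = df.head(top_fraction_k)

    return {
        "k": k,
        "n_repeated_hexamers": hex_mult.n_repeated,
        "max_hexamer_multiplicity": hex_mult.max_count,
        "n_repeated_heptamers": hept_mult.n_repeated,
        "n_heptamers_exactly_twice": sum(
            1 for c in hept_mult.counts.values() if c == 2
        ),
        "hexamer_counts": hex_mult.counts,
        "n_reproducible": len(reproducible),
        "n_reproducible_with_enriched_seed": len(repro_enriched),
        "n_top_slice_with_enriched_seed": int(
            (top_slice["enriched_flag"] == "+").sum()
        ),
        "n_off_target": int(off_target.sum()),
        "n_off_target_with_enriched_seed": int((off_target & enriched).sum()),
        "n_explained_by_hit_or_seed": int(
            (df["status"].isin(REPRODUCIBLE_STATUSES) & (hit | enriched)).sum()
        ),
        "seed_count_in_reproducible": {
            seed: int((reproducible["hexamer"] == seed).sum())
            for seed in sorted(set(df["hexamer"]))
            if (reproducible["hexamer"] == seed).sum() > 0
        },
    }
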