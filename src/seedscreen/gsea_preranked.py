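"""Pre-ranked set enrichment analysis over seed-defined siRNA sets.

A weighted Kolmogorov-Smirnov-like statistic asks whether the members of
a set (here: all siRNAs sharing one seed) concentrate at the top of a
ranked list.  Walking down the ranking, the running sum gains
|score|^p / sum_members |score|^p at each member ("hit") and loses
1/(N - n_set) at each non-member ("miss"); the enrichment score (ES) is
the signed maximum deviation of this running sum from zero, so
ES in [-1, 1].

Significance is calibrated against random member sets of equal size
drawn from the ranked universe — the only meaningful null for
pre-ranked input.  The normalized score (NES) divides the ES by the
mean of same-sign null scores; the family-wide error rate (FWER) p of a
set is the fraction of permutations in which the maximum same-sign NES
across *all* sets reaches that set's NES.  One shuffle of the universe
per permutation supplies a disjoint size-matched null set for every
tested set — mirroring the disjointness of the real seed sets — so the
per-permutation maxima behave like the family they correct for.

Seeds with FWER p <= 0.05 and positive NES are called "enriched":
over-represented among high-scoring siRNAs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "make_ranked",
    "enrichment_score",
    "calibrate",
    "select_enriched",
]

logger = logging.getLogger(__name__)


def make_ranked(ids, scores) -> pd.DataFrame:
    """Build a ranked list: scores descending, ties broken by id.

    Returns a DataFrame (item_id, score) in rank order; ids must be
    unique.
    """
    df = pd.DataFrame({"item_id": list(ids), "score": np.asarray(scores, dtype=float)})
    if df["item_id"].duplicated().any():
        raise ValueError("ranked list ids must be unique")
    if df["score"].isna().any():
        raise ValueError("ranked list scores must not be missing")
    return df.sort_values(
        ["score", "item_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def _es_batch(
    positions: np.ndarray, weights: np.ndarray, n_total: int
) -> np.ndarray:
    """ES for a batch of equally sized sets given by sorted hit positions.

    ``positions``: (n_batch, n_set) 0-based ranks, sorted ascending per
    row.  ``weights``: |score|^p at every rank, shape (n_total,).  The
    running sum is piecewise linear between hits, so only the values
    just after each hit (local maxima candidates) and just before each
    hit (local minima candidates) need inspecting; it starts and ends at
    exactly zero.
    """
    n_batch, n_set = positions.shape
    if n_set == 0 or n_set >= n_total:
        raise ValueError("set must be non-empty and a strict subset of the universe")
    w = weights[positions]  # (n_batch, n_set)
    tot = w.sum(axis=1, keepdims=True)
    # all-zero weight rows (e.g. p_weight>0 with all member scores 0)
    # degrade to the unweighted statistic
    flat = (tot == 0).ravel()
    if flat.any():
        w = w.copy()
        w[flat] = 1.0
        tot = w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1) / tot
    miss = 1.0 / (n_total - n_set)
    i = np.arange(n_set)
    n_misses_before = positions - i  # misses strictly before hit i
    after = cum - miss * n_misses_before  # running sum just after hit i
    before = after - w / tot  # running sum just before hit i
    max_pos = np.maximum(after.max(axis=1), 0.0)
    min_neg = np.minimum(before.min(axis=1), 0.0)
    # exact |max| == |min| ties are structural (e.g. a contiguous member
    # block); resolve them to the positive extreme, with a tolerance so
    # floating-point noise cannot flip the choice
    return np.where(max_pos >= -min_neg - 1e-9, max_pos, min_neg)


def enrichment_score(
    ranked: pd.DataFrame,
    members,
    p_weight: float = 1.0,
    return_profile: bool = False,
):
    """ES of one member set against a ranked list.

    ``members`` is an iterable of item ids; it must be a non-empty
    strict subset of the ranked universe.  With ``return_profile=True``
    also returns the length-N running-sum profile (value after each
    position).
    """
    ids = ranked["item_id"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    n = len(ids)
    member_set = set(members)
    unknown = member_set - set(ids)
    if unknown:
        raise KeyError(f"set member(s) not in ranked universe: {sorted(unknown)[:5]}")
    hit = np.isin(ids, list(member_set))
    n_set = int(hit.sum())
    if n_set == 0 or n_set == n:
        raise ValueError("set must be non-empty and a strict subset of the universe")
    weights = np.abs(scores) ** p_weight
    positions = np.flatnonzero(hit)[None, :]
    es = float(_es_batch(positions, weights, n)[0])
    if not return_profile:
        return es
    tot = weights[hit].sum()
    hit_steps = weights / tot if tot > 0 else np.full(n, 1.0 / n_set)
    steps = np.where(hit, hit_steps, -1.0 / (n - n_set))
    profile = np.cumsum(steps)
    return es, profile


def calibrate(
    ranked: pd.DataFrame,
    sets: dict[str, list],
    n_perm: int = 1000,
    p_weight: float = 1.0,
    min_size: int = 5,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """ES/NES/nominal-p/FWER-p for every set against a permutation null.

    ``p_nominal`` follows the same-sign convention (fraction of same-sign
    null ES at least as extreme, add-one); ``p_upper`` is the
    directional enrichment p, the add-one upper-tail fraction of all
    null ES at or above the observed ES — monotone in enrichment even
    for sets with negative ES, which is what before/after comparisons
    should use.

    Null sets are size-matched random subsets of the universe; one
    shuffle per permutation supplies a disjoint null set for every
    tested set, and the FWER p of a set is the fraction of permutations whose
    maximum same-sign NES over all sets is at least as extreme as the
    set's NES.  Sets smaller than ``min_size`` are dropped with a
    warning.  Deterministic for a fixed ``rng_seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable null")
    ids = ranked["item_id"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    n = len(ids)
    pos_of = {item: i for i, item in enumerate(ids)}
    weights = np.abs(scores) ** p_weight

    kept: list[tuple[str, np.ndarray]] = []
    for name, members in sets.items():
        uniq = sorted(set(members))
        unknown = [m for m in uniq if m not in pos_of]
        if unknown:
            raise KeyError(
                f"set {name!r}: member(s) not in ranked universe: {unknown[:5]}"
            )
        if len(uniq) < min_size:
            logger.warning(
                "set %s dropped: size %d < min_size %d", name, len(uniq), min_size
            )
            continue
        if len(uniq) >= n:
            raise ValueError(f"set {name!r} covers the whole universe")
        kept.append((name, np.sort(np.array([pos_of[m] for m in uniq]))))
    if not kept:
        return pd.DataFrame(
            columns=["set", "size", "es", "nes", "p_nominal", "p_upper", "fwer_p"]
        )

    rng = np.random.default_rng(rng_seed)
    # One shuffled universe per permutation; each tested set takes its
    # own disjoint slice of the shuffle as its null member set.  Slices
    # of a uniform shuffle are uniform size-matched subsets, and their
    # disjointness mirrors the real structure of seed sets (a partition
    # of the library), keeping the per-permutation null scores of
    # different sets nearly independent — essential for a calibrated
    # max-NES family-wide correction.  When the combined set sizes
    # exceed the universe, additional shuffles are drawn.
    pools = [np.argsort(rng.random((n_perm, n)), axis=1)]
    slice_of: list[tuple[int, int]] = []
    cursor = 0
    for _, p in kept:
        if cursor + len(p) > n:
            pools.append(np.argsort(rng.random((n_perm, n)), axis=1))
            cursor = 0
        slice_of.append((len(pools) - 1, cursor))
        cursor += len(p)

    names = [name for name, _ in kept]
    sizes = [len(p) for _, p in kept]
    obs_es = np.array(
        [_es_batch(p[None, :], weights, n)[0] for _, p in kept]
    )
    null_es = np.empty((len(kept), n_perm))
    for j, (_, p) in enumerate(kept):
        pool_i, off = slice_of[j]
        null_pos = np.sort(pools[pool_i][:, off : off + len(p)], axis=1)
        null_es[j] = _es_batch(null_pos, weights, n)

    # sign-specific normalization: divide by the mean same-sign null ES
    pos_mean = np.array(
        [row[row > 0].mean() if (row > 0).any() else np.nan for row in null_es]
    )
    neg_mean = np.array(
        [(-row[row < 0]).mean() if (row < 0).any() else np.nan for row in null_es]
    )

    def _normalize(es_vals: np.ndarray, j: int) -> np.ndarray:
        scale = np.where(es_vals >= 0, pos_mean[j], neg_mean[j])
        with np.errstate(invalid="ignore"):
            return es_vals / scale

    nes = np.array([_normalize(np.array([obs_es[j]]), j)[0] for j in range(len(kept))])
    null_nes = np.vstack([_normalize(null_es[j], j) for j in range(len(kept))])

    p_nominal = np.empty(len(kept))
    p_upper = np.empty(len(kept))
    for j in range(len(kept)):
        row = null_es[j]
        if obs_es[j] >= 0:
            same = row[row >= 0]
            extreme = int((same >= obs_es[j]).sum())
        else:
            same = row[row < 0]
            extreme = int((same <= obs_es[j]).sum())
        p_nominal[j] = (extreme + 1) / (len(same) + 1)
        # directional enrichment p: upper tail over the whole null,
        # monotone in ES even when the observed ES is negative
        p_upper[j] = (int((row >= obs_es[j]).sum()) + 1) / (n_perm + 1)

    with np.errstate(invalid="ignore"):
        pos_masked = np.where(null_nes > 0, null_nes, -np.inf)
        neg_masked = np.where(null_nes < 0, null_nes, np.inf)
    max_pos = pos_masked.max(axis=0)  # per permutation
    min_neg = neg_masked.min(axis=0)
    fwer = np.empty(len(kept))
    for j in range(len(kept)):
        if np.isnan(nes[j]):
            fwer[j] = np.nan
        elif nes[j] >= 0:
            fwer[j] = float((max_pos >= nes[j]).mean())
        else:
            fwer[j] = float((min_neg <= nes[j]).mean())

    out = pd.DataFrame(
        {
            "set": names,
            "size": sizes,
            "es": obs_es,
            "nes": nes,
            "p_nominal": p_nominal,
            "p_upper": p_upper,
            "fwer_p": fwer,
        }
    )
    return out.sort_values(
        ["nes", "set"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def select_enriched(
    results: pd.DataFrame,
    fwer_threshold: float = 0.05,
    seed_column: str | None = None,
) -> pd.DataFrame:
    """Sets enriched at the top: FWER p <= threshold and NES > 0.

    Accepts any DataFrame with ``nes`` and ``fwer_p`` columns (e.g. a
    calibration result or a published result table).  Returns rows
    sorted by NES descending.
    """
    if not 0 <= fwer_threshold <= 1:
        raise ValueError("fwer_threshold must lie in [0, 1]")
    required = {"nes", "fwer_p"}
    if not required <= set(results.columns):
        raise ValueError(f"results table needs columns {sorted(required)}")
    hit = results[(results["fwer_p"] <= fwer_threshold) & (results["nes"] > 0)]
    return hit.sort_values("nes", ascending=False, kind="mergesort").reset_index(
        drop=True
    )
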