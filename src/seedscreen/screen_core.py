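"""Robust scoring of arrayed viability screens.

The pipeline converts raw pre/post-treatment fluorescence into one score
per siRNA:

1. survival = post / pre per well;
2. wells in the bottom 20% of pre-treatment fluorescence are dropped
   (cells that failed to seed or transfect poorly);
3. log(survival) is centred on its plate median to remove plate effects;
4. each replicate is converted to a robust z score,
   z = (x - median(x)) / (1.4826 * MAD(x)), over the replicate's sample
   wells (the 1.4826 factor makes the MAD consistent with the normal
   standard deviation);
5. the minimum over replicates represents the siRNA, a conservative
   summary that demands the effect in every replicate.

Higher scores mean more treatment-resistant.  Control wells never enter
the median/MAD estimation; they feed the Z' assay-quality metric
instead.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "MEASUREMENT_COLUMNS",
    "compute_survival",
    "filter_low_viability",
    "robust_z",
    "score_replicate",
    "summarize_min_replicate",
    "score_screen",
    "zprime",
]

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = [
    "plate",
    "well",
    "replicate",
    "phase",
    "fluorescence",
    "role",
    "sirna_id",
]

_ROLES = {"sample", "pos_ctrl", "neg_ctrl", "transfection_ctrl", "empty"}
MAD_TO_SD = 1.4826


def compute_survival(measurements: pd.DataFrame) -> pd.DataFrame:
    """Pair pre and post rows per well and compute survival = post / pre.

    Returns one row per (plate, well, replicate) with columns
    ``pre, post, survival, role, sirna_id, valid, reason``.  Wells with a
    missing phase or zero pre-treatment fluorescence are kept but flagged
    invalid with a reason, never silently dropped.  Duplicate
    (plate, well, replicate, phase) rows are a hard error.
    """
    df = measurements.copy()
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement table missing columns {sorted(missing)}")
    bad_phase = set(df["phase"].unique()) - {"pre", "post"}
    if bad_phase:
        raise ValueError(f"unknown phase value(s) {sorted(bad_phase)}")
    bad_role = set(df["role"].unique()) - _ROLES
    if bad_role:
        raise ValueError(f"unknown role value(s) {sorted(bad_role)}")
    if (df["fluorescence"] < 0).any():
        raise ValueError("negative fluorescence value in measurements")

    key = ["plate", "well", "replicate", "phase"]
    dup = df.duplicated(key)
    if dup.any():
        first = df.loc[dup, key].iloc[0].tolist()
        raise ValueError(f"duplicate measurement for (plate, well, replicate, phase)={first}")

    wide = (
        df.pivot_table(
            index=["plate", "well", "replicate"],
            columns="phase",
            values="fluorescence",
            aggfunc="first",
        )
        .reindex(columns=["pre", "post"])
        .reset_index()
    )
    wide.columns.name = None
    meta = df[["plate", "well", "replicate", "role", "sirna_id"]].drop_duplicates(
        ["plate", "well", "replicate"]
    )
    wide = wide.merge(meta, on=["plate", "well", "replicate"], how="left")

    wide["valid"] = True
    wide["reason"] = ""
    no_pre = wide["pre"].isna()
    no_post = wide["post"].isna()
    zero_pre = wide["pre"] == 0
    wide.loc[no_pre, ["valid", "reason"]] = [False, "missing pre-treatment reading"]
    wide.loc[no_post, ["valid", "reason"]] = [False, "missing post-treatment reading"]
    wide.loc[zero_pre, ["valid", "reason"]] = [False, "pre-treatment fluorescence is zero"]
    n_bad = int((~wide["valid"]).sum())
    if n_bad:
        logger.warning("%d well(s) flagged invalid: %s", n_bad,
                       wide.loc[~wide["valid"], "reason"].value_counts().to_dict())

    with np.errstate(divide="ignore", invalid="ignore"):
        wide["survival"] = np.where(wide["valid"], wide["post"] / wide["pre"], np.nan)
    return wide


def filter_low_viability(wells: pd.DataFrame, fraction: float = 0.2) -> pd.DataFrame:
    """Drop the lowest-viability sample wells per replicate.

    Exactly ``floor(fraction * n_sample_wells)`` valid sample wells are
    removed per replicate, lowest pre-treatment fluorescence first with
    ties broken by (plate, well) so the cut is deterministic.  Control
    wells are never removed.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    out = []
    for rep, grp in wells.groupby("replicate", sort=True):
        samples = grp[(grp["role"] == "sample") & grp["valid"]]
        n_remove = math.floor(fraction * len(samples))
        if n_remove:
            drop_idx = samples.sort_values(
                ["pre", "plate", "well"], kind="mergesort"
            ).index[:n_remove]
            grp = grp.drop(index=drop_idx)
            logger.info("replicate %s: removed %d low-viability wells", rep, n_remove)
        out.append(grp)
    return pd.concat(out, axis=0) if out else wells.iloc[0:0]


def robust_z(values: np.ndarray) -> np.ndarray:
    """Median/MAD z score; all-NaN with a warning when the MAD is zero."""
    x = np.asarray(values, dtype=float)
    med = np.nanmedian(x)
    mad = np.nanmedian(np.abs(x - med))
    if mad == 0 or np.isnan(mad):
        warnings.warn(
            "MAD is zero; z scores undefined for this group", RuntimeWarning,
            stacklevel=2,
        )
        return np.full_like(x, np.nan)
    return (x - med) / (MAD_TO_SD * mad)


def score_replicate(
    wells: pd.DataFrame,
    replicate: int,
    mad_scope: str = "replicate",
) -> pd.DataFrame:
    """Robust z scores for the sample wells of one replicate.

    log(survival) is centred on the plate median (sample wells only),
    then converted to z with median/MAD taken over all sample wells of
    the replicate (``mad_scope='replicate'``, default) or per plate
    (``mad_scope='plate'``).  Returns (plate, well, sirna_id, log_survival,
    normalized, z).
    """
    if mad_scope not in {"replicate", "plate"}:
        raise ValueError("mad_scope must be 'replicate' or 'plate'")
    sub = wells[
        (wells["replicate"] == replicate) & (wells["role"] == "sample") & wells["valid"]
    ].copy()
    if sub.empty:
        raise ValueError(f"no valid sample wells for replicate {replicate}")
    counts = sub.groupby("plate").size()
    thin = counts[counts < 3]
    if not thin.empty:
        raise ValueError(
            f"plate(s) {list(thin.index)} have fewer than 3 surviving sample wells"
        )
    if (sub["survival"] <= 0).any():
        raise ValueError("non-positive survival ratio among valid sample wells")

    sub["log_survival"] = np.log(sub["survival"])
    sub["normalized"] = sub["log_survival"] - sub.groupby("plate")[
        "log_survival"
    ].transform("median")
    if mad_scope == "replicate":
        sub["z"] = robust_z(sub["normalized"].to_numpy())
    else:
        sub["z"] = sub.groupby("plate")["normalized"].transform(
            lambda s: robust_z(s.to_numpy())
        )
    return sub[["plate", "well", "sirna_id", "log_survival", "normalized", "z"]]


def summarize_min_replicate(replicate_z: dict[int, pd.DataFrame]) -> pd.DataFrame:
    """Summarize per-replicate z scores into one score per siRNA.

    score = min over replicates; an siRNA missing a z in any replicate
    (filtered well, undefined z) gets a missing score and is excluded
    from ranking.  Ranks are 1..n over non-missing scores, descending,
    ties broken by sirna_id.
    """
    if not replicate_z:
        return pd.DataFrame(columns=["sirna_id", "score", "rank"])
    cols = {}
    for rep, df in sorted(replicate_z.items()):
        dup = df["sirna_id"].duplicated()
        if dup.any():
            raise ValueError(
                f"replicate {rep}: duplicate sample wells for siRNA(s) "
                f"{sorted(df.loc[dup, 'sirna_id'].unique())}"
            )
        cols[f"z_rep{rep}"] = df.set_index("sirna_id")["z"]
    table = pd.DataFrame(cols)
    zcols = list(cols)
    table["score"] = table[zcols].min(axis=1)
    table.loc[table[zcols].isna().any(axis=1), "score"] = np.nan
    n_missing = int(table["score"].isna().sum())
    if n_missing:
        logger.info("%d siRNA(s) excluded from ranking (missing replicate z)", n_missing)

    table = table.reset_index().rename(columns={"index": "sirna_id"})
    scored = table["score"].notna()
    order = table[scored].sort_values(
        ["score", "sirna_id"], ascending=[False, True], kind="mergesort"
    )
    table["rank"] = pd.Series(pd.NA, index=table.index, dtype="Int64")
    table.loc[order.index, "rank"] = np.arange(1, scored.sum() + 1)
    return table.sort_values(["rank", "sirna_id"], na_position="last").reset_index(
        drop=True
    )


def score_screen(
    library: pd.DataFrame,
    measurements: pd.DataFrame,
    viability_fraction: float = 0.2,
    mad_scope: str = "replicate",
) -> pd.DataFrame:
    """Full scoring pipeline: survival -> filter -> per-replicate z -> min.

    ``library`` needs columns sirna_id, gene_id.  Returns a score table
    with sirna_id, gene_id, z_rep*, score, rank sorted by rank.
    """
    wells = compute_survival(measurements)
    sample_ids = set(wells.loc[wells["role"] == "sample", "sirna_id"].dropna())
    unknown = sample_ids - set(library["sirna_id"])
    if unknown:
        raise ValueError(f"sample wells reference unknown siRNA(s): {sorted(unknown)[:5]}")
    kept = filter_low_viability(wells, viability_fraction)
    reps = sorted(kept.loc[kept["role"] == "sample", "replicate"].unique())
    per_rep = {rep: score_replicate(kept, rep, mad_scope) for rep in reps}
    table = summarize_min_replicate(per_rep)
    # every library siRNA appears; ones lost to filtering stay unscored
    table = library[["sirna_id", "gene_id"]].merge(table, on="sirna_id", how="left")
    return table[
        ["sirna_id", "gene_id"]
        + [c for c in table.columns if c.startswith("z_rep")]
        + ["score", "rank"]
    ].sort_values(["rank", "sirna_id"], na_position="last").reset_index(drop=True)


def zprime(pos_values, neg_values) -> float:
    """Z' factor: 1 - 3(sd_pos + sd_neg) / |mean_pos - mean_neg|.

    A scale-free measure of control separation; > 0 means the two
    control distributions barely overlap, 1 would mean infinite
    separation.  Undefined (error) when the means coincide.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 values in each control group")
    delta = abs(pos.mean() - neg.mean())
    if delta == 0:
        raise ValueError("Z' undefined: control means are equal")
    return 1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / delta
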