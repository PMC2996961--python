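import math

import numpy as np
import pandas as pd
import pytest

from seedscreen.screen_core import (
    MAD_TO_SD,
    compute_survival,
    filter_low_viability,
    robust_z,
    score_replicate,
    score_screen,
    summarize_min_replicate,
    zprime,
)

from conftest import make_measurements


def wells_df(rows):
    """(plate, well, replicate, pre, role, survival) -> survival-stage frame."""
    df = pd.DataFrame(
        rows, columns=["plate", "well", "replicate", "pre", "role", "survival"]
    )
    df["post"] = df["pre"] * df["survival"]
    df["sirna_id"] = [f"s{i}" for i in range(len(df))]
    df["valid"] = True
    df["reason"] = ""
    return df


class TestComputeSurvival:
    @pytest.mark.parametrize(
        "pre,post,expected", [(1000, 1000, 1.0), (2000, 500, 0.25)]
    )
    def test_ratio(self, pre, post, expected):
        m = make_measurements(
            [
                ("P1", "A01", 1, "pre", pre, "sample", "s1"),
                ("P1", "A01", 1, "post", post, "sample", "s1"),
            ]
        )
        out = compute_survival(m)
        assert out.loc[0, "survival"] == pytest.approx(expected)
        assert out.loc[0, "valid"]

    def test_zero_pre_flagged_invalid_not_nan_silent(self):
        m = make_measurements(
            [
                ("P1", "A01", 1, "pre", 0.0, "sample", "s1"),
                ("P1", "A01", 1, "post", 500.0, "sample", "s1"),
            ]
        )
        out = compute_survival(m)
        assert not out.loc[0, "valid"]
        assert "zero" in out.loc[0, "reason"]
        assert np.isnan(out.loc[0, "survival"])

    def test_missing_phase_reported_with_reason(self):
        m = make_measurements([("P1", "A01", 1, "pre", 100.0, "sample", "s1")])
        out = compute_survival(m)
        assert not out.loc[0, "valid"]
        assert "post" in out.loc[0, "reason"]

    def test_duplicate_well_phase_is_hard_error(self):
        m = make_measurements(
            [
                ("P1", "A01", 1, "pre", 100.0, "sample", "s1"),
                ("P1", "A01", 1, "pre", 200.0, "sample", "s1"),
            ]
        )
        with pytest.raises(ValueError, match="duplicate"):
            compute_survival(m)


class TestViabilityFilter:
    def test_rank_cut_removes_lowest_pre(self):
        rows = [("P1", f"A{i:02d}", 1, float(i), "sample", 0.5) for i in range(1, 11)]
        out = filter_low_viability(wells_df(rows), 0.2)
        assert len(out) == 8
        assert set(out["pre"]) == set(map(float, range(3, 11)))

    def test_tie_broken_by_well_id(self):
        rows = [("P1", f"A{i:02d}", 1, 100.0, "sample", 0.5) for i in range(1, 6)]
        out = filter_low_viability(wells_df(rows), 0.2)
        assert len(out) == 4
        assert "A01" not in set(out["well"])

    def test_exact_count_on_lognormal_wells(self):
        rng = np.random.default_rng(0)
        rows = [
            ("P1", f"W{i:03d}", 1, float(p), "sample", 0.5)
            for i, p in enumerate(rng.lognormal(7, 0.5, 100))
        ]
        df = wells_df(rows)
        out = filter_low_viability(df, 0.2)
        assert len(df) - len(out) == 20
        # matches a direct sort of pre-treatment fluorescence
        cutoff = set(df.sort_values("pre")["well"].iloc[:20])
        assert set(df["well"]) - set(out["well"]) == cutoff

    def test_controls_never_removed(self):
        rows = [("P1", f"A{i:02d}", 1, float(i), "sample", 0.5) for i in range(1, 9)]
        rows += [("P1", "A09", 1, 0.001, "neg_ctrl", 0.5)]
        out = filter_low_viability(wells_df(rows), 0.2)
        assert "A09" in set(out["well"])

    def test_fraction_one_rejected(self):
        with pytest.raises(ValueError):
            filter_low_viability(wells_df([("P1", "A01", 1, 1.0, "sample", 0.5)]), 1.0)


class TestRobustZ:
    def test_hand_computed_value(self):
        z = robust_z(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert z[-1] == pytest.approx((5 - 3) / (MAD_TO_SD * 1.0))
        assert z[-1] == pytest.approx(1.349, abs=5e-4)

    def test_zero_mad_gives_missing_with_warning(self):
        with pytest.warns(RuntimeWarning, match="MAD"):
            z = robust_z(np.full(5, 2.0))
        assert np.isnan(z).all()


class TestScoreReplicate:
    def test_shift_invariance(self, toy_screen):
        library, meas = toy_screen
        wells = compute_survival(meas)
        base = score_replicate(wells, 1)
        shifted = wells.copy()
        shifted["survival"] = shifted["survival"] * 7.3  # constant on log scale
        again = score_replicate(shifted, 1)
        np.testing.assert_allclose(base["z"], again["z"], atol=1e-12)

    def test_plate_scale_invariance(self, toy_screen):
        library, meas = toy_screen
        scaled = meas.copy()
        on_p1 = scaled["plate"] == "P1"
        scaled.loc[on_p1, "fluorescence"] *= 5.0  # both phases: survival unchanged
        a = score_replicate(compute_survival(meas), 1)
        b = score_replicate(compute_survival(scaled), 1)
        np.testing.assert_allclose(a["z"], b["z"], atol=1e-12)

    def test_identical_survival_hits_mad_zero_path(self):
        rows = [("P1", f"A{i:02d}", 1, 100.0 + i, "sample", 0.5) for i in range(6)]
        with pytest.warns(RuntimeWarning):
            out = score_replicate(wells_df(rows), 1)
        assert out["z"].isna().all()


class TestSummarize:
    def test_min_of_replicates(self):
        reps = {
            1: pd.DataFrame({"plate": "P1", "well": "A1", "sirna_id": ["a"], "z": [2.0]}),
            2: pd.DataFrame({"plate": "P1", "well": "A1", "sirna_id": ["a"], "z": [3.0]}),
        }
        out = summarize_min_replicate(reps)
        assert out.loc[0, "score"] == 2.0

    def test_missing_replicate_excludes_sirna(self):
        reps = {
            1: pd.DataFrame({"plate": "P1", "well": "A1", "sirna_id": ["a", "b"],
                             "z": [np.nan, 1.0]}),
            2: pd.DataFrame({"plate": "P1", "well": "A1", "sirna_id": ["a", "b"],
                             "z": [2.5, 0.5]}),
        }
        out = summarize_min_replicate(reps).set_index("sirna_id")
        assert np.isnan(out.loc["a", "score"])
        assert pd.isna(out.loc["a", "rank"])
        assert out.loc["b", "rank"] == 1

    def test_empty_input_empty_output(self):
        assert summarize_min_replicate({}).empty

    def test_score_never_exceeds_any_replicate_z(self, toy_screen):
        library, meas = toy_screen
        table = score_screen(library, meas, viability_fraction=0.0)
        zcols = [c for c in table.columns if c.startswith("z_rep")]
        scored = table[table["score"].notna()]
        for c in zcols:
            assert (scored["score"] <= scored[c] + 1e-12).all()

    def test_table1_fixture_rank1_is_top_scorer(self, table1):
        reps = {
            1: pd.DataFrame({"plate": "P", "well": table1["symbol"],
                             "sirna_id": table1["symbol"], "z": table1["score"]})
        }
        out = summarize_min_replicate(reps)
        assert out.loc[0, "sirna_id"] == "TEGT"
        assert out.loc[0, "score"] == pytest.approx(3.51)
        assert out.loc[0, "rank"] == 1


class TestZPrime:
    def test_hand_computed(self):
        pos = [9.0, 10.0, 11.0]  # mean 10, sd 1
        neg = [-1.0, 0.0, 1.0]  # mean 0, sd 1
        assert zprime(pos, neg) == pytest.approx(1 - 6 / 10)

    def test_perfect_separation(self):
        assert zprime([1.0, 1.0], [0.0, 0.0]) == 1.0

    def test_equal_means_error(self):
        with pytest.raises(ValueError):
            zprime([1.0, 2.0], [2.0, 1.0])


def brute_force_scores(library, measurements, fraction=0.2):
    """Direct, unvectorized re-implementation of the scoring pipeline."""
    wells = {}
    for r in measurements.itertuples(index=False):
        key = (r.plate, r.well, r.replicate)
        wells.setdefault(key, {})[r.phase] = r.fluorescence
        wells[key]["role"] = r.role
        wells[key]["sirna_id"] = r.sirna_id

    per_rep = {}
    reps = sorted({k[2] for k in wells})
    for rep in reps:
        ws = [
            (k, v) for k, v in wells.items()
            if k[2] == rep and v["role"] == "sample" and v.get("pre", 0) > 0
            and "post" in v
        ]
        ws.sort(key=lambda kv: (kv[1]["pre"], kv[0][0], kv[0][1]))
        kept = ws[math.floor(fraction * len(ws)):]
        logs = {k: math.log(v["post"] / v["pre"]) for k, v in kept}
        plates = {k[0] for k in logs}
        norm = {}
        for plate in plates:
            vals = sorted(v for k, v in logs.items() if k[0] == plate)
            med = float(np.median(vals))
            for k in logs:
                if k[0] == plate:
                    norm[k] = logs[k] - med
        allv = np.array(list(norm.values()))
        med = float(np.median(allv))
        mad = float(np.median(np.abs(allv - med)))
        per_rep[rep] = {
            wells[k]["sirna_id"]: (norm[k] - med) / (1.4826 * mad) for k in norm
        }
    scores = {}
    for sid in library["sirna_id"]:
        zs = [per_rep[rep].get(sid) for rep in reps]
        scores[sid] = min(zs) if all(z is not None for z in zs) else None
    return scores


def test_pipeline_matches_bruteforce_on_toy_screen(toy_screen):
    library, meas = toy_screen
    expected = brute_force_scores(library, meas)
    table = score_screen(library, meas).set_index("sirna_id")
    for sid, exp in expected.items():
        got = table.loc[sid, "score"]
        if exp is None:
            assert np.isnan(got)
        else:
            assert got == pytest.approx(exp, abs=1e-12)
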