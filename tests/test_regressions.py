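"""Covariate builders (with brute-force oracles) and estimator contracts."""

import numpy as np
import pandas as pd
import pytest

from tadanet import regressions as rg
from tadanet.networks import DAY_S

from conftest import puzzle_frame


class TestParentalStrategy:
    @pytest.mark.parametrize(
        "n_right,n_left,want",
        [
            (0, 0, "none"),
            (19, 1, "nonconflicting_right"),  # 95% right
            (1, 19, "nonconflicting_left"),
            (12, 8, "conflicting"),  # 60% right
            (18, 2, "conflicting"),  # exactly 90% is not > 90%
        ],
    )
    def test_rule(self, n_right, n_left, want):
        assert rg.classify_parental_strategy(n_right, n_left) == want


class TestSideChoiceRecords:
    def test_hand_counted_windows(self, toy_registry):
        t0 = 1000.0
        puz = puzzle_frame(
            [
                ("A-F", t0 - 200, "S1", "solve_right"),
                ("A-M", t0 - 100, "S1", "solve_right"),
                ("J2", t0 - 50, "S1", "solve_left"),
                ("J1", t0 - 40, "S1", "solve_left"),  # J1's own, in 1-h window
                ("J1", t0, "S1", "solve_right"),  # focal solve
            ]
        )
        rec = rg.build_side_choice_records(puz, toy_registry)
        focal = rec[(rec.juvenile_id == "J1") & (rec.solve_time == t0)].iloc[0]
        assert focal.social_count == 3
        assert focal.social_prop_right == pytest.approx(2 / 3)
        assert focal.personal_count == 1
        assert focal.personal_prop_right == 0.0
        assert focal.cumulative_solves == 1

    def test_first_solve_has_no_personal_information(self, toy_registry):
        puz = puzzle_frame(
            [("J2", 10.0, "S1", "solve_right"), ("J1", 20.0, "S1", "solve_right")]
        )
        rec = rg.build_side_choice_records(puz, toy_registry)
        j1 = rec[rec.juvenile_id == "J1"].iloc[0]
        assert j1.personal_count == 0 and np.isnan(j1.personal_prop_right)
        # excluded from the all-days model by the availability filter
        with np.errstate(invalid="ignore"):
            kept = rec[(rec.social_count >= 1) & (rec.personal_count >= 1)]
        assert "J1" not in set(kept.juvenile_id)

    def test_matches_brute_force_double_loop(self, toy_registry):
        rng = np.random.default_rng(17)
        birds = toy_registry.bird_ids
        rows = [
            (
                birds[rng.integers(len(birds))],
                float(rng.uniform(0, 2 * DAY_S)),
                rng.choice(["S1", "S2"]),
                rng.choice(["solve_left", "solve_right"]),
            )
            for _ in range(200)
        ]
        puz = puzzle_frame(rows).sort_values("timestamp").reset_index(drop=True)
        rec = rg.build_side_choice_records(puz, toy_registry)
        # oracle: double loop over (focal solve, context solve)
        solves = puz.reset_index(drop=True)
        n_expected = 0
        for i, r in solves.iterrows():
            if not toy_registry.is_juvenile(r.bird_id):
                continue
            n_expected += 1
            soc = per = soc_r = per_r = 0
            for k, q in solves.iterrows():
                if q.site_id != r.site_id or q.timestamp >= r.timestamp:
                    continue
                if q.bird_id != r.bird_id and q.timestamp >= r.timestamp - 300.0:
                    soc += 1
                    soc_r += q.action == "solve_right"
                if q.bird_id == r.bird_id and q.timestamp >= r.timestamp - 3600.0:
                    per += 1
                    per_r += q.action == "solve_right"
            row = rec[
                (rec.juvenile_id == r.bird_id) & (rec.solve_time == r.timestamp)
            ].iloc[0]
            assert row.social_count == soc and row.personal_count == per
            if soc:
                assert row.social_prop_right == pytest.approx(soc_r / soc)
            if per:
                assert row.personal_prop_right == pytest.approx(per_r / per)
        assert len(rec) == n_expected

    def test_first_day_counts_match_groupby(self, toy_registry):
        rng = np.random.default_rng(23)
        rows = [
            (
                rng.choice(["J1", "J3"]),
                float(rng.uniform(0, 5 * DAY_S)),
                "S1",
                rng.choice(["solve_left", "solve_right"]),
            )
            for _ in range(120)
        ]
        puz = puzzle_frame(rows).sort_values("timestamp").reset_index(drop=True)
        rec = rg.build_side_choice_records(puz, toy_registry)
        for b, grp in rec.groupby("juvenile_id"):
            d0 = int(grp.solve_time.min() // DAY_S)
            want = ((grp.solve_time // DAY_S).astype(int) == d0).sum()
            assert grp.first_day.sum() == want


def simulate_side_records(rng, n_juv, solves_per_juv, coefs):
    """Directly simulated record table with known logistic truth."""
    rows = []
    for j in range(n_juv):
        for k in range(solves_per_juv):
            ps = rng.uniform()
            pp = rng.uniform()
            # cumulative experience spans hundreds of solves, as in the field
            c = int(k * rng.integers(25, 75))
            z = (
                coefs.get("intercept", 0.0)
                + coefs.get("social", 0.0) * ps
                + coefs.get("personal", 0.0) * pp
                + coefs.get("cum", 0.0) * c / 100
                + coefs.get("social_x", 0.0) * ps * c / 100
                + coefs.get("personal_x", 0.0) * pp * c / 100
            )
            rows.append(
                {
                    "juvenile_id": f"j{j}",
                    "choice": "right" if rng.random() < 1 / (1 + np.exp(-z)) else "left",
                    "social_prop_right": ps,
                    "personal_prop_right": pp,
                    "social_count": int(rng.integers(1, 6)),
                    "personal_count": 1,
                    "cumulative_solves": c,
                    "first_day": k < 4,
                }
            )
    return pd.DataFrame(rows)


class TestEstimators:
    def test_exposure_null_scrounge_or_covers_one(self):
        rng = np.random.default_rng(31)
        n = 500
        solves = rng.integers(0, 300, n)
        scrounges = rng.integers(0, 50, n)
        x1 = np.log10(solves + 1.0)
        z = -2.0 + 1.5 * x1  # scrounges truly null
        y = rng.random(n) < 1 / (1 + np.exp(-z))
        rec = pd.DataFrame(
            {
                "juvenile_id": [f"j{i}" for i in range(n)],
                "learned": y,
                "log_parental_solves": x1,
                "log_parental_scrounges": np.log10(scrounges + 1.0),
                "parental_strategy": "none",
            }
        )
        out = rg.fit_exposure_model(rec).set_index("term")
        scr = out.loc["log_parental_scrounges"]
        assert scr.or_lower <= 1.0 <= scr.or_upper
        slv = out.loc["log_parental_solves"]
        assert slv.or_lower <= np.exp(1.5) <= slv.or_upper

    def test_exposure_baseline_matches_observed_proportion(self):
        rng = np.random.default_rng(5)
        n = 400
        y = rng.random(n) < 0.3
        rec = pd.DataFrame(
            {
                "juvenile_id": [f"j{i}" for i in range(n)],
                "learned": y,
                "log_parental_solves": np.zeros(n),
                "log_parental_scrounges": np.zeros(n),
                "parental_strategy": "none",
            }
        )
        out = rg.fit_exposure_model(rec).set_index("term")
        base = out.loc["baseline_probability"]
        assert base.or_lower <= y.mean() <= base.or_upper

    def test_rescaling_halves_coefficient(self):
        rng = np.random.default_rng(7)
        n = 600
        x = rng.normal(0, 1, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.5 + x)))).astype(float)
        f1 = rg.penalized_logit(np.column_stack([np.ones(n), x]), y, ["i", "x"])
        f2 = rg.penalized_logit(np.column_stack([np.ones(n), 2 * x]), y, ["i", "x2"])
        assert f2.coef[1] == pytest.approx(f1.coef[1] / 2, rel=1e-3)

    def test_all_days_recovers_social_or(self):
        rng = np.random.default_rng(41)
        truth = {"intercept": -1.5, "social": np.log(20.0), "personal": 0.0}
        rec = simulate_side_records(rng, 200, 4, truth)
        out = rg.fit_side_choice_models(rec, "all_days").set_index("term")
        soc = out.loc["social_prop_right"]
        assert soc.or_lower <= 20.0 <= soc.or_upper

    def test_constant_social_information_covers_null(self):
        rng = np.random.default_rng(43)
        rec = simulate_side_records(rng, 80, 5, {"personal": 1.0})
        rec["social_prop_right"] = 0.5
        out = rg.fit_side_choice_models(rec, "all_days").set_index("term")
        soc = out.loc["social_prop_right"]
        assert soc.or_lower <= 1.0 <= soc.or_upper

    def test_first_day_parental_model_shape(self, toy_registry):
        rng = np.random.default_rng(3)
        rows = [
            (
                rng.choice(["J1", "J2", "J3", "J4", "J5"]),
                float(rng.uniform(0, DAY_S)),
                "S1",
                rng.choice(["solve_left", "solve_right"]),
            )
            for _ in range(100)
        ]
        puz = puzzle_frame(rows).sort_values("timestamp").reset_index(drop=True)
        rec = rg.build_side_choice_records(puz, toy_registry)
        exposure = pd.DataFrame(
            {
                "juvenile_id": ["J1", "J2", "J3", "J4", "J5"],
                "parental_strategy": [
                    "none",
                    "conflicting",
                    "nonconflicting_right",
                    "nonconflicting_left",
                    "none",
                ],
            }
        )
        out = rg.fit_side_choice_models(rec, "first_day_parental", exposure=exposure)
        assert "Intercept" in set(out.term)
        assert len(out) >= 2

    def test_single_juvenile_warns_and_falls_back(self):
        rng = np.random.default_rng(51)
        rec = simulate_side_records(rng, 1, 80, {"social": 1.0})
        with pytest.warns(UserWarning, match="single group"):
            rg.fit_side_choice_models(rec, "all_days")
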