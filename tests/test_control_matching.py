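import numpy as np
import pandas as pd
import pytest

from wardcost.control_matching import (
    MatchingError,
    balance_table,
    estimate_propensity,
    match_1to1,
    propensity_design,
)


def covariate_frame(ids, ages, genders, codes):
    return pd.DataFrame({"id": ids, "age": ages, "gender": genders, "icd10": codes})


def random_pool(rng, n, age_mean=75.0, prefix="s"):
    return covariate_frame(
        [f"{prefix}{i}" for i in range(n)],
        rng.normal(age_mean, 8.0, size=n),
        rng.choice(["F", "M"], size=n),
        rng.choice(["I50.0", "I50.1", "I50.9"], size=n),
    )


def newton_logit_oracle(y, X, iterations=60):
    """Independent iterative (Newton/IRLS) logistic fit."""
    Xm = np.asarray(X, dtype=float)
    beta = np.zeros(Xm.shape[1])
    for _ in range(iterations):
        eta = Xm @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1.0 - p)
        grad = Xm.T @ (y - p)
        hess = Xm.T @ (Xm * W[:, None])
        beta = beta + np.linalg.solve(hess, grad)
    return 1.0 / (1.0 + np.exp(-(Xm @ beta)))


class TestEstimatePropensity:
    def test_no_signal_mean_score_is_treated_fraction(self):
        rng = np.random.default_rng(1)
        treated = random_pool(rng, 40, prefix="t")
        control = random_pool(rng, 80, prefix="c")
        t_scores, c_scores = estimate_propensity(treated, control)
        mean = np.concatenate([t_scores, c_scores]).mean()
        # score equation of an intercept logistic model pins the mean exactly
        assert mean == pytest.approx(40 / 120, abs=1e-6)
        assert ((t_scores > 0) & (t_scores < 1)).all()

    @pytest.mark.filterwarnings(
        "ignore::statsmodels.tools.sm_exceptions.PerfectSeparationWarning",
        "ignore::statsmodels.tools.sm_exceptions.ConvergenceWarning",
    )
    def test_perfect_separation_raises(self):
        treated = covariate_frame(
            ["t0", "t1", "t2", "t3"], [85, 86, 88, 90], ["F", "M", "F", "M"],
            ["I50.0"] * 4,
        )
        control = covariate_frame(
            ["c0", "c1", "c2", "c3"], [40, 42, 45, 47], ["F", "M", "F", "M"],
            ["I50.0"] * 4,
        )
        with pytest.raises(MatchingError):
            estimate_propensity(treated, control)

    def test_scores_match_independent_newton_fit(self):
        # 20-subject worked pool with hand-specified covariates
        treated = covariate_frame(
            [f"t{i}" for i in range(10)],
            [62, 71, 75, 80, 68, 77, 82, 66, 74, 79],
            ["F", "M", "F", "F", "M", "M", "F", "M", "F", "M"],
            ["I50.0", "I50.9", "I50.0", "I50.1", "I50.9",
             "I50.0", "I50.1", "I50.9", "I50.0", "I50.1"],
        )
        control = covariate_frame(
            [f"c{i}" for i in range(10)],
            [65, 70, 73, 78, 81, 69, 76, 84, 72, 67],
            ["M", "F", "M", "F", "M", "F", "F", "M", "M", "F"],
            ["I50.9", "I50.0", "I50.1", "I50.0", "I50.9",
             "I50.1", "I50.0", "I50.9", "I50.1", "I50.0"],
        )
        t_scores, c_scores = estimate_propensity(treated, control)
        y, X = propensity_design(treated, control)
        oracle = newton_logit_oracle(y, X)
        np.testing.assert_allclose(
            np.concatenate([t_scores, c_scores]), oracle, atol=1e-6
        )

    def test_missing_covariate_column_rejected(self):
        bad = pd.DataFrame({"id": ["a"], "age": [70]})
        with pytest.raises(MatchingError, match="gender"):
            estimate_propensity(bad, bad)


def greedy_oracle(t_ids, t_scores, c_ids, c_scores, caliper=None):
    """Naive O(n^2) greedy nearest-neighbour matching without replacement."""
    order = sorted(range(len(t_ids)), key=lambda i: -t_scores[i])
    used = set()
    pairs = []
    unmatched = []
    for ti in order:
        best = None
        for cj in range(len(c_ids)):
            if cj in used:
                continue
            d = abs(t_scores[ti] - c_scores[cj])
            if best is None or d < best[0] or (d == best[0] and c_scores[cj] < best[2]):
                best = (d, cj, c_scores[cj])
        if best is None or (caliper is not None and best[0] > caliper):
            unmatched.append(t_ids[ti])
            continue
        used.add(best[1])
        pairs.append((t_ids[ti], c_ids[best[1]]))
    return pairs, unmatched


class TestMatch1to1:
    def test_identical_controls_all_matched_at_zero_distance(self):
        rng = np.random.default_rng(3)
        treated = random_pool(rng, 15, prefix="t")
        control = treated.copy()
        control["id"] = [f"c{i}" for i in range(15)]
        scores = np.linspace(0.2, 0.8, 15)
        result = match_1to1(treated, control, scores, scores)
        assert len(result.pairs) == 15
        assert result.unmatched_treated == []
        assert all(d == 0.0 for d in result.distances)

    def test_three_by_three_hand_set_scores_match_oracle(self):
        treated = covariate_frame(["t0", "t1", "t2"], [70, 75, 80],
                                  ["F", "M", "F"], ["I50.0"] * 3)
        control = covariate_frame(["c0", "c1", "c2"], [71, 74, 81],
                                  ["F", "M", "F"], ["I50.0"] * 3)
        t_scores = np.array([0.30, 0.55, 0.70])
        c_scores = np.array([0.50, 0.28, 0.72])
        result = match_1to1(treated, control, t_scores, c_scores)
        expected_pairs, _ = greedy_oracle(
            ["t0", "t1", "t2"], t_scores, ["c0", "c1", "c2"], c_scores
        )
        assert sorted(result.pairs) == sorted(expected_pairs)

    @pytest.mark.parametrize("seed", range(25))
    def test_random_small_pools_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nt, nc = rng.integers(1, 5), rng.integers(1, 5)
        # distinct scores keep the tie-break rule out of play
        all_scores = rng.permutation(np.linspace(0.05, 0.95, nt + nc))
        t_scores, c_scores = all_scores[:nt], all_scores[nt:]
        t_ids = [f"t{i}" for i in range(nt)]
        c_ids = [f"c{i}" for i in range(nc)]
        treated = covariate_frame(t_ids, 70 + t_scores * 10, ["F"] * nt, ["I50.0"] * nt)
        control = covariate_frame(c_ids, 70 + c_scores * 10, ["F"] * nc, ["I50.0"] * nc)
        caliper = rng.choice([None, 0.2])
        result = match_1to1(treated, control, t_scores, c_scores, caliper=caliper)
        expected_pairs, expected_unmatched = greedy_oracle(
            t_ids, t_scores, c_ids, c_scores, caliper=caliper
        )
        assert result.pairs == expected_pairs
        assert result.unmatched_treated == expected_unmatched

    def test_zero_caliper_distinct_scores_nothing_matches(self):
        treated = covariate_frame(["t0", "t1"], [70, 75], ["F", "M"], ["I50.0"] * 2)
        control = covariate_frame(["c0", "c1"], [71, 74], ["F", "M"], ["I50.0"] * 2)
        result = match_1to1(
            treated, control, np.array([0.3, 0.6]), np.array([0.4, 0.7]), caliper=0.0
        )
        assert result.pairs == []
        assert sorted(result.unmatched_treated) == ["t0", "t1"]

    def test_empty_control_pool_rejected(self):
        treated = covariate_frame(["t0"], [70], ["F"], ["I50.0"])
        control = treated.iloc[:0]
        with pytest.raises(MatchingError, match="empty"):
            match_1to1(treated, control, np.array([0.5]), np.array([]))

    def test_no_control_reused(self):
        rng = np.random.default_rng(11)
        treated = random_pool(rng, 30, prefix="t")
        control = random_pool(rng, 40, prefix="c")
        t_scores, c_scores = estimate_propensity(treated, control)
        result = match_1to1(treated, control, t_scores, c_scores)
        controls_used = [c for _, c in result.pairs]
        assert len(controls_used) == len(set(controls_used))
        assert len(result.pairs) + len(result.unmatched_treated) == 30

    def test_deterministic_given_fixed_inputs(self):
        rng = np.random.default_rng(5)
        treated = random_pool(rng, 20, prefix="t")
        control = random_pool(rng, 40, age_mean=77.0, prefix="c")
        t_scores, c_scores = estimate_propensity(treated, control)
        r1 = match_1to1(treated, control, t_scores, c_scores)
        r2 = match_1to1(treated, control, t_scores, c_scores)
        assert r1.pairs == r2.pairs


class TestBalance:
    def test_age_smd_improves_on_shifted_pools(self):
        # property over >=100 simulated pools; <=5% failures tolerated
        failures = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            treated = random_pool(rng, 50, age_mean=75.0, prefix="t")
            control = random_pool(rng, 150, age_mean=81.0, prefix="c")
            try:
                t_scores, c_scores = estimate_propensity(treated, control)
            except MatchingError:
                continue
            result = match_1to1(treated, control, t_scores, c_scores)
            before = abs(result.balance.loc["age", "smd_before"])
            after = abs(result.balance.loc["age", "smd_after"])
            if after > before + 1e-9:
                failures += 1
        assert failures <= 5

    def test_balance_table_shape(self):
        rng = np.random.default_rng(2)
        treated = random_pool(rng, 10, prefix="t")
        control = random_pool(rng, 20, prefix="c")
        t_scores, c_scores = estimate_propensity(treated, control)
        result = match_1to1(treated, control, t_scores, c_scores)
        table = result.balance
        assert {"smd_before", "smd_after"} <= set(table.columns)
        assert "age" in table.index and "female" in table.index

    def test_perfectly_matched_pairs_have_zero_smd(self):
        treated = covariate_frame(["t0", "t1"], [70, 80], ["F", "M"], ["I50.0", "I50.9"])
        control = covariate_frame(
            ["c0", "c1", "c2"], [70, 80, 95], ["F", "M", "M"], ["I50.0", "I50.9", "I50.9"]
        )
        table = balance_table(treated, control, [("t0", "c0"), ("t1", "c1")])
        assert table["smd_after"].abs().max() == pytest.approx(0.0)
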