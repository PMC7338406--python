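import numpy as np
import pytest
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score

from skie.stats import (
    clopper_pearson_ci,
    conditional_grade_table,
    interpretation_band,
    linear_weighted_kappa,
    residual_errors,
)


def _weighted_kappa_by_hand(a, b):
    """Cellwise evaluation of the linear-weighted kappa formula."""
    cats = sorted(set(a) | set(b))
    k = len(cats)
    idx = {c: i for i, c in enumerate(cats)}
    n = len(a)
    O = np.zeros((k, k))
    for x, y in zip(a, b):
        O[idx[x], idx[y]] += 1 / n
    E = np.outer(O.sum(1), O.sum(0))
    num = den = 0.0
    for i in range(k):
        for j in range(k):
            w = abs(i - j) / (k - 1)
            num += w * O[i, j]
            den += w * E[i, j]
    return 1 - num / den


class TestKappa:
    def test_perfect_agreement_is_one(self):
        a = ["G1", "G2", "G3", "G2", "G1"] * 4
        res = linear_weighted_kappa(a, list(a), confidence=None)
        assert res.kappa == pytest.approx(1.0)

    def test_contrived_table_matches_hand_formula_and_sklearn(self):
        a = ["G1"] * 10 + ["G2"] * 15 + ["G3"] * 5 + ["G1", "G2", "G3"] * 5
        rng = np.random.default_rng(0)
        b = [x if rng.uniform() < 0.7 else rng.choice(["G1", "G2", "G3"]) for x in a]
        res = linear_weighted_kappa(a, b, confidence=None)
        assert res.kappa == pytest.approx(_weighted_kappa_by_hand(a, b), abs=1e-12)
        sk = cohen_kappa_score(a, b, weights="linear")
        assert res.kappa == pytest.approx(sk, abs=1e-12)

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(1)
        kappas = []
        for _ in range(50):
            a = rng.choice(["G1", "G2", "G3"], size=2000).tolist()
            b = rng.choice(["G1", "G2", "G3"], size=2000).tolist()
            kappas.append(linear_weighted_kappa(a, b, confidence=None).kappa)
        assert abs(np.mean(kappas)) < 0.01
        assert np.std(kappas) < 0.05

    def test_symmetry_between_raters(self):
        rng = np.random.default_rng(2)
        a = rng.choice(["G1", "G2", "G3"], size=60).tolist()
        b = rng.choice(["G1", "G2", "G3"], size=60).tolist()
        k1 = linear_weighted_kappa(a, b, confidence=None).kappa
        k2 = linear_weighted_kappa(b, a, confidence=None).kappa
        assert k1 == pytest.approx(k2, abs=1e-12)

    def test_two_categories_linear_equals_unweighted(self):
        rng = np.random.default_rng(3)
        a = rng.choice(["G1", "G2"], size=100).tolist()
        b = [x if rng.uniform() < 0.8 else ("G1" if x == "G2" else "G2") for x in a]
        ours = linear_weighted_kappa(a, b, confidence=None).kappa
        unweighted = cohen_kappa_score(a, b, weights=None)
        assert ours == pytest.approx(unweighted, abs=1e-12)

    def test_bootstrap_ci_contains_kappa(self):
        rng = np.random.default_rng(4)
        a = rng.choice(["G1", "G2", "G3"], size=80).tolist()
        b = [x if rng.uniform() < 0.7 else rng.choice(["G1", "G2", "G3"]) for x in a]
        res = linear_weighted_kappa(a, b, confidence=0.95, seed=0)
        assert res.ci_low <= res.kappa <= res.ci_high

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            linear_weighted_kappa([], [], confidence=None)
        with pytest.raises(ValueError):
            linear_weighted_kappa(["G1"] * 5, ["G1"] * 5, confidence=None)


class TestBands:
    @pytest.mark.parametrize(
        "kappa,band",
        [
            (0.62, "substantial"),  # the headline agreement level
            (0.95, "near perfect"),
            (-0.1, "none"),
            (0.1, "slight"),
            (0.21, "fair"),  # boundary goes to the upper band
            (0.4, "fair"),
            (0.41, "moderate"),
            (0.6, "moderate"),
            (0.8, "substantial"),
            (0.81, "near perfect"),
            (0.0, "slight"),
        ],
    )
    def test_band_lookup(self, kappa, band):
        assert interpretation_band(kappa) == band

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            interpretation_band(1.5)


def _cp_bisection_oracle(successes, n, confidence, tol=1e-9):
    """Clopper-Pearson by direct bisection on the binomial tail sums."""
    alpha = 1 - confidence

    def upper_tail(p):  # P(X >= successes | p)
        return 1 - sps.binom.cdf(successes - 1, n, p)

    def lower_tail(p):  # P(X <= successes | p)
        return sps.binom.cdf(successes, n, p)

    def bisect(f, target, lo, hi):
        for _ in range(100):
            mid = (lo + hi) / 2
            if f(mid) > target:
                hi = mid
            else:
                lo = mid
        return (lo + hi) / 2

    low = 0.0 if successes == 0 else bisect(lambda p: upper_tail(p), alpha / 2, 0, 1)
    high = 1.0 if successes == n else bisect(lambda p: 1 - lower_tail(p), 1 - alpha / 2, 0, 1)
    return low, high


class TestClopperPearson:
    def test_boundaries(self):
        assert clopper_pearson_ci(0, 10, 0.95)[0] == 0.0
        assert clopper_pearson_ci(10, 10, 0.95)[1] == 1.0

    @pytest.mark.parametrize("successes,n", [(45, 50), (1, 10), (25, 50), (49, 50)])
    def test_matches_tail_sum_bisection(self, successes, n):
        lo, hi = clopper_pearson_ci(successes, n, 0.95)
        lo_o, hi_o = _cp_bisection_oracle(successes, n, 0.95)
        assert lo == pytest.approx(lo_o, abs=1e-6)
        assert hi == pytest.approx(hi_o, abs=1e-6)

    def test_widens_with_confidence_and_contains_estimate(self):
        last_width = 0.0
        for conf in (0.8, 0.9, 0.95, 0.99):
            lo, hi = clopper_pearson_ci(45, 50, conf)
            assert lo <= 45 / 50 <= hi
            width = hi - lo
            assert width > last_width
            last_width = width

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            clopper_pearson_ci(11, 10, 0.95)
        with pytest.raises(ValueError):
            clopper_pearson_ci(0, 0, 0.95)


class TestConditionalTable:
    def test_perfect_agreement_identity(self):
        ratings = ["G1", "G2", "G3"] * 5
        table = conditional_grade_table(ratings, list(ratings))
        assert np.allclose(table.values, np.eye(3))

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        ref = rng.choice(["G1", "G2", "G3"], size=40).tolist()
        pred = rng.choice(["G1", "G2", "G3"], size=40).tolist()
        table = conditional_grade_table(ref, pred)
        assert np.allclose(table.sum(axis=1).dropna(), 1.0)

    def test_hand_computed_fractions(self):
        ref = ["G1"] * 6 + ["G2"] * 4
        pred = ["G1"] * 5 + ["G2"] + ["G2"] * 3 + ["G1"]
        table = conditional_grade_table(ref, pred)
        assert table.loc["G1", "G1"] == pytest.approx(5 / 6)
        assert table.loc["G1", "G2"] == pytest.approx(1 / 6)
        assert table.loc["G2", "G2"] == pytest.approx(3 / 4)
        assert table.loc["G2", "G1"] == pytest.approx(1 / 4)


class TestResiduals:
    def test_zero_when_equal(self):
        out = residual_errors([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["mean_abs_error"] == 0.0
        assert np.all(out["residuals"] == 0)

    def test_constant_offset(self):
        out = residual_errors([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert out["mean_abs_error"] == pytest.approx(1.0)
        assert out["sd_abs_error"] == pytest.approx(0.0)
        assert out["mean_signed"] == pytest.approx(1.0)

    def test_recovers_injected_noise_scale(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(0, 20, size=5000)
        est = ref + rng.normal(0, 1.0, size=5000)
        out = residual_errors(est, ref)
        # E|N(0,1)| = sqrt(2/pi) ~ 0.7979
        assert out["mean_abs_error"] == pytest.approx(np.sqrt(2 / np.pi), rel=0.05)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            residual_errors([1.0], [1.0, 2.0])
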