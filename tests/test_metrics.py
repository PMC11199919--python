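"""Evaluation metrics against brute-force oracles and identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hsm.metrics import (
    auc_prg,
    auc_roc,
    compute_report,
    confusion_metrics,
    continuous_boyce_index,
    continuous_scores,
    max_tss_threshold,
)

# ---------------------------------------------------------------------------
# independent oracles (explicit loops, no shared code with the implementation)
# ---------------------------------------------------------------------------


def auc_pair_enumeration(sp, sa):
    wins = 0.0
    for p in sp:
        for a in sa:
            wins += 1.0 if p > a else 0.5 if p == a else 0.0
    return wins / (len(sp) * len(sa))


def contingency_oracle(pred, obs, t):
    tp = fn = tn = fp = 0
    for p, o in zip(pred, obs):
        hat = p >= t
        if o == 1 and hat:
            tp += 1
        elif o == 1:
            fn += 1
        elif hat:
            fp += 1
        else:
            tn += 1
    n = tp + fn + tn + fp
    sens, spec = tp / (tp + fn), tn / (tn + fp)
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    kappa = 0.0 if pe == 1 else (po - pe) / (1 - pe)
    return dict(sensitivity=sens, specificity=spec, pcc=po,
                tss=sens + spec - 1, kappa=kappa)


def prg_curve_oracle(sp, sa):
    """Brute-force PRG curve: loop all distinct thresholds, transform to
    gains, insert the recall-gain-0 crossing, trapezoid-integrate."""
    P, N = len(sp), len(sa)
    pi = P / (P + N)
    pts = []
    for t in sorted(set(list(sp) + list(sa)), reverse=True):
        tp = sum(s >= t for s in sp)
        fp = sum(s >= t for s in sa)
        if tp == 0:
            continue
        rg = 1 - pi / (1 - pi) * ((P - tp) / tp)
        pg = 1 - pi / (1 - pi) * (fp / tp)
        pts.append((rg, pg))
    area, prev = 0.0, None
    for rg, pg in pts:
        if prev is not None and rg > prev[0] and rg > 0:
            lo_rg, lo_pg = prev
            if lo_rg < 0:
                w = -lo_rg / (rg - lo_rg)
                lo_pg, lo_rg = lo_pg + w * (pg - lo_pg), 0.0
            area += (rg - lo_rg) * (lo_pg + pg) / 2
        prev = (rg, pg)
    return area


def random_instance(seed, n_max=30):
    rng = np.random.default_rng(seed)
    n_p = rng.integers(2, n_max)
    n_a = rng.integers(2, n_max)
    # mix continuous scores with heavy ties
    pool = np.round(rng.uniform(0, 1, 8), 2)
    sp = rng.choice(pool, n_p) + rng.choice([0, 0.3], n_p)
    sa = rng.choice(pool, n_a)
    return sp, sa


# ---------------------------------------------------------------------------
# worked examples and degenerate cases
# ---------------------------------------------------------------------------


class TestAucRoc:
    def test_complete_separation(self):
        assert auc_roc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_identical_tied_distributions(self):
        assert auc_roc([0.5, 0.5], [0.5, 0.5]) == 0.5

    def test_four_pair_enumeration(self):
        assert auc_roc([0.9, 0.4], [0.5, 0.1]) == 0.75

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            auc_roc([], [0.1])


class TestConfusion:
    def test_perfect_separation_all_ones(self):
        pred = [0.9, 0.8, 0.2, 0.1]
        obs = [1, 1, 0, 0]
        m = confusion_metrics(pred, obs, 0.5)
        assert all(m[k] == 1.0 for k in ("sensitivity", "specificity", "pcc", "tss", "kappa"))

    def test_mixed_contingency_against_oracle(self):
        # TP=3, FN=1, TN=2, FP=2 at threshold 0.5
        pred = [0.9, 0.8, 0.7, 0.2, 0.6, 0.9, 0.1, 0.3]
        obs = [1, 1, 1, 1, 0, 0, 0, 0]
        m = confusion_metrics(pred, obs, 0.5)
        o = contingency_oracle(pred, obs, 0.5)
        assert m == pytest.approx(o)
        assert m["sensitivity"] == 0.75
        assert m["specificity"] == 0.5
        assert m["pcc"] == 0.625
        assert m["tss"] == 0.25
        assert m["kappa"] == 0.25  # (0.625 - 0.5) / (1 - 0.5), Cohen's kappa

    def test_constant_predictions_no_skill(self):
        m = confusion_metrics([0.5] * 6, [1, 1, 1, 0, 0, 0], 0.5)
        assert m["tss"] == 0.0
        assert {m["sensitivity"], m["specificity"]} == {1.0, 0.0}

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([0.5, 0.6], [1, 1], 0.5)


class TestAucPrg:
    def test_perfect_ranking_is_one(self):
        assert auc_prg([0.9, 0.8, 0.7], [0.3, 0.2, 0.1]) == pytest.approx(1.0)

    def test_six_point_toy_matches_curve_oracle(self):
        sp = [0.9, 0.7, 0.4]
        sa = [0.8, 0.5, 0.2]
        assert auc_prg(sp, sa) == pytest.approx(prg_curve_oracle(sp, sa))

    @pytest.mark.parametrize("seed", range(10))
    def test_never_exceeds_one(self, seed):
        sp, sa = random_instance(seed)
        assert auc_prg(sp, sa) <= 1.0 + 1e-12


class TestBoyce:
    def test_calibrated_predictions_high_cbi(self):
        rng = np.random.default_rng(0)
        landscape = rng.uniform(0, 1, 20_000)
        keep = rng.uniform(0, 1, 20_000) < landscape  # density proportional to score
        presences = landscape[keep][:1000]
        assert continuous_boyce_index(presences, landscape, 101, 0.1) >= 0.9

    def test_uninformative_predictions_centered_on_zero(self):
        """Presences placed independently of the score: the index has no
        systematic sign. Single draws scatter widely (the rank correlation
        over heavily overlapping windows has few effective degrees of
        freedom), so the null check is on the mean across seeds."""
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            landscape = rng.uniform(0, 1, 5000)
            presences = rng.uniform(0, 1, 2000)
            vals.append(continuous_boyce_index(presences, landscape))
        assert abs(np.mean(vals)) < 0.25

    def test_bounded_in_minus_one_one(self):
        rng = np.random.default_rng(9)
        cbi = continuous_boyce_index(rng.uniform(0, 1, 200), rng.uniform(0, 1, 2000))
        assert -1.0 <= cbi <= 1.0

    def test_window_count_validated(self):
        with pytest.raises(ValueError):
            continuous_boyce_index([0.5], [0.1, 0.9], n_windows=2)


class TestContinuousScores:
    def test_perfect_prediction(self):
        m = continuous_scores([1.0, 1.0, 0.0], [1, 1, 0])
        assert m["mae"] == 0.0 and m["cor"] == pytest.approx(1.0)

    def test_constant_half_mae(self):
        with pytest.raises(ValueError, match="constant"):
            continuous_scores([0.5, 0.5], [1, 0])
        assert np.mean(np.abs(np.array([0.5, 0.5]) - np.array([1, 0]))) == 0.5

    def test_four_point_arithmetic(self):
        pred = [0.8, 0.6, 0.3, 0.1]
        obs = [1, 1, 0, 0]
        m = continuous_scores(pred, obs)
        # hand-computed: sum|d| = 0.2+0.4+0.3+0.1 = 1.0 -> mae 0.25
        assert m["mae"] == pytest.approx(0.25)
        # hand-computed covariance 0.125, sds 0.269258.. and 0.5
        assert m["cor"] == pytest.approx(0.125 / (np.sqrt(0.0725) * 0.5))


class TestMaxTss:
    def test_separable_threshold_at_smallest_presence_score(self):
        pred = [0.9, 0.7, 0.6, 0.3, 0.2]
        obs = [1, 1, 1, 0, 0]
        assert max_tss_threshold(pred, obs) == 0.6

    def test_all_equal_predictions(self):
        assert max_tss_threshold([0.4] * 4, [1, 0, 1, 0]) == 0.4

    @pytest.mark.parametrize("seed", range(10))
    def test_grid_search_never_beats_returned_threshold(self, seed):
        sp, sa = random_instance(seed)
        pred = np.concatenate([sp, sa])
        obs = np.concatenate([np.ones(len(sp), int), np.zeros(len(sa), int)])
        t_star = max_tss_threshold(pred, obs)
        best = confusion_metrics(pred, obs, t_star)["tss"]
        for t in np.linspace(pred.min(), pred.max(), 1000):
            assert confusion_metrics(pred, obs, t)["tss"] <= best + 1e-12


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_tss_identity_holds_everywhere(seed):
    """TSS == sensitivity + specificity - 1 at arbitrary thresholds."""
    rng = np.random.default_rng(seed)
    n = rng.integers(4, 50)
    pred = rng.uniform(0, 1, n)
    obs = np.r_[1, 0, rng.integers(0, 2, n - 2)]
    t = rng.uniform(0, 1)
    m = confusion_metrics(pred, obs, t)
    assert m["tss"] == pytest.approx(m["sensitivity"] + m["specificity"] - 1.0)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_auc_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    sp = rng.uniform(0, 1, rng.integers(2, 30))
    sa = rng.uniform(0, 1, rng.integers(2, 30))
    base = auc_roc(sp, sa)
    for f in (lambda x: 3 * x + 1, np.exp, lambda x: x**3):
        assert auc_roc(f(sp), f(sa)) == pytest.approx(base)


def test_report_assembles_all_ten_metrics():
    rng = np.random.default_rng(1)
    sp = rng.uniform(0.3, 1, 300)
    sa = rng.uniform(0, 0.8, 300)
    rep = compute_report(sp, sa, pred_landscape=rng.uniform(0, 1, 3000))
    s = rep.as_series()
    assert len(s) == 11  # ten metrics + threshold
    assert 0 <= s["auc_roc"] <= 1
    assert s["tss"] == pytest.approx(s["sensitivity"] + s["specificity"] - 1)
    assert -1 <= s["cbi"] <= 1
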