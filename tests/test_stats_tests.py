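"""Van der Waerden test, letter display, ANCOVA and small-sample oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from nanosip.stats_tests import (
    GroupedSamples,
    ancova_slopes,
    one_sample_t,
    pairwise_letters,
    pearson_corr,
    van_der_waerden,
)


def _grouped(*arrays, labels=None):
    labels = labels or [chr(97 + i) for i in range(len(arrays))]
    values = np.concatenate([np.asarray(a, dtype=float) for a in arrays])
    group = np.concatenate(
        [np.full(len(a), lab) for a, lab in zip(arrays, labels)]
    )
    return GroupedSamples(values=values, group=group)


def brute_force_vdw_permutation_p(values, group):
    """Independent oracle: enumerate every distinct label arrangement and
    compute the normal-scores statistic with explicit loops."""
    values = np.asarray(values, float)
    n = len(values)
    ranks = sps.rankdata(values)
    scores = sps.norm.ppf(ranks / (n + 1))
    s2 = sum(a * a for a in scores) / (n - 1)

    def statistic(labels):
        t = 0.0
        for g in set(labels):
            sel = [scores[i] for i in range(n) if labels[i] == g]
            t += len(sel) * (sum(sel) / len(sel)) ** 2
        return t / s2

    t_obs = statistic(tuple(group))
    null = [statistic(p) for p in set(itertools.permutations(group))]
    return sum(t >= t_obs - 1e-12 for t in null) / len(null)


class TestVanDerWaerden:
    def test_identical_groups_near_one(self, rng):
        x = rng.normal(size=15)
        res = van_der_waerden(_grouped(x, x), method="chisq")
        assert res.p_value > 0.9

    def test_all_values_identical_is_degenerate(self):
        res = van_der_waerden(_grouped([1.0, 1.0, 1.0], [1.0, 1.0]))
        assert res.degenerate
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_monotone_transform_invariance(self, rng):
        a, b = rng.normal(size=12), rng.normal(1.0, 1.0, size=10)
        raw = van_der_waerden(_grouped(a, b), method="chisq")
        warped = van_der_waerden(
            _grouped(np.exp(a), np.exp(b)), method="chisq"
        )
        assert warped.statistic == pytest.approx(raw.statistic, rel=1e-12)
        assert warped.p_value == pytest.approx(raw.p_value, rel=1e-12)

    def test_separated_groups_significant(self, rng):
        a = rng.normal(0.0, 1.0, size=20)
        b = rng.normal(5.0, 1.0, size=20)
        assert van_der_waerden(_grouped(a, b)).p_value < 1e-4

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_permutation_p_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=6)
        group = np.array(["a", "a", "a", "b", "b", "b"])
        res = van_der_waerden(
            GroupedSamples(values=values, group=group), method="permutation"
        )
        oracle = brute_force_vdw_permutation_p(values, group)
        assert res.p_value == pytest.approx(oracle, abs=1e-12)

    def test_permutation_handles_ties_with_midranks(self):
        values = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0])
        group = np.array(["a", "a", "a", "b", "b", "b"])
        res = van_der_waerden(
            GroupedSamples(values=values, group=group), method="permutation"
        )
        oracle = brute_force_vdw_permutation_p(values, group)
        assert res.p_value == pytest.approx(oracle, abs=1e-12)

    def test_type_one_error_calibration(self, rng):
        # 500 null replicates of 2 groups x 20; full 2000-rep calibration is
        # exercised in the acceptance suite
        rejections = 0
        reps = 500
        for _ in range(reps):
            x = rng.normal(size=40)
            res = van_der_waerden(
                GroupedSamples(values=x, group=np.repeat(["a", "b"], 20)),
                method="chisq",
            )
            rejections += res.p_value < 0.05
        assert 0.02 <= rejections / reps <= 0.08

    def test_input_validation(self):
        with pytest.raises(ValueError):
            van_der_waerden(_grouped([1.0, 2.0, 3.0]))  # one group


class TestPairwiseLetters:
    def test_identical_groups_share_a_letter(self, rng):
        x = rng.normal(size=20)
        disp = pairwise_letters(_grouped(x, x + 1e-9 * 0, x.copy()))
        letters = set(disp.letters.values())
        assert len(letters) == 1

    def test_constructed_separation(self, rng):
        a = rng.normal(0.0, 1.0, size=20)
        b = rng.normal(0.0, 1.0, size=20)
        c = rng.normal(10.0, 1.0, size=20)
        disp = pairwise_letters(_grouped(a, b, c))
        assert set(disp.letters["a"]) & set(disp.letters["b"])
        assert not set(disp.letters["a"]) & set(disp.letters["c"])
        assert not set(disp.letters["b"]) & set(disp.letters["c"])

    def test_order_invariance_up_to_renaming(self, rng):
        arrays = [rng.normal(m, 1.0, size=15) for m in (0.0, 0.5, 8.0)]
        d1 = pairwise_letters(_grouped(*arrays, labels=["a", "b", "c"]))
        d2 = pairwise_letters(
            _grouped(arrays[2], arrays[0], arrays[1], labels=["c", "a", "b"])
        )
        # sharing structure must be identical
        for x, y in itertools.combinations("abc", 2):
            share1 = bool(set(d1.letters[x]) & set(d1.letters[y]))
            share2 = bool(set(d2.letters[x]) & set(d2.letters[y]))
            assert share1 == share2

    def test_holm_adjustment_never_below_raw(self, rng):
        arrays = [rng.normal(m, 1.0, size=10) for m in (0, 1, 2, 3)]
        samples = _grouped(*arrays)
        disp = pairwise_letters(samples)
        for a, b in itertools.combinations(disp.letters, 2):
            sub = GroupedSamples(
                values=np.concatenate(
                    [samples.values[samples.group == a],
                     samples.values[samples.group == b]]
                ),
                group=np.concatenate(
                    [samples.group[samples.group == a],
                     samples.group[samples.group == b]]
                ),
            )
            raw = van_der_waerden(sub, method="chisq").p_value
            assert disp.pairwise_p.loc[a, b] >= raw - 1e-12

    def test_letters_consistent_with_adjusted_p_matrix(self, rng):
        # exhaustive consistency on several random 4-5 group layouts
        for seed in range(6):
            r = np.random.default_rng(seed)
            k = 4 + seed % 2
            arrays = [r.normal(r.uniform(0, 4), 1.0, size=12) for _ in range(k)]
            samples = _grouped(*arrays)
            disp = pairwise_letters(samples)
            for a, b in itertools.combinations(disp.letters, 2):
                share = bool(set(disp.letters[a]) & set(disp.letters[b]))
                assert share == (disp.pairwise_p.loc[a, b] >= disp.alpha)


class TestAncova:
    def _make(self, slopes, n=50, sd=0.1, seed=0):
        rng = np.random.default_rng(seed)
        xs, ys, gs = [], [], []
        for i, slope in enumerate(slopes):
            x = rng.uniform(0, 10, size=n)
            y = slope * x + rng.normal(0, sd, size=n)
            xs.append(x)
            ys.append(y)
            gs.append(np.full(n, f"g{i}"))
        return np.concatenate(xs), np.concatenate(ys), np.concatenate(gs)

    def test_equal_slopes_rarely_rejected(self):
        hits = sum(
            ancova_slopes(*self._make([2.0, 2.0], seed=s)).p_value > 0.05
            for s in range(200)
        )
        assert hits >= 180

    def test_different_slopes_detected(self):
        hits = sum(
            ancova_slopes(*self._make([2.0, 5.0], seed=s)).p_value < 0.001
            for s in range(200)
        )
        assert hits >= 190

    def test_interaction_f_matches_least_squares_oracle(self):
        # two groups, 3 points each; oracle: F from explicit residual sums of
        # the separate-slopes vs common-slope fits
        x = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        y = np.array([0.0, 1.1, 1.9, 0.5, 2.4, 4.6])
        g = np.array(["a", "a", "a", "b", "b", "b"])

        def rss(xs, ys):
            A = np.column_stack([np.ones_like(xs), xs])
            beta, *_ = np.linalg.lstsq(A, ys, rcond=None)
            return np.sum((ys - A @ beta) ** 2)

        # full model: separate intercepts and slopes
        rss_full = rss(x[:3], y[:3]) + rss(x[3:], y[3:])
        # reduced: separate intercepts, common slope
        xc = x - x.mean()
        A = np.column_stack([g == "a", g == "b", xc])
        beta, *_ = np.linalg.lstsq(A.astype(float), y, rcond=None)
        rss_red = np.sum((y - A.astype(float) @ beta) ** 2)
        f_oracle = (rss_red - rss_full) / 1 / (rss_full / 2)

        res = ancova_slopes(x, y, g)
        assert res.statistic == pytest.approx(f_oracle, rel=1e-9)
        assert res.df == (1.0, 2.0)

    def test_rank_deficient_group_rejected(self):
        x = np.array([1.0, 1.0, 1.0, 0.0, 1.0, 2.0])
        y = np.arange(6.0)
        g = np.array(["a", "a", "a", "b", "b", "b"])
        with pytest.raises(ValueError, match="'a'"):
            ancova_slopes(x, y, g)


class TestSimpleTests:
    def test_t_zero_when_values_equal_mu(self):
        res = one_sample_t(np.full(5, 2.0), 2.0)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_t_statistic_closed_form(self):
        # mean 3, s = sqrt(2.5), se = sqrt(0.5): t = 1/sqrt(0.5)
        res = one_sample_t(np.array([1.0, 2.0, 3.0, 4.0, 5.0]), 2.0)
        assert res.statistic == pytest.approx(np.sqrt(2.0), rel=1e-12)

    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = pearson_corr(x, x)
        assert res.statistic == pytest.approx(1.0)

    def test_zero_variance_degenerate(self):
        res = pearson_corr(np.ones(5), np.arange(5.0))
        assert res.degenerate
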