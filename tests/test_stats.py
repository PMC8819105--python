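import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score

from abcscreen import hedges_g, jonckheere_terpstra, optimal_threshold, roc_auc
from abcscreen.errors import ParameterError, UndefinedEffectError
from abcscreen.stats import evaluate_threshold


def brute_force_auc(scores, labels):
    """All-pairs concordance count, ties = 1/2 (independent oracle)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos, neg = s[y], s[~y]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (pos.size * neg.size)


class TestJonckheereTerpstra:
    def test_maximal_ordering_exact_p(self):
        """Perfectly ordered groups: JT = 12 of 12 pairs, exact p = 1/90."""
        res = jonckheere_terpstra([[1, 2], [3, 4], [5, 6]])
        assert res.jt_statistic == 12
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 90)

    def test_fully_tied_convention(self):
        res = jonckheere_terpstra([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        assert res.p_value == 0.5
        assert res.z == 0.0

    def test_two_groups_reduce_to_mann_whitney(self):
        g1, g2 = [1.0, 3.0, 5.0, 5.0], [2.0, 5.0, 7.0, 9.0, 11.0]
        res = jonckheere_terpstra([g1, g2])
        u = mannwhitneyu(g2, g1, alternative="greater").statistic
        assert res.jt_statistic == pytest.approx(u)

    def test_single_group_rejected(self):
        with pytest.raises(ParameterError):
            jonckheere_terpstra([[1.0, 2.0]])

    @pytest.mark.parametrize(
        "shape",
        [(2, 2), (3, 3), (2, 2, 2), (4, 4), (2, 3, 3), (3, 3, 2), (2, 2, 2, 2), (1, 3, 4)],
    )
    def test_exact_path_matches_permutation_oracle(self, shape):
        """For pooled n <= 8 the returned p equals a full-enumeration oracle.

        The oracle iterates over raw permutations of the pooled sample
        (including duplicates), an implementation independent of the
        package's combination recursion.
        """
        from itertools import permutations

        rng = np.random.default_rng(sum(shape) * 1000 + len(shape))
        for rep in range(3):
            groups = [rng.normal(size=n) + 0.4 * i for i, n in enumerate(shape)]
            if rep == 2:  # exercise ties as well
                groups = [np.round(g * 2) / 2 for g in groups]
            res = jonckheere_terpstra(groups)
            assert res.method == "exact"

            pooled = np.concatenate(groups)
            bounds = np.cumsum([0] + list(shape))

            def jt_of(arrangement):
                gs = [np.asarray(arrangement[bounds[i] : bounds[i + 1]]) for i in range(len(shape))]
                total = 0.0
                for i in range(len(gs)):
                    for j in range(i + 1, len(gs)):
                        d = gs[j][None, :] - gs[i][:, None]
                        total += np.sum(d > 0) + 0.5 * np.sum(d == 0)
                return total

            observed = jt_of(pooled)
            hits, count = 0, 0
            for perm in permutations(pooled):
                count += 1
                if jt_of(perm) >= observed - 1e-9:
                    hits += 1
            assert res.p_value == pytest.approx(hits / count, abs=1e-12)

    def test_normal_approximation_improves_with_sample_size(self):
        """Mean |p_normal - p_exact| shrinks from pooled n = 4 to n = 8."""
        from scipy.stats import norm

        def mean_gap(shape, seed):
            rng = np.random.default_rng(seed)
            gaps = []
            for _ in range(40):
                groups = [rng.normal(size=n) + 0.3 * i for i, n in enumerate(shape)]
                res = jonckheere_terpstra(groups)
                gaps.append(abs(float(norm.sf(res.z)) - res.p_value))
            return np.mean(gaps)

        assert mean_gap((2, 2, 2, 2), 1) < mean_gap((2, 2), 1)


class TestRocAuc:
    def test_perfect_separation(self):
        roc = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert roc.auc == 1.0
        opt = optimal_threshold(roc)
        assert opt.sensitivity == 1.0 and opt.specificity == 1.0
        assert 3 < opt.optimal_threshold <= 10

    def test_one_class_absent_rejected(self):
        with pytest.raises(ParameterError):
            roc_auc([1.0, 2.0], ["P", "P"])

    @given(st.data())
    @settings(derandomize=True, max_examples=100)
    def test_matches_brute_force_and_sklearn(self, data):
        n = data.draw(st.integers(4, 50))
        scores = data.draw(
            st.lists(st.integers(0, 20), min_size=n, max_size=n).map(
                lambda v: np.asarray(v, dtype=float)
            )
        )
        labels = np.asarray(data.draw(st.lists(st.booleans(), min_size=n, max_size=n)))
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        roc = roc_auc(scores, labels)
        assert roc.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
        assert roc.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    @given(
        scores=st.lists(st.floats(0.1, 100), min_size=6, max_size=30, unique=True),
        flips=st.lists(st.booleans(), min_size=6, max_size=30),
    )
    @settings(derandomize=True, max_examples=50)
    def test_auc_invariant_under_monotone_transform(self, scores, flips):
        s = np.asarray(scores)
        labels = np.resize(np.asarray(flips), s.size)
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        base = roc_auc(s, labels).auc
        assert roc_auc(np.log(s), labels).auc == pytest.approx(base)
        assert roc_auc(s**3, labels).auc == pytest.approx(base)

    def test_roc_points_monotone(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        labels[0], labels[1] = True, False
        roc = roc_auc(scores, labels)
        assert np.all(np.diff(roc.tpr) <= 0)  # thresholds ascend, rates fall
        assert np.all(np.diff(roc.fpr) <= 0)

    def test_optimal_threshold_tie_prefers_specificity(self):
        # two cutpoints equidistant from the corner; the more specific one wins
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([0, 1, 0, 1])
        opt = optimal_threshold(roc_auc(scores, labels))
        sens, spec, _ = evaluate_threshold(scores, labels, opt.optimal_threshold)
        alt = [
            evaluate_threshold(scores, labels, t)
            for t in (1.5, 2.5, 3.5)
        ]
        d = np.sqrt((1 - sens) ** 2 + (1 - spec) ** 2)
        assert all(d <= np.sqrt((1 - s) ** 2 + (1 - p) ** 2) + 1e-12 for s, p, _ in alt)
        assert opt.optimal_threshold == pytest.approx(3.5)  # the more specific of the tied pair


class TestHedgesG:
    def test_null_effect(self):
        assert hedges_g([5.0, 6.0, 7.0], 6.0) == 0.0

    def test_hand_computed_example(self):
        """(40, 42, 44) vs 38: J = 4/7, g = (4/7) * 4 / 2 = 8/7."""
        assert hedges_g([40.0, 42.0, 44.0], 38.0) == pytest.approx(8 / 7)

    @pytest.mark.parametrize("mean_shift", [-3.0, -0.5, 0.5, 3.0])
    def test_sign_property(self, mean_shift):
        x = np.array([1.0, 2.0, 3.0]) + mean_shift
        assert np.sign(hedges_g(x, 2.0)) == np.sign(mean_shift)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedEffectError):
            hedges_g([4.0, 4.0, 4.0], 2.0)

    def test_single_replicate_rejected(self):
        with pytest.raises(UndefinedEffectError):
            hedges_g([4.0], 2.0)
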