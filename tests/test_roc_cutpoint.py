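import numpy as np
import pytest

from homacut import (
    auc,
    auc_bootstrap_ci,
    distance_sq,
    empirical_roc,
    optimal_cutpoint,
    percentile_table,
    plr,
    weighted_percentile,
    youden,
)
from homacut.errors import (
    DegenerateLabelsError,
    InvalidArgumentError,
    NoCutpointError,
)
from homacut.roc_cutpoint import sens_spec_at


def concordance_auc(scores, labels, weights=None):
    """Brute-force pairwise concordance oracle: 1 per win, 1/2 per tie."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    w = np.ones_like(s) if weights is None else np.asarray(weights, float)
    num = den = 0.0
    for i in np.flatnonzero(y):
        for j in np.flatnonzero(~y):
            ww = w[i] * w[j]
            den += ww
            if s[i] > s[j]:
                num += ww
            elif s[i] == s[j]:
                num += 0.5 * ww
    return num / den


def random_fixture(rng, n_max=50, weighted=True, ties=True):
    n = int(rng.integers(4, n_max + 1))
    while True:
        y = rng.random(n) < rng.uniform(0.2, 0.8)
        if y.any() and (~y).any():
            break
    if ties:
        s = rng.integers(0, max(2, n // 2), size=n).astype(float)
    else:
        s = rng.normal(size=n)
    w = rng.uniform(0.2, 3.0, size=n) if weighted else None
    return s, y, w


class TestPointwiseCriteria:
    def test_youden_examples(self):
        assert youden(1.0, 1.0) == (1.0, 2.0)
        j, plus_one = youden(0.5, 0.5)
        assert j == pytest.approx(0.0) and plus_one == pytest.approx(1.0)
        j, plus_one = youden(0.573, 0.653)
        assert j == pytest.approx(0.226)
        assert plus_one == pytest.approx(1.226)

    def test_distance_examples(self):
        assert distance_sq(1.0, 1.0) == 0.0
        assert distance_sq(0.5, 0.5) == pytest.approx(0.5)
        assert distance_sq(0.0, 0.0) == pytest.approx(2.0)

    def test_plr_examples(self):
        assert plr(0.5, 0.75) == pytest.approx(2.0)
        assert plr(0.5, 0.5) == pytest.approx(1.0)
        assert plr(0.8, 1.0) == np.inf

    @pytest.mark.parametrize("fn", [youden, distance_sq, plr])
    def test_out_of_range_rejected(self, fn):
        with pytest.raises(InvalidArgumentError):
            fn(1.2, 0.5)


class TestEmpiricalRoc:
    def test_small_fixture_threshold_by_threshold(self):
        roc = empirical_roc([1.0, 2.0, 3.0, 4.0], [False, False, True, True])
        assert roc.thresholds == pytest.approx([-np.inf, 1.5, 2.5, 3.5, np.inf])
        i = list(roc.thresholds).index(2.5)
        assert roc.sensitivity[i] == 1.0 and roc.specificity[i] == 1.0

    def test_endpoints(self, rng):
        s, y, w = random_fixture(rng)
        roc = empirical_roc(s, y, w)
        assert (roc.sensitivity[0], roc.specificity[0]) == (1.0, 0.0)
        assert (roc.sensitivity[-1], roc.specificity[-1]) == (0.0, 1.0)
        assert (np.diff(roc.sensitivity) <= 1e-15).all()
        assert (np.diff(roc.specificity) >= -1e-15).all()

    def test_all_tied_scores_only_sentinels(self):
        roc = empirical_roc([2.0, 2.0, 2.0], [True, False, True])
        assert list(roc.thresholds) == [-np.inf, np.inf]
        assert auc(roc) == pytest.approx(0.5)

    def test_single_class_signals(self):
        with pytest.raises(DegenerateLabelsError):
            empirical_roc([1.0, 2.0], [True, True])

    def test_perfect_separation(self):
        roc = empirical_roc([1, 2, 10, 11], [False, False, True, True])
        assert auc(roc) == pytest.approx(1.0)


class TestAucProperties:
    def test_matches_concordance_oracle(self, rng):
        for _ in range(25):
            s, y, w = random_fixture(rng)
            assert auc(empirical_roc(s, y, w)) == pytest.approx(
                concordance_auc(s, y, w), abs=1e-12
            )

    def test_label_swap_maps_to_complement(self, rng):
        s, y, w = random_fixture(rng)
        assert auc(empirical_roc(s, ~y, w)) == pytest.approx(
            1.0 - auc(empirical_roc(s, y, w)), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self, rng):
        s, y, w = random_fixture(rng)
        assert auc(empirical_roc(np.exp(2.0 * s), y, w)) == pytest.approx(
            auc(empirical_roc(s, y, w)), abs=1e-12
        )

    def test_independent_labels_near_half(self, rng):
        n = 20000
        s = rng.normal(size=n)
        y = rng.random(n) < 0.4
        assert auc(empirical_roc(s, y)) == pytest.approx(0.5, abs=0.02)


class TestOptimalCutpoint:
    def _brute_force(self, s, y, w, method):
        uniq = np.unique(s)
        mids = (uniq[:-1] + uniq[1:]) / 2.0
        best_val, best_thr = None, None
        for t in mids:
            sens, spec = sens_spec_at(s, y, w, t)
            val = sens + spec - 1.0 if method == "youden" else (1 - sens) ** 2 + (1 - spec) ** 2
            better = (
                best_val is None
                or (method == "youden" and val > best_val + 1e-15)
                or (method == "distance" and val < best_val - 1e-15)
            )
            if better:
                best_val, best_thr = val, t
        return best_val, best_thr

    @pytest.mark.parametrize("method", ["youden", "distance"])
    def test_matches_exhaustive_enumeration(self, method, rng):
        for _ in range(30):
            s, y, w = random_fixture(rng)
            if len(np.unique(s)) < 2:
                continue
            cp = optimal_cutpoint(empirical_roc(s, y, w), method)
            best_val, _ = self._brute_force(s, y, w, method)
            got = cp.youden_j if method == "youden" else cp.distance_sq
            assert got == pytest.approx(best_val, abs=1e-12)

    def test_tie_breaks_to_lowest_threshold_with_plateau(self):
        # alternating labels: J = 0.5 at both outer midpoints, 0 between,
        # so the optimum is a two-point plateau resolved to the lower edge
        s = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([False, True, False, True])
        cp = optimal_cutpoint(empirical_roc(s, y), "youden")
        assert cp.threshold == 1.5
        assert cp.plateau == (1.5, 3.5)
        assert cp.youden_j == pytest.approx(0.5)

    def test_perfect_separation_single_optimum(self):
        s = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([False, False, True, True])
        cp = optimal_cutpoint(empirical_roc(s, y), "youden")
        assert cp.threshold == 1.5
        assert cp.plateau == (1.5, 1.5)
        assert cp.sensitivity == 1.0 and cp.specificity == 1.0

    def test_youden_and_distance_agree_on_symmetric_curve(self, rng):
        neg = rng.normal(0, 1, 300)
        pos = rng.normal(1.2, 1, 300)
        s = np.concatenate([neg, pos])
        y = np.repeat([False, True], 300)
        roc = empirical_roc(s, y)
        ty = optimal_cutpoint(roc, "youden").threshold
        td = optimal_cutpoint(roc, "distance").threshold
        assert abs(ty - td) < 0.35  # same plateau region of a symmetric ROC

    def test_planted_separation_recovered(self, rng):
        c = 5.0
        s = np.concatenate([rng.uniform(0, c - 0.1, 200), rng.uniform(c + 0.1, 10, 200)])
        y = np.repeat([False, True], 200)
        cp = optimal_cutpoint(empirical_roc(s, y), "youden")
        gap = np.diff(np.sort(s)).max()
        assert abs(cp.threshold - c) <= gap

    def test_degenerate_curve_signals(self):
        with pytest.raises(NoCutpointError):
            optimal_cutpoint(empirical_roc([1.0, 1.0], [True, False]), "youden")

    def test_unknown_method_rejected(self):
        with pytest.raises(InvalidArgumentError):
            optimal_cutpoint(empirical_roc([1.0, 2.0], [False, True]), "topleft")

    def test_result_internal_consistency(self, rng):
        s, y, w = random_fixture(rng, ties=False)
        cp = optimal_cutpoint(empirical_roc(s, y, w), "distance")
        assert cp.youden_j == pytest.approx(cp.sensitivity + cp.specificity - 1)
        assert cp.youden_plus_one == pytest.approx(cp.youden_j + 1)
        assert cp.distance_sq == pytest.approx(
            (1 - cp.sensitivity) ** 2 + (1 - cp.specificity) ** 2
        )


class TestPercentileTable:
    def test_default_grid_has_ten_rows(self, rng):
        s, y, w = random_fixture(rng, n_max=40, ties=False)
        table = percentile_table(s, y, w)
        assert list(table["percentile"]) == list(range(50, 100, 5))

    def test_sensitivity_non_increasing(self, rng):
        s, y, w = random_fixture(rng, n_max=40)
        table = percentile_table(s, y, w)
        assert (np.diff(table["sensitivity"]) <= 1e-12).all()
        assert (np.diff(table["specificity"]) >= -1e-12).all()

    def test_cells_match_brute_force(self, rng):
        s = rng.normal(size=20)
        y = np.r_[np.ones(8, bool), np.zeros(12, bool)]
        w = rng.uniform(0.5, 2.0, size=20)
        table = percentile_table(s, y, w)
        for _, row in table.iterrows():
            t = weighted_percentile(s, w, row["percentile"])
            assert row["threshold"] == pytest.approx(t)
            sens = w[y & (s >= t)].sum() / w[y].sum()
            spec = w[~y & (s < t)].sum() / w[~y].sum()
            assert row["sensitivity"] == pytest.approx(sens)
            assert row["specificity"] == pytest.approx(spec)
            expected_plr = np.inf if spec == 1 else sens / (1 - spec)
            assert row["plr"] == pytest.approx(expected_plr)


class TestBootstrapCi:
    def test_reproducible_and_contains_point_estimate(self, rng):
        s, y, w = random_fixture(rng, n_max=50, ties=False)
        lo1, hi1 = auc_bootstrap_ci(s, y, w, n_boot=300, seed=42)
        lo2, hi2 = auc_bootstrap_ci(s, y, w, n_boot=300, seed=42)
        assert (lo1, hi1) == (lo2, hi2)
        point = auc(empirical_roc(s, y, w))
        assert lo1 <= point <= hi1
        lo3, _ = auc_bootstrap_ci(s, y, w, n_boot=300, seed=43)
        assert lo3 != lo1  # different seed, different resamples

    def test_requires_minimum_replicates(self):
        with pytest.raises(InvalidArgumentError):
            auc_bootstrap_ci([1.0, 2.0], [False, True], n_boot=50)

    def test_single_class_signals(self):
        with pytest.raises(DegenerateLabelsError):
            auc_bootstrap_ci([1.0, 2.0], [True, True], n_boot=200)
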