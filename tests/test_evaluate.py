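import numpy as np
import pytest
from scipy import stats

from radview.evaluate import (
    Prediction,
    classify,
    clopper_pearson,
    compare_groups,
    perturb,
    text_stamp_bbox,
    youden_cutoff,
)
from radview.records import ImageRecord


def preds(frontal_pfis, lateral_pfis):
    out = [Prediction(f"f{i}", p, "frontal") for i, p in enumerate(frontal_pfis)]
    out += [Prediction(f"l{i}", p, "lateral") for i, p in enumerate(lateral_pfis)]
    return out


def youden_oracle(predictions):
    """Exhaustive J over every distinct pfi value (plus 0 and just-above-max)."""
    pf = np.array([p.pfi for p in predictions if p.label == "frontal"])
    pl = np.array([p.pfi for p in predictions if p.label == "lateral"])
    best = -2.0
    for c in sorted({0.0, *(p.pfi for p in predictions), 1.0 + 1e-9}):
        j = (pf >= c).mean() + (pl < c).mean() - 1.0
        best = max(best, j)
    return best


def cp_bisection_oracle(k, n, level=0.95):
    """Invert the exact binomial tails numerically (independent of beta ppf)."""
    alpha = 1.0 - level

    def solve(f, lo, hi):
        for _ in range(200):
            mid = (lo + hi) / 2.0
            if f(mid) > 0:
                hi = mid
            else:
                lo = mid
        return (lo + hi) / 2.0

    lower = 0.0 if k == 0 else solve(lambda p: stats.binom.sf(k - 1, n, p) - alpha / 2.0, 0.0, 1.0)
    upper = 1.0 if k == n else solve(lambda p: -(stats.binom.cdf(k, n, p) - alpha / 2.0), 0.0, 1.0)
    return lower, upper


class TestYoudenCutoff:
    def test_separated_scores_choose_highest_perfect_grid_point(self):
        rng = np.random.default_rng(0)
        fr = np.round(rng.uniform(0.99, 1.0, 20), 3)
        la = np.round(rng.uniform(0.0, 0.10, 20), 3)
        result = youden_cutoff(preds(fr, la))
        assert result.max_j == 1.0
        assert result.chosen_cutoff == pytest.approx(fr.min())
        assert result.max_range[1] == result.chosen_cutoff

    def test_perfect_zero_one_scores_choose_top_of_grid(self):
        result = youden_cutoff(preds([1.0] * 5, [0.0] * 5))
        assert result.max_j == 1.0
        assert result.chosen_cutoff == 1.0

    def test_uninformative_scores_give_zero_j(self):
        result = youden_cutoff(preds([0.7] * 4, [0.7] * 4))
        assert result.max_j == pytest.approx(0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_cutoff([Prediction("a", 0.5, "frontal")])

    def test_matches_exhaustive_oracle_on_random_sets(self):
        """Grid maximum equals the exact maximum whenever scores lie on the
        0.001 grid, and never exceeds it."""
        rng = np.random.default_rng(42)
        for trial in range(200):
            nf, nl = rng.integers(1, 30, size=2)
            on_grid = trial % 2 == 0
            pf = rng.integers(0, 1001, size=nf) / 1000.0 if on_grid else rng.uniform(0, 1, nf)
            pl = rng.integers(0, 1001, size=nl) / 1000.0 if on_grid else rng.uniform(0, 1, nl)
            ps = preds(pf, pl)
            result = youden_cutoff(ps)
            exact = youden_oracle(ps)
            assert result.max_j <= exact + 1e-12
            if on_grid:
                assert result.max_j == pytest.approx(exact, abs=1e-12)

    def test_grid_is_zero_to_one_in_thousandths(self):
        result = youden_cutoff(preds([0.9], [0.1]))
        assert len(result.grid) == 1001
        assert result.grid[0] == 0.0 and result.grid[-1] == 1.0
        assert result.grid[1] == pytest.approx(0.001)


class TestClassify:
    def test_cutoff_zero_calls_everything_frontal(self):
        table = classify(preds([0.2, 0.9], [0.1, 0.0]), 0.0)
        assert table.true_frontal == 2 and table.false_frontal == 2

    def test_cutoff_above_max_calls_everything_lateral(self):
        table = classify(preds([0.2, 0.9], [0.1, 0.0]), 0.95)
        assert table.true_lateral == 2 and table.false_lateral == 2

    def test_hand_counted_toy_table(self):
        # frontal@0.9 -> TF; frontal@0.3 -> FL; lateral@0.6 -> FF; lateral@0.2 -> TL
        table = classify(preds([0.9, 0.3], [0.6, 0.2]), 0.5)
        assert (table.true_frontal, table.false_lateral, table.false_frontal, table.true_lateral) == (1, 1, 1, 1)
        assert table.accuracy == 0.5

    def test_counts_conserved(self, rng):
        ps = preds(rng.uniform(0, 1, 37), rng.uniform(0, 1, 23))
        for cutoff in (0.0, 0.25, 0.5, 1.0):
            assert classify(ps, cutoff).total == 60


class TestClopperPearson:
    def test_all_correct_1377(self):
        ci = clopper_pearson(1377, 1377, 0.95)
        assert round(ci.lower, 4) == 0.9973
        assert ci.upper == 1.0
        # closed form for k = n: lower = (alpha/2)^(1/n)
        assert ci.lower == pytest.approx(0.025 ** (1 / 1377), rel=1e-12)

    def test_zero_successes(self):
        ci = clopper_pearson(0, 10)
        assert ci.lower == 0.0
        assert 0 < ci.upper < 1

    def test_matches_binomial_tail_bisection(self):
        for n in (5, 10, 50):
            for k in range(0, n + 1, max(1, n // 5)):
                lo, hi = cp_bisection_oracle(k, n)
                ci = clopper_pearson(k, n)
                assert ci.lower == pytest.approx(lo, abs=1e-9)
                assert ci.upper == pytest.approx(hi, abs=1e-9)

    def test_interval_brackets_point_estimate(self):
        for k, n in [(0, 5), (3, 7), (10, 10), (250, 400)]:
            ci = clopper_pearson(k, n)
            assert 0 <= ci.lower <= k / n <= ci.upper <= 1

    def test_nesting_99_contains_95(self):
        for k, n in [(0, 8), (4, 9), (7, 10), (99, 100), (123, 456)]:
            ci95 = clopper_pearson(k, n, 0.95)
            ci99 = clopper_pearson(k, n, 0.99)
            assert ci99.lower <= ci95.lower and ci99.upper >= ci95.upper

    def test_conservative_coverage(self):
        """Over 2000 simulated binomial draws at p=0.8, n=50, the exact 95%
        interval covers p at least 95% of the time."""
        rng = np.random.default_rng(7)
        ks = rng.binomial(50, 0.8, size=2000)
        covered = 0
        for k in ks:
            ci = clopper_pearson(int(k), 50)
            covered += ci.lower <= 0.8 <= ci.upper
        assert covered / 2000 >= 0.95

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)
        with pytest.raises(ValueError):
            clopper_pearson(0, 0)
        with pytest.raises(ValueError):
            clopper_pearson(1, 2, level=1.0)


class TestCompareGroups:
    def test_homogeneous_rows_give_zero_chi2(self):
        gc = compare_groups([(50, 50), (50, 50)], ["a", "b"])
        assert gc.chi2 == pytest.approx(0.0)
        assert gc.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # pooled table [[90,10],[50,50]]: E = [[70,30],[70,30]]
        expected = (20**2 / 70 + 20**2 / 30) * 2
        gc = compare_groups([(90, 10), (50, 50)], ["a", "b"])
        assert gc.chi2 == pytest.approx(expected)

    def test_group_order_symmetric(self):
        a = compare_groups([(80, 20), (40, 60)], ["x", "y"])
        b = compare_groups([(40, 60), (80, 20)], ["y", "x"])
        assert a.chi2 == pytest.approx(b.chi2)
        assert a.p == pytest.approx(b.p)

    def test_pools_by_summation(self):
        gc = compare_groups([(30, 5), (60, 5), (40, 10)], ["g1", "g1", "g2"])
        assert np.array_equal(gc.counts, np.array([[90, 10], [40, 10]]))

    def test_matches_brute_force_oe_on_random_tables(self, rng):
        """Pearson statistic equals the hand Σ(O−E)²/E on random 2x2 tables."""
        for _ in range(100):
            o = rng.integers(1, 250, size=(2, 2)).astype(float)  # totals <= 1000
            gc = compare_groups([(int(o[0, 0]), int(o[0, 1])), (int(o[1, 0]), int(o[1, 1]))], ["a", "b"])
            total = o.sum()
            e = np.outer(o.sum(1), o.sum(0)) / total
            chi2_hand = ((o - e) ** 2 / e).sum()
            assert gc.chi2 == pytest.approx(chi2_hand, rel=1e-12)
            assert gc.p == pytest.approx(stats.chi2.sf(chi2_hand, 1), rel=1e-9)

    def test_no_outcome_variation_is_homogeneous(self):
        gc = compare_groups([(50, 0), (70, 0)], ["a", "b"])
        assert gc.chi2 == 0.0 and gc.p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([(0, 0), (5, 5)], ["a", "b"])
        with pytest.raises(ValueError):
            compare_groups([(5, 5)], ["a"])


class TestPerturb:
    @pytest.fixture
    def record(self, noisy_phantom):
        return ImageRecord(image_id="t", pixels=noisy_phantom, label="frontal")

    def test_obscure_half_masks_exactly_one_half(self, record):
        out = perturb(record, "obscure_half", side="left")
        w = record.pixels.shape[1]
        assert (out.pixels[:, : w // 2] == 0).all()
        assert np.array_equal(out.pixels[:, w // 2 :], record.pixels[:, w // 2 :])

    def test_full_frame_crop_is_identity(self, record):
        out = perturb(record, "crop", fraction=1.0)
        assert np.array_equal(out.pixels, record.pixels)

    def test_crop_preserves_shape(self, record):
        out = perturb(record, "crop", fraction=0.6)
        assert out.pixels.shape == record.pixels.shape

    def test_text_label_changes_exactly_the_stamp_block(self):
        base = ImageRecord(image_id="c", pixels=np.full((64, 64), 128, dtype=np.uint8), label="frontal")
        out = perturb(base, "text_label")
        diff = np.argwhere(out.pixels != base.pixels)
        r0, r1, c0, c1 = text_stamp_bbox((64, 64))
        assert diff[:, 0].min() == r0 and diff[:, 0].max() == r1 - 1
        assert diff[:, 1].min() == c0 and diff[:, 1].max() == c1 - 1
        # nothing outside the block moved
        mask = np.zeros((64, 64), bool)
        mask[r0:r1, c0:c1] = True
        assert not (out.pixels != base.pixels)[~mask].any()

    def test_rotate_preserves_shape_and_sets_lineage(self, record):
        out = perturb(record, "rotate", angle=15)
        assert out.pixels.shape == record.pixels.shape
        assert out.parent_id == record.image_id
        assert out.label == record.label

    def test_unknown_kind_rejected(self, record):
        with pytest.raises(ValueError):
            perturb(record, "invert")
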