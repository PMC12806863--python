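import numpy as np
import pytest

from grincd.core_io import GeneRoster, GoldStandard, RankedEdgeList
from grincd.evaluation import (
    NullDistribution,
    auroc_aupr,
    confidence_score,
    curve_points,
    epr,
    evaluate,
    random_null,
)


def _universe(n_tfs, n_tgs):
    roster = GeneRoster(
        tfs=tuple(f"T{i}" for i in range(n_tfs)),
        targets=tuple(f"G{i}" for i in range(n_tgs)),
    )
    return roster, list(roster.admissible_pairs())


def _ranking(pairs):
    L = len(pairs)
    return RankedEdgeList(
        rows=tuple((r, t, float(L - i)) for i, (r, t) in enumerate(pairs))
    )


class TestCurvePoints:
    def test_perfect_ranking_has_unit_areas(self):
        roster, pairs = _universe(3, 4)
        gold = GoldStandard(roster=roster, positives=frozenset(pairs[:5]))
        ranked = _ranking(pairs[:5] + pairs[5:])
        auroc, aupr = auroc_aupr(curve_points(ranked, gold))
        assert auroc == pytest.approx(1.0)
        assert aupr == pytest.approx(1.0)

    def test_reversed_perfect_ranking_scores_zero_auroc(self):
        roster, pairs = _universe(3, 4)
        gold = GoldStandard(roster=roster, positives=frozenset(pairs[:5]))
        ranked = _ranking(pairs[5:] + pairs[:5])
        auroc, _ = auroc_aupr(curve_points(ranked, gold))
        assert auroc == pytest.approx(0.0)

    def test_filling_formula_hand_value(self):
        """T=10, P=4, L=5, TP_L=3: at k=8, dTP = 3*1/5 = 0.6, recall 0.9."""
        roster, pairs = _universe(2, 4)  # T = 2*5 = 10
        assert roster.n_admissible_pairs == 10
        positives = [pairs[0], pairs[2], pairs[4], pairs[6]]
        gold = GoldStandard(roster=roster, positives=frozenset(positives))
        # list of length 5 containing 3 of the positives
        listed = [pairs[0], pairs[2], pairs[4], pairs[1], pairs[3]]
        points = curve_points(_ranking(listed), gold)
        k8 = points.k.tolist().index(8)
        assert points.tp[k8] == pytest.approx(3 + 0.6)
        assert points.tpr[k8] == pytest.approx(0.9)
        assert points.precision[k8] == pytest.approx(3.6 / 8)
        assert points.fp[k8] == pytest.approx(8 - 3.6)

    def test_exact_branch_matches_sklearn(self, rng):
        from sklearn.metrics import average_precision_score, roc_auc_score

        roster, pairs = _universe(4, 10)
        T = len(pairs)
        for _ in range(10):
            pos_idx = rng.choice(T, size=12, replace=False)
            gold = GoldStandard(
                roster=roster, positives=frozenset(pairs[i] for i in pos_idx)
            )
            order = rng.permutation(T)
            ranked = _ranking([pairs[i] for i in order])
            auroc, aupr = auroc_aupr(curve_points(ranked, gold))
            y_true = np.array([pairs[i] in gold.positives for i in order])
            y_score = -np.arange(T, dtype=float)
            assert auroc == pytest.approx(roc_auc_score(y_true, y_score), abs=1e-9)
            assert aupr == pytest.approx(
                average_precision_score(y_true, y_score), abs=1e-9
            )

    def test_foreign_pair_rejected(self):
        roster, pairs = _universe(2, 3)
        gold = GoldStandard(roster=roster, positives=frozenset(pairs[:2]))
        bad = RankedEdgeList(rows=(("G0", "G1", 1.0),))
        with pytest.raises(ValueError, match="outside"):
            curve_points(bad, gold)

    def test_filled_recall_monotone_and_bounded(self, rng):
        roster, pairs = _universe(3, 6)
        gold = GoldStandard(roster=roster, positives=frozenset(pairs[::4]))
        ranked = _ranking([pairs[i] for i in rng.permutation(len(pairs))[:8]])
        points = curve_points(ranked, gold)
        assert np.all(np.diff(points.tpr) >= -1e-12)
        L, P = points.list_length, points.n_positives
        tp_L = points.tp[L - 1]
        dtp = points.tp[L:] - tp_L
        assert np.all(dtp >= 0) and np.all(dtp <= P - tp_L + 1e-12)


class TestFillingOracle:
    def test_filled_auroc_matches_random_completions(self, rng):
        """The Eq-filled area equals the Monte-Carlo mean over uniformly
        random completions of a truncated list (T=50, P=10, L=20)."""
        roster, pairs = _universe(5, 6)  # 5 TFs * (11 - 1) genes = 50 pairs
        T = len(pairs)
        assert T == 50
        gold = GoldStandard(
            roster=roster,
            positives=frozenset(pairs[i] for i in rng.choice(T, 10, replace=False)),
        )
        order = rng.permutation(T)
        head = [pairs[i] for i in order[:20]]
        tail = [pairs[i] for i in order[20:]]
        filled_auroc, _ = auroc_aupr(curve_points(_ranking(head), gold))

        completions = []
        for _ in range(3000):
            completion = head + [tail[i] for i in rng.permutation(len(tail))]
            full_auroc, _ = auroc_aupr(curve_points(_ranking(completion), gold))
            completions.append(full_auroc)
        mc_mean = np.mean(completions)
        mc_se = np.std(completions) / np.sqrt(len(completions))
        assert abs(filled_auroc - mc_mean) <= 3 * mc_se + 1e-12


class TestRandomNull:
    def test_auroc_null_centered_at_half(self, toy_gold):
        null = random_null(toy_gold, n=400, seed=5, metric="auroc")
        se = null.samples.std() / np.sqrt(null.samples.size)
        assert abs(null.samples.mean() - 0.5) < 3 * se + 0.01

    def test_aupr_null_centered_near_density(self, rng):
        """A random predictor's precision is the gold density P/T; the
        step-wise PR area of a finite random ranking sits slightly above
        it (early-rank harmonic inflation), vanishing as T grows."""
        roster, pairs = _universe(5, 36)  # T = 200
        T = len(pairs)
        gold = GoldStandard(
            roster=roster,
            positives=frozenset(pairs[i] for i in rng.choice(T, 30, replace=False)),
        )
        null = random_null(gold, n=400, seed=2, metric="aupr")
        density = gold.n_positives / gold.universe_size
        assert density <= null.samples.mean() <= density + 0.05

    def test_seeded_determinism(self, toy_gold):
        a = random_null(toy_gold, n=50, seed=7)
        b = random_null(toy_gold, n=50, seed=7)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_matches_direct_evaluation_of_permutations(self, rng):
        """The fast position-based null equals evaluating an explicitly
        permuted full ranking."""
        roster, pairs = _universe(2, 4)
        gold = GoldStandard(roster=roster, positives=frozenset(pairs[:3]))
        for seed in range(5):
            prng = np.random.default_rng(seed)
            order = prng.permutation(len(pairs))
            ranked = _ranking([pairs[i] for i in order])
            auroc, aupr = auroc_aupr(curve_points(ranked, gold))
            pos = np.sort([int(np.where(order == i)[0][0])
                           for i, p in enumerate(pairs) if p in gold.positives]) + 1
            from grincd.evaluation import _auroc_from_positions, _aupr_from_positions

            assert auroc == pytest.approx(
                _auroc_from_positions(pos, 3, len(pairs) - 3), abs=1e-12
            )
            assert aupr == pytest.approx(_aupr_from_positions(pos, 3), abs=1e-12)


class TestConfidenceScore:
    def test_null_median_scores_about_point_three(self, rng):
        samples = rng.normal(0.5, 0.05, 2000)
        null = NullDistribution("auroc", np.clip(samples, 0, 1), 2000)
        score = confidence_score(float(np.median(null.samples)), null)
        assert score == pytest.approx(-np.log10(0.5), abs=0.05)

    def test_value_below_null_scores_near_zero(self, rng):
        samples = np.clip(rng.normal(0.5, 0.05, 1000), 0, 1)
        null = NullDistribution("auroc", samples, 1000)
        assert confidence_score(0.0, null) < 0.01

    def test_extreme_value_engages_cap(self, rng):
        samples = np.clip(rng.normal(0.5, 0.02, 5000), 0, 1)
        null = NullDistribution("auroc", samples, 5000)
        assert confidence_score(1.0, null) == 100.0

    def test_monotone_in_value(self, rng):
        samples = np.clip(rng.normal(0.5, 0.05, 1000), 0, 1)
        null = NullDistribution("auroc", samples, 1000)
        values = np.linspace(0.3, 0.9, 13)
        scores = [confidence_score(v, null) for v in values]
        assert all(b >= a - 1e-9 for a, b in zip(scores, scores[1:]))

    def test_small_null_rejected(self):
        null = NullDistribution("auroc", np.full(10, 0.5), 10)
        with pytest.raises(ValueError, match="100 samples"):
            confidence_score(0.6, null)


class TestEpr:
    def test_perfect_ranking_reaches_inverse_density(self):
        roster, pairs = _universe(3, 5)
        gold = GoldStandard(roster=roster, positives=frozenset(pairs[:7]))
        ranked = _ranking(pairs)
        assert epr(ranked, gold) == pytest.approx(gold.universe_size / 7)

    def test_saturated_gold_pins_epr_to_one(self):
        roster, pairs = _universe(2, 2)
        gold = GoldStandard(roster=roster, positives=frozenset(pairs))
        assert epr(_ranking(pairs), gold) == pytest.approx(1.0)

    def test_random_rankings_average_to_one(self, rng):
        roster, pairs = _universe(3, 6)
        T = len(pairs)
        gold = GoldStandard(
            roster=roster,
            positives=frozenset(pairs[i] for i in rng.choice(T, 6, replace=False)),
        )
        values = []
        for _ in range(200):
            order = rng.permutation(T)
            values.append(epr(_ranking([pairs[i] for i in order]), gold))
        assert 0.8 < np.mean(values) < 1.2

    def test_short_list_rejected(self):
        roster, pairs = _universe(2, 3)
        gold = GoldStandard(roster=roster, positives=frozenset(pairs[:4]))
        with pytest.raises(ValueError, match="shorter"):
            epr(_ranking(pairs[:2]), gold)


def test_evaluate_report_is_complete(toy_gold):
    roster = toy_gold.roster
    pairs = list(roster.admissible_pairs())
    ranked = RankedEdgeList(
        rows=tuple((r, t, float(len(pairs) - i)) for i, (r, t) in enumerate(pairs))
    )
    report = evaluate(ranked, toy_gold, n_null=200, seed=0)
    assert 0 <= report.auroc <= 1
    assert 0 <= report.aupr <= 1
    assert 0 <= report.confidence_auroc <= 100
    assert report.confidence_mean == pytest.approx(
        (report.confidence_auroc + report.confidence_aupr) / 2
    )
    assert report.epr >= 0
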