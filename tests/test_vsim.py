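"""Screening-rank similarity, score fusion and BEDROC early recognition."""

import numpy as np
import pytest

from pocketrepo import fixtures
from pocketrepo.vsim import (
    RankList,
    RecognitionCase,
    bedroc,
    combine_scores,
    evaluate_recognition,
    random_baseline,
    rank_list_from_scores,
    read_rank_list,
    spearman_rho,
    write_rank_list,
)


def _ranklist(target, ranks):
    # scores equal to ranks give exactly those ranks back
    return rank_list_from_scores(target, {f"c{i}": float(r) for i, r in enumerate(ranks)})


class TestSpearman:
    def test_identical_rankings(self):
        a = _ranklist("a", range(1, 11))
        b = _ranklist("b", range(1, 11))
        assert spearman_rho(a, b).rho == pytest.approx(1.0)

    def test_reversed_rankings(self):
        a = _ranklist("a", range(1, 11))
        b = _ranklist("b", range(10, 0, -1))
        assert spearman_rho(a, b).rho == pytest.approx(-1.0)

    def test_single_swap_classic_value(self):
        a = _ranklist("a", [1, 2, 3, 4, 5])
        b = _ranklist("b", [1, 2, 3, 5, 4])
        # 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 12/120
        assert spearman_rho(a, b).rho == pytest.approx(0.9)

    def test_monotone_transform_invariance(self, rng):
        scores = {f"c{i}": float(s) for i, s in enumerate(rng.normal(size=30))}
        a = rank_list_from_scores("a", scores)
        cubed = rank_list_from_scores("a2", {k: v**3 for k, v in scores.items()})
        other = rank_list_from_scores("b", {k: float(rng.normal()) for k in scores})
        assert spearman_rho(a, other).rho == pytest.approx(
            spearman_rho(cubed, other).rho, abs=1e-12
        )

    def test_symmetry(self, rng):
        a = rank_list_from_scores("a", {f"c{i}": float(rng.normal()) for i in range(20)})
        b = rank_list_from_scores("b", {f"c{i}": float(rng.normal()) for i in range(20)})
        assert spearman_rho(a, b).rho == pytest.approx(spearman_rho(b, a).rho)

    def test_too_few_common_compounds(self):
        a = _ranklist("a", [1, 2, 3])
        b = rank_list_from_scores("b", {"x1": 1.0, "x2": 2.0, "x3": 3.0})
        with pytest.raises(ValueError, match="common"):
            spearman_rho(a, b)

    def test_partial_overlap_uses_common_subset(self):
        a = rank_list_from_scores("a", {"c1": 1.0, "c2": 2.0, "c3": 3.0, "only_a": 0.5})
        b = rank_list_from_scores("b", {"c1": 1.0, "c2": 2.0, "c3": 3.0, "only_b": 9.0})
        sim = spearman_rho(a, b)
        assert sim.n_common == 3
        assert sim.rho == pytest.approx(1.0)

    def test_rank_list_roundtrip(self, tmp_path, rng):
        rl = rank_list_from_scores("t", {f"c{i}": float(rng.normal()) for i in range(10)})
        path = tmp_path / "ranks.tsv"
        write_rank_list(rl, path)
        back = read_rank_list(path, "t")
        assert back.entries == rl.entries

    def test_rank_validation(self):
        with pytest.raises(ValueError, match="average ranks"):
            RankList(target_id="bad", entries={"a": (0.1, 1.0), "b": (0.2, 3.0)})


class TestCombineScores:
    def test_both_maximal(self):
        assert combine_scores(1.0, 1.0) == 1.0

    def test_negative_rho_clamped(self):
        assert combine_scores(0.8, -0.5) == pytest.approx(0.4)
        assert combine_scores(0.8, 0.0) == pytest.approx(0.4)

    def test_example_fusion_value(self):
        # structure score 0.97 with screening correlation 0.86
        assert combine_scores(0.97, 0.86) == pytest.approx(0.915)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            combine_scores(1.2, 0.0)
        with pytest.raises(ValueError):
            combine_scores(0.5, -1.5)


def _case(ranks_of_actives, n_total, query="q"):
    """Candidates scored so actives land exactly at the given 1-based ranks."""
    actives = set(ranks_of_actives)
    cands = [
        (f"c{r:04d}", float(n_total - r), r in actives) for r in range(1, n_total + 1)
    ]
    return RecognitionCase(query_id=query, candidates=cands)


def _bedroc_brute(ranks, n_total, alpha):
    """Independent oracle: direct exponential sum with min/max normalization."""
    ranks = np.asarray(ranks, dtype=float)
    n = len(ranks)
    s = np.sum(np.exp(-alpha * ranks / n_total))
    smax = np.sum(np.exp(-alpha * np.arange(1, n + 1) / n_total))
    smin = np.sum(np.exp(-alpha * np.arange(n_total - n + 1, n_total + 1) / n_total))
    return (s - smin) / (smax - smin)


class TestBedroc:
    def test_all_actives_first(self):
        case = _case(range(1, 6), 100)
        assert bedroc(case, alpha=20) >= 0.99

    def test_all_actives_last(self):
        case = _case(range(96, 101), 100)
        assert bedroc(case, alpha=20) <= 0.01

    def test_matches_brute_force_normalization(self, rng):
        for _ in range(100):
            n_total = int(rng.integers(10, 200))
            n_act = int(rng.integers(1, n_total))
            ranks = rng.choice(np.arange(1, n_total + 1), size=n_act, replace=False)
            alpha = float(rng.uniform(2, 40))
            case = _case(ranks.tolist(), n_total)
            assert bedroc(case, alpha=alpha) == pytest.approx(
                _bedroc_brute(ranks, n_total, alpha), abs=1e-9
            )

    def test_random_mean_matches_analytic_expectation(self, rng):
        # mean over random rankings ~ closed form at RIE = 1
        alpha, n_total, n_act = 20.0, 100, 5
        ra = n_act / n_total
        analytic = (
            ra * np.sinh(alpha / 2) / (np.cosh(alpha / 2) - np.cosh(alpha / 2 - alpha * ra))
            + 1.0 / (1 - np.exp(alpha * (1 - ra)))
        )
        vals = []
        for _ in range(1000):
            ranks = rng.choice(np.arange(1, n_total + 1), size=n_act, replace=False)
            vals.append(bedroc(_case(ranks.tolist(), n_total), alpha=alpha))
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - analytic) < 3 * se

    def test_early_swap_never_decreases(self, rng):
        # promoting an active above an inactive can only help
        for _ in range(20):
            n_total = 50
            ranks = sorted(rng.choice(np.arange(2, n_total + 1), size=5, replace=False))
            before = bedroc(_case(list(ranks), n_total))
            promoted = [ranks[0] - 1] + list(ranks[1:])
            after = bedroc(_case(promoted, n_total))
            assert after >= before - 1e-12

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError):
            RecognitionCase("q", [("a", 1.0, True), ("b", 0.5, True)])


class TestEvaluateRecognition:
    def test_median_of_three(self):
        cases = [_case(range(1, 3), 20, query=f"q{i}") for i in range(3)]
        # manipulate scores so BEDROCs differ: shift active ranks
        cases = [
            _case([1, 2], 20, "a"),     # high
            _case([8, 12], 20, "b"),    # middling
            _case([18, 19], 20, "c"),   # low
        ]
        summary = evaluate_recognition(cases)
        vals = sorted(summary.per_case.values())
        assert summary.median == pytest.approx(vals[1])

    def test_single_case_median(self):
        case = _case([1, 5], 20)
        summary = evaluate_recognition([case])
        assert summary.median == pytest.approx(bedroc(case))

    def test_planted_signal_beats_shuffled(self, rng):
        signal_cases, shuffled_cases = [], []
        for s in range(10):
            case, _, _ = fixtures.make_screen_library(100, 5, enrichment=2.0, seed=s)
            signal_cases.append(case)
            shuffled_cases.append(
                RecognitionCase(
                    query_id=case.query_id,
                    candidates=[
                        (cid, float(rng.uniform()), act)
                        for cid, _, act in case.candidates
                    ],
                )
            )
        assert (
            evaluate_recognition(signal_cases).median
            > evaluate_recognition(shuffled_cases).median
        )


class TestRandomBaseline:
    def test_reproducible_under_seed(self):
        cases = [_case([1, 2], 20, f"q{i}") for i in range(3)]
        a = random_baseline(cases, n_rep=5, seed=7)
        b = random_baseline(cases, n_rep=5, seed=7)
        assert np.array_equal(a, b)

    def test_single_replicate(self):
        cases = [_case([1, 2], 20)]
        assert random_baseline(cases, n_rep=1, seed=0).shape == (1,)

    def test_baseline_below_planted_signal(self):
        cases = [
            fixtures.make_screen_library(100, 5, enrichment=3.0, seed=s)[0]
            for s in range(5)
        ]
        signal_median = evaluate_recognition(cases).median
        baseline = random_baseline(cases, n_rep=20, seed=1)
        assert np.all(baseline < signal_median)
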