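"""Choice probabilities, Thurstone Case V scaling, rank correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kendalltau, norm, spearmanr

from fishbone.psychophysics import (
    PairwiseChoiceTable,
    choice_probability,
    correlate_model_perception,
    rank_correlation,
    thurstone_scale,
)
from fishbone.synthetic import generate_choices, generate_profile


def table_of(labels, wins):
    return PairwiseChoiceTable(labels=tuple(labels), wins=np.array(wins))


class TestPairwiseChoiceTable:
    def test_validates_shape_and_diagonal(self):
        with pytest.raises(ValueError):
            table_of((1.0, 2.0), [[1, 0], [0, 0]])
        with pytest.raises(ValueError):
            table_of((1.0, 2.0), [[0, -1], [0, 0]])

    def test_from_trials_roundtrip(self):
        trials = pd.DataFrame(
            {
                "interval_a_mm": [0.4, 0.4, 1.0],
                "interval_b_mm": [1.0, 1.0, 2.0],
                "chosen_mm": [0.4, 1.0, 1.0],
            }
        )
        table = PairwiseChoiceTable.from_trials(trials)
        assert table.labels == (0.4, 1.0, 2.0)
        assert table.wins[0, 1] == 1 and table.wins[1, 0] == 1
        assert table.wins[1, 2] == 1
        np.testing.assert_array_equal(table.presentations, table.presentations.T)


class TestChoiceProbability:
    def test_always_chosen(self):
        table = table_of((1.0, 2.0), [[0, 8], [0, 0]])
        p = choice_probability(table)
        assert p[1.0] == 1.0 and p[2.0] == 0.0

    def test_symmetric_table_is_half(self):
        table = table_of((1.0, 2.0, 3.0), [[0, 4, 4], [4, 0, 4], [4, 4, 0]])
        assert np.allclose(choice_probability(table).values, 0.5)

    def test_partial_preference(self):
        # stimulus 1 chosen 6 of its 8 presentations
        table = table_of((1.0, 2.0, 3.0), [[0, 3, 3], [1, 0, 2], [1, 2, 0]])
        assert choice_probability(table)[1.0] == pytest.approx(0.75)

    def test_participant_averaging(self):
        t1 = table_of((1.0, 2.0), [[0, 4], [0, 0]])
        t2 = table_of((1.0, 2.0), [[0, 0], [4, 0]])
        p = choice_probability([t1, t2])
        assert p[1.0] == pytest.approx(0.5)

    def test_never_presented_stimulus_errors(self):
        table = table_of((1.0, 2.0, 3.0), [[0, 4, 0], [4, 0, 0], [0, 0, 0]])
        with pytest.raises(ValueError):
            choice_probability(table)


class TestThurstoneScale:
    def test_indifference_gives_zero_scale(self):
        table = table_of((1.0, 2.0, 3.0), [[0, 5, 5], [5, 0, 5], [5, 5, 0]])
        np.testing.assert_allclose(thurstone_scale(table).values, 0.0)

    def test_two_stimulus_probit_difference(self):
        table = table_of((1.0, 2.0), [[0, 76], [24, 0]])
        scale = thurstone_scale(table)
        diff = scale.values[0] - scale.values[1]
        assert diff == pytest.approx(norm.ppf(0.76), abs=1e-9)
        assert diff == pytest.approx(0.7063, abs=1e-3)

    def test_zero_presentation_pair_errors(self):
        table = table_of((1.0, 2.0, 3.0), [[0, 5, 0], [5, 0, 5], [0, 5, 0]])
        with pytest.raises(ValueError):
            thurstone_scale(table)

    def test_recovers_known_scales(self):
        profile = generate_profile("unimodal")
        table = generate_choices(profile, n_participants=1, trials_per_pair=200, seed=3)
        recovered = thurstone_scale(table)
        rho = rank_correlation(profile.values, recovered.values, "spearman")
        assert rho.coefficient >= 0.9

    def test_translation_equivariance_of_generator(self):
        base = generate_profile("unimodal")
        shifted = generate_profile("custom", values=base.values + 10.0)
        t1 = generate_choices(base, n_participants=2, trials_per_pair=20, seed=9)
        t2 = generate_choices(shifted, n_participants=2, trials_per_pair=20, seed=9)
        np.testing.assert_array_equal(t1.wins, t2.wins)


class TestRankCorrelation:
    def test_perfect_and_reversed(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        for method in ("kendall", "spearman"):
            assert rank_correlation(a, a, method).coefficient == pytest.approx(1.0)
            assert rank_correlation(a, a[::-1], method).coefficient == pytest.approx(-1.0)

    def test_hand_counted_tau(self):
        # pairs (2,3) discordant; 5 of 6 concordant -> tau = 4/6
        res = rank_correlation([1, 2, 3, 4], [1, 3, 2, 4], "kendall")
        assert res.coefficient == pytest.approx(4 / 6)

    def test_matches_brute_force_concordance_count(self):
        rng = np.random.default_rng(5)
        for n in (4, 6, 9):
            a = rng.integers(0, 5, n).astype(float)  # ties likely
            b = rng.integers(0, 5, n).astype(float)
            if np.all(a == a[0]) or np.all(b == b[0]):
                continue
            n0 = n * (n - 1) // 2
            num = ties_a = ties_b = 0
            for i, j in itertools.combinations(range(n), 2):
                sa, sb = np.sign(a[i] - a[j]), np.sign(b[i] - b[j])
                num += sa * sb
                ties_a += sa == 0
                ties_b += sb == 0
            tau_bf = num / np.sqrt((n0 - ties_a) * (n0 - ties_b))
            assert rank_correlation(a, b, "kendall").coefficient == pytest.approx(tau_bf)

    def test_agrees_with_scipy_coefficients(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=9)
        b = rng.normal(size=9)
        assert rank_correlation(a, b, "kendall").coefficient == pytest.approx(
            kendalltau(a, b).statistic
        )
        assert rank_correlation(a, b, "spearman").coefficient == pytest.approx(
            spearmanr(a, b).statistic
        )

    def test_exact_permutation_p_values(self):
        a = np.arange(9.0)
        res = rank_correlation(a, a, "kendall")
        # only 2 of 9! orderings achieve |tau| = 1
        import math

        assert res.p_value == pytest.approx(2 / math.factorial(9))
        rng = np.random.default_rng(0)
        shuffled = rank_correlation(a, rng.permutation(a), "spearman")
        assert shuffled.p_value > 0.1

    def test_constant_input_undefined(self):
        res = rank_correlation([1.0] * 5, [1, 2, 3, 4, 5], "kendall")
        assert np.isnan(res.coefficient)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            rank_correlation([1, 2], [1, 2], "kendall")
        with pytest.raises(ValueError):
            rank_correlation([1, 2, 3], [1, 2, 3], "pearson")


class TestCorrelateModelPerception:
    def _summary(self):
        intervals = [0.2, 0.4, 1.0, 1.4, 1.8]
        return pd.DataFrame(
            {
                "matrix": "PM1",
                "L2_mm": intervals,
                "mean_rate_per_ms": [0.03, 0.04, 0.02, 0.025, 0.022],
                "entropy_nats": [5.0, 5.1, 4.0, 5.2, 5.05],
            }
        )

    def test_self_correlation_is_one(self):
        summary = self._summary()
        perception = pd.Series(
            summary["entropy_nats"].values, index=summary["L2_mm"].values
        )
        out = correlate_model_perception(summary, perception)
        ent = out[(out.metric == "entropy")]
        assert np.allclose(ent["coefficient"], 1.0)

    def test_interval_mismatch_errors(self):
        summary = self._summary()
        perception = pd.Series([1.0, 2.0], index=[0.2, 0.4])
        with pytest.raises(ValueError):
            correlate_model_perception(summary, perception)

    def test_shuffled_perception_decorrelates(self):
        summary = self._summary()
        rng = np.random.default_rng(1)
        perception = pd.Series(
            rng.permutation(summary["entropy_nats"].values),
            index=summary["L2_mm"].values,
        )
        out = correlate_model_perception(summary, perception)
        assert (out["p_value"] > 0.05).any()

    def test_tidy_output_shape(self):
        summary = self._summary()
        perception = pd.Series([1, 2, 3, 4, 5.0], index=summary["L2_mm"].values)
        out = correlate_model_perception(summary, perception)
        assert set(out.columns) == {
            "matrix", "metric", "method", "coefficient", "p_value", "n",
        }
        assert len(out) == 4  # 1 matrix x 2 metrics x 2 methods
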