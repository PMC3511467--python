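import math

import numpy as np
import pandas as pd
import pytest

from discountfit import (ScoreTable, aic, bic, delta_scores,
                         pairwise_wilcoxon, winner_frequencies)


class TestCriteria:
    def test_aic_arithmetic(self):
        assert aic(-6.9315, 3) == pytest.approx(19.863)
        assert aic(0.0, 2) == 4.0
        # one extra parameter buying one loglik unit is an exact tie
        assert aic(-100.0, 3) == aic(-99.0, 4) == 206.0

    def test_bic_arithmetic(self):
        assert bic(-6.9315, 3, 100) == pytest.approx(13.863 + 3 * math.log(100))
        assert bic(-5.0, 3, 1) == 10.0  # ln 1 = 0, penalty vanishes

    def test_bic_exceeds_aic_beyond_seven_trials(self):
        for n in (8, 20, 200):
            assert bic(-10.0, 3, n) > aic(-10.0, 3)
        assert bic(-10.0, 3, 7) < aic(-10.0, 3)


def _table(data, subjects=None, models=("H", "E", "GM")):
    df = pd.DataFrame(np.asarray(data, float),
                      index=subjects or [f"s{i}" for i in range(len(data))],
                      columns=list(models))
    return ScoreTable(df, score_kind="AIC")


class TestDeltaScores:
    def test_simple_row(self):
        delta = delta_scores(_table([[10, 12, 15]]))
        assert delta.per_subject.iloc[0].tolist() == [0.0, 2.0, 5.0]

    def test_all_equal_tie_goes_to_fewest_parameters(self):
        delta = delta_scores(_table([[7, 7, 7]]))
        assert delta.per_subject.iloc[0].tolist() == [0.0, 0.0, 0.0]
        assert delta.winner.iloc[0] == "H"  # H before E; both beat GM on arity

    def test_tie_between_equal_arity_uses_canonical_order(self):
        delta = delta_scores(_table([[9, 7, 7]]))
        assert delta.winner.iloc[0] == "E"

    def test_group_delta_is_delta_of_column_sums(self):
        # 3 subjects x 2 models, worked by hand: sums (16, 15) -> (1, 0)
        tab = _table([[4, 6], [5, 2], [7, 7]], models=("GM", "R"))
        delta = delta_scores(tab)
        assert delta.group.tolist() == [1.0, 0.0]
        # and explicitly NOT the sum of per-subject deltas (0+3+0, 2+0+0)
        assert delta.per_subject.sum(axis=0).tolist() == [3.0, 2.0]

    def test_per_subject_constant_shift_invariance(self):
        base = np.array([[10.0, 12, 15], [9, 8, 20]])
        shifted = base + np.array([[100.0], [-40.0]])
        d1 = delta_scores(_table(base)).per_subject
        d2 = delta_scores(_table(shifted)).per_subject
        assert np.allclose(d1.values, d2.values)

    def test_missing_cells_rejected(self):
        tab = _table([[1, 2, np.nan]])
        with pytest.raises(ValueError, match="incomplete"):
            delta_scores(tab)


class TestWinnerFrequencies:
    def test_proportions(self):
        rows = [[0, 1, 2]] * 4 + [[3, 0, 1]] * 6
        freqs = winner_frequencies(delta_scores(_table(rows)))
        assert freqs["H"] == pytest.approx(0.4)
        assert freqs["E"] == pytest.approx(0.6)
        assert freqs.sum() == pytest.approx(1.0)

    def test_single_subject_indicator(self):
        freqs = winner_frequencies(delta_scores(_table([[5, 1, 9]])))
        assert freqs.tolist() == [0.0, 1.0, 0.0]

    def test_order_invariance(self):
        rows = [[0, 1, 2], [2, 0, 1], [1, 2, 0], [0, 2, 1]]
        f1 = winner_frequencies(delta_scores(_table(rows)))
        f2 = winner_frequencies(delta_scores(_table(rows[::-1])))
        assert f1.equals(f2)


class TestPairwiseWilcoxon:
    def test_identical_columns_p_one(self):
        tab = _table(np.tile([[3.0, 3.0]], (8, 1)), models=("GM", "R"))
        with pytest.warns(UserWarning, match="zero"):
            p = pairwise_wilcoxon(delta_scores(tab))
        assert p.loc["GM", "R"] == 1.0

    def test_uniform_shift_highly_significant(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 10, size=20)
        shift = 5.0 + 0.01 * np.arange(20)  # distinct, all one-signed
        tab = _table(np.column_stack([a, a + shift]), models=("GM", "R"))
        p = pairwise_wilcoxon(delta_scores(tab))
        # all 20 signed ranks on one side: exact two-sided p = 2 * 2^-20
        assert p.loc["GM", "R"] < 0.001
        assert p.loc["GM", "R"] == pytest.approx(2 * 2.0 ** -20, rel=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        tab = _table(rng.uniform(0, 5, size=(12, 3)))
        p = pairwise_wilcoxon(delta_scores(tab))
        assert np.allclose(p.values, p.values.T, equal_nan=True)

    def test_holm_never_decreases_p(self):
        rng = np.random.default_rng(2)
        tab = _table(rng.uniform(0, 5, size=(12, 3)))
        delta = delta_scores(tab)
        raw = pairwise_wilcoxon(delta)
        adj = pairwise_wilcoxon(delta, holm=True)
        mask = ~np.isnan(raw.values)
        assert np.all(adj.values[mask] >= raw.values[mask] - 1e-12)
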