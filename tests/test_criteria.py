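import numpy as np
import pytest

from stratifs.criteria import (
    CRITERIA,
    SelectionState,
    greedy_select,
    score_candidate,
)
from stratifs.info import DiscreteMatrix, entropy, mutual_information

from oracles import brute_force_greedy, criterion_score_oracle


def state_of(dm, names):
    return SelectionState(selected=list(names))


class TestScoreCandidate:
    @pytest.mark.parametrize("criterion", [c for c in CRITERIA if c != "DISR"])
    def test_empty_s_reduces_to_univariate_mi(self, fixed_table, criterion):
        xk = fixed_table.codes[:, 0]
        got = score_candidate(criterion, xk, fixed_table.y, SelectionState(), fixed_table)
        assert got == pytest.approx(mutual_information(xk, fixed_table.y), abs=1e-12)

    def test_disr_empty_s_is_normalised_mi(self, fixed_table):
        xk = fixed_table.codes[:, 0]
        got = score_candidate("DISR", xk, fixed_table.y, SelectionState(), fixed_table)
        expected = mutual_information(xk, fixed_table.y) / entropy(xk, fixed_table.y)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_mrmr_with_exact_duplicate_pays_full_entropy(self, fixed_table):
        # S = {copy of Xk}: I(X;X) = H(X), so J = I(Xk;Y) - H(Xk)
        xk = fixed_table.codes[:, 2]
        dup = DiscreteMatrix(
            fixed_table.feature_names + ["copy"],
            np.column_stack([fixed_table.codes, xk]),
            list(fixed_table.n_categories) + [2],
            fixed_table.y,
        )
        got = score_candidate("mRMR", xk, dup.y, SelectionState(["copy"]), dup)
        expected = mutual_information(xk, dup.y) - entropy(xk)
        assert got == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("criterion", CRITERIA)
    @pytest.mark.parametrize("s_size", [0, 1, 2])
    def test_all_criteria_match_longhand_oracle(self, fixed_table, criterion, s_size):
        """Each formula, term by term, against the independent oracle."""
        selected = [f"f{i}" for i in range(s_size)]
        sel_cols = [list(fixed_table.codes[:, i]) for i in range(s_size)]
        for k in range(s_size, fixed_table.p):
            xk = fixed_table.codes[:, k]
            got = score_candidate(
                criterion, xk, fixed_table.y, state_of(fixed_table, selected), fixed_table, beta=1.0
            )
            want = criterion_score_oracle(criterion, list(xk), list(fixed_table.y), sel_cols)
            assert got == pytest.approx(want, abs=1e-12), (criterion, k)

    def test_already_selected_candidate_rejected(self, fixed_table):
        with pytest.raises(ValueError, match="already selected"):
            score_candidate(
                "CMIM",
                fixed_table.codes[:, 0],
                fixed_table.y,
                SelectionState(["f0"]),
                fixed_table,
                xk_name="f0",
            )

    def test_unknown_criterion_rejected(self, fixed_table):
        with pytest.raises(ValueError, match="unknown criterion"):
            score_candidate("RELIEF", fixed_table.codes[:, 0], fixed_table.y, SelectionState(), fixed_table)

    def test_purity(self, fixed_table):
        args = ("JMI", fixed_table.codes[:, 3], fixed_table.y, SelectionState(["f0", "f2"]), fixed_table)
        assert score_candidate(*args) == score_candidate(*args)


class TestGreedySelect:
    def test_mim_sorts_by_univariate_mi(self, fixed_table):
        result = greedy_select("MIM", fixed_table, K=fixed_table.p)
        mis = {f: mutual_information(fixed_table.column(f), fixed_table.y) for f in fixed_table.feature_names}
        expected = sorted(mis, key=lambda f: (-mis[f], f))
        assert result.ranked_features == expected

    def test_k_equals_p_is_a_permutation(self, fixed_table):
        for criterion in CRITERIA:
            result = greedy_select(criterion, fixed_table, K=fixed_table.p)
            assert sorted(result.ranked_features) == sorted(fixed_table.feature_names)

    def test_k_out_of_range(self, fixed_table):
        with pytest.raises(ValueError):
            greedy_select("MIM", fixed_table, K=fixed_table.p + 1)

    @pytest.mark.parametrize("criterion", CRITERIA)
    def test_greedy_matches_brute_force_oracle(self, fixed_table, criterion):
        """The cached greedy loop equals from-scratch re-scoring every step."""
        columns = {f: list(fixed_table.column(f)) for f in fixed_table.feature_names}
        want = brute_force_greedy(criterion, columns, fixed_table.feature_names, list(fixed_table.y), K=3)
        got = greedy_select(criterion, fixed_table, K=3)
        assert got.ranked_features == want

    @pytest.mark.parametrize("criterion", CRITERIA)
    def test_greedy_scores_match_reference_scorer(self, fixed_table, criterion):
        """Caching must not change results: recorded scores equal score_candidate."""
        result = greedy_select(criterion, fixed_table, K=4)
        state = SelectionState()
        for f, score in zip(result.ranked_features, result.scores):
            ref = score_candidate(criterion, fixed_table.column(f), fixed_table.y, state, fixed_table)
            assert score == pytest.approx(ref, abs=1e-10), (criterion, f)
            state.selected.append(f)

    @pytest.mark.parametrize("criterion", ["mRMR", "MIFS", "CMIM", "ICAP"])
    def test_duplicated_feature_penalised(self, criterion):
        """A copy of an already-selected feature never beats genuine signal."""
        rng = np.random.default_rng(3)
        n = 400
        y = rng.integers(0, 2, n)
        strong = np.where(rng.random(n) < 0.9, y, 1 - y)
        weak = np.where(rng.random(n) < 0.7, y, rng.integers(0, 2, n))
        dup = strong.copy()
        dm = DiscreteMatrix(
            ["a_strong", "b_dup", "c_weak"],
            np.column_stack([strong, dup, weak]).astype(np.int16),
            [2, 2, 2],
            y.astype(np.int16),
        )
        result = greedy_select(criterion, dm, K=2)
        assert result.ranked_features == ["a_strong", "c_weak"]

    def test_independent_features_agree_with_mim_on_top_pick(self):
        """With mutually independent features, every criterion picks MIM's winner."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 2000
            y = rng.integers(0, 2, n)
            cols = [np.where(rng.random(n) < q, y, rng.integers(0, 2, n)) for q in (0.7, 0.4, 0.3, 0.2)]
            dm = DiscreteMatrix(
                [f"g{i}" for i in range(4)],
                np.column_stack(cols).astype(np.int16),
                [2] * 4,
                y.astype(np.int16),
            )
            top = {c: greedy_select(c, dm, K=1).ranked_features[0] for c in CRITERIA}
            mim_top = top["MIM"]
            hits += all(v == mim_top for v in top.values())
        assert hits >= 9
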