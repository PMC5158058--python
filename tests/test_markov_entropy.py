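"""Markovian Entropy: discretization, transition tallies, entropy value."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

import calentropy as ce
from calentropy.markov_entropy import (
    EntropyParams,
    SymbolSequence,
    build_transition_model,
    discretize,
    markovian_entropy,
)


def naive_entropy(values, n, k):
    """Independent oracle: longhand quantiles + dict-based transition tally."""
    v = list(float(x) for x in values)
    srt = sorted(v)
    bounds = []
    for j in range(1, n):
        q = j / n * (len(v) - 1)
        lo, hi = math.floor(q), math.ceil(q)
        bounds.append(srt[lo] + (q - lo) * (srt[hi] - srt[lo]))
    sym = [sum(1 for b in bounds if b < x) for x in v]
    trans: dict = {}
    for t in range(k, len(sym)):
        trans.setdefault(tuple(sym[t - k : t]), []).append(sym[t])
    total = 0.0
    for nxts in trans.values():
        tot = len(nxts)
        for s in range(n):
            c = nxts.count(s)
            if c:
                total -= c / tot * math.log2(c / tot)
    return total / (n**k * math.log2(n))


class TestDiscretize:
    def test_median_split(self):
        seq = discretize(np.array([1.0, 2.0, 3.0, 4.0]), 2)
        assert seq.symbols.tolist() == [0, 0, 1, 1]
        assert not seq.degenerate

    def test_constant_trace_is_degenerate(self):
        seq = discretize(np.array([5.0] * 4), 2)
        assert seq.symbols.tolist() == [0, 0, 0, 0]
        assert seq.degenerate

    def test_boundary_tie_goes_to_lower_state(self):
        # median of [0,1,1,2] is 1; the tied values must land in state 0
        seq = discretize(np.array([0.0, 1.0, 1.0, 2.0]), 2)
        assert seq.symbols.tolist() == [0, 0, 0, 1]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=60, unique=True),
        st.integers(2, 5),
    )
    def test_rank_invariance_under_monotone_map(self, vals, n):
        v = np.asarray(vals)
        mapped = np.exp(v / 2e3)  # strictly increasing map
        # invariance holds whenever the map keeps values distinct in floats
        assume(len(set(mapped.tolist())) == len(vals))
        assert np.array_equal(discretize(v, n).symbols, discretize(mapped, n).symbols)

    def test_rejects_small_n(self):
        with pytest.raises(ValueError):
            discretize(np.array([1.0, 2.0]), 1)


class TestTransitionModel:
    def test_alternating_tally_k1(self):
        model = build_transition_model(SymbolSequence(np.array([0, 1, 0, 1, 0]), n=2), 1)
        assert model.counts.tolist() == [[0, 2], [2, 0]]
        assert model.probabilities.tolist() == [[0.0, 1.0], [1.0, 0.0]]

    def test_hand_tally_k2(self):
        # six 2-gram transitions of [0,0,1,1,0,0,1,1]; every observed row deterministic
        seq = SymbolSequence(np.array([0, 0, 1, 1, 0, 0, 1, 1]), n=2)
        model = build_transition_model(seq, 2)
        # rows lexicographic (oldest symbol most significant): 00,01,10,11
        assert model.counts.tolist() == [[0, 2], [0, 2], [1, 0], [1, 0]]
        assert model.counts.sum() == len(seq) - 2

    def test_minimal_sequence_has_one_count(self):
        model = build_transition_model(SymbolSequence(np.array([0, 1, 1]), n=2), 2)
        assert model.counts.sum() == 1

    def test_observed_rows_sum_to_one(self, rng):
        seq = SymbolSequence(rng.integers(0, 3, 200), n=3)
        model = build_transition_model(seq, 2)
        sums = model.probabilities.sum(axis=1)
        assert np.allclose(sums[model.row_observed], 1.0, atol=1e-12)
        assert np.all(sums[~model.row_observed] == 0)

    def test_sequence_too_short(self):
        with pytest.raises(ValueError):
            build_transition_model(SymbolSequence(np.array([0, 1]), n=2), 2)


class TestMarkovianEntropy:
    def test_alternating_trace_is_fully_predictable(self):
        trace = np.array([1.0, 9.0] * 450)
        assert markovian_entropy(trace, n=2, k=1).value == 0.0

    def test_period_four_trace_k1_vs_k2(self):
        trace = np.array([1.0, 1.0, 9.0, 9.0, 1.0, 1.0, 9.0, 9.0, 1.0])
        assert markovian_entropy(trace, n=2, k=1).value == 1.0
        with pytest.warns(UserWarning, match="sparse"):
            assert markovian_entropy(trace, n=2, k=2).value == 0.0

    def test_degenerate_trace_scores_zero_with_flag(self):
        res = markovian_entropy(np.full(100, 2.5), n=2, k=1)
        assert res.value == 0.0
        assert res.degenerate

    def test_value_is_row_sum_over_max(self, rng):
        res = markovian_entropy(rng.random(300), n=3, k=2)
        assert res.value == pytest.approx(
            res.row_entropies.sum() / (9 * np.log2(3)), abs=0
        )

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_brute_force_oracle_all_binary_traces(self, k):
        """Exhaustive check against the naive tally for every short binary trace."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # short traces are sparse by design
            for length in range(k + 1, 10):
                for code in range(2**length):
                    vals = [1.0 + ((code >> i) & 1) for i in range(length)]
                    got = markovian_entropy(np.array(vals), n=2, k=k).value
                    assert got == pytest.approx(naive_entropy(vals, 2, k), abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 4), st.integers(1, 3))
    def test_value_always_in_unit_interval(self, seed, n, k):
        import warnings

        v = np.random.default_rng(seed).random(80)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert 0.0 <= markovian_entropy(v, n=n, k=k).value <= 1.0

    def test_monotone_transform_invariance_is_exact(self, rng):
        for _ in range(100):
            v = rng.standard_normal(120)
            base = markovian_entropy(v, n=2, k=1).value
            assert markovian_entropy(np.exp(v), n=2, k=1).value == base

    def test_iid_traces_approach_maximum_entropy(self):
        vals = [
            markovian_entropy(np.random.default_rng(s).random(900), n=2, k=1).value
            for s in range(50)
        ]
        assert np.mean(vals) >= 0.995

    def test_order_consistency_on_first_order_chain(self):
        """For first-order data with all 2-grams observed, k=2 matches k=1."""
        diffs = []
        for s in range(100):
            trace, _ = ce.gen_chain_trace(ce.symmetric_two_state(0.8, seed=s))
            e1 = markovian_entropy(trace, n=2, k=1).value
            e2 = markovian_entropy(trace, n=2, k=2).value
            diffs.append(e2 - e1)
        assert abs(np.mean(diffs)) < 0.03

    def test_sparse_regime_warns(self):
        with pytest.warns(UserWarning, match="sparse"):
            markovian_entropy(np.random.default_rng(0).random(50), n=4, k=3)

    def test_trace_shorter_than_order_rejected(self):
        with pytest.raises(ValueError):
            markovian_entropy(np.array([1.0, 2.0]), n=2, k=2)
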