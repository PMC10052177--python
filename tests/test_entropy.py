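import math

import pytest
from hypothesis import given, settings, strategies as st

from rnaorder.entropy import (
    EntropyBreakdown,
    InfiniteOrderError,
    entropy_general,
    entropy_two_level,
    entropy_uniform,
    limiting_case_entropy,
    living_dead_gap,
    order_parameter,
)
from rnaorder.system_model import AVOGADRO, BOLTZMANN, Alphabet, ParameterError, SystemState

from oracles import dec_entropy_general, dec_entropy_uniform

# Frozen values computed with the 50-digit decimal oracle (tests/oracles.py).
GENERAL_EXAMPLE_SRK = 172.14748528467286        # n=4,N=120,L=6,M=2,r=(.4,.3,.2,.1),a unif,pk=(.7,.1,.1,.1)
GENERAL_EXAMPLE_TERMS = (61.433002840016038, 43.002227261473320, 67.712255183183499)
TWO_LEVEL_EXAMPLE_SRK = 1189.5073845176175      # n=4,N=1000,L=20,M=10,p=0.5
CASE1_ONE_MOL_JK = 11.526292643287959           # = R ln 4 for one mole of units
CASE4_L20_ONE_MOL_JK = 2.4907904002459874       # = R (2/20) ln 20


def uniform_state(n, N, L, M, p, **kw):
    return SystemState(Alphabet(n), N=N, L=L, M=M, p=p, **kw)


class TestEntropyGeneral:
    def test_matches_high_precision_oracle(self):
        state = SystemState(Alphabet(4, (0.4, 0.3, 0.2, 0.1)), N=120, L=6, M=2,
                            p=0.5, pk=(0.7, 0.1, 0.1, 0.1), a=(1 / 6,) * 6)
        b = entropy_general(state)
        oracle = float(dec_entropy_general(120, 6, 2, (0.4, 0.3, 0.2, 0.1),
                                           (1 / 6,) * 6, (0.7, 0.1, 0.1, 0.1)))
        assert oracle == pytest.approx(GENERAL_EXAMPLE_SRK, rel=1e-12)
        assert b.S_r_k == pytest.approx(GENERAL_EXAMPLE_SRK, rel=1e-12)
        for term, frozen in zip(
                (b.term_mixing, b.term_contact, b.term_sequence), GENERAL_EXAMPLE_TERMS):
            assert term == pytest.approx(frozen, rel=1e-12)

    def test_fully_defined_chains_have_zero_sequence_term(self):
        # pk = [1,0,0,0], M=0, uniform a: S_r/k = (2N/L) ln L
        state = uniform_state(4, 100, 10, 0, 0.0, pk=(1.0, 0.0, 0.0, 0.0),
                              a=(0.1,) * 10)
        b = entropy_general(state)
        assert b.term_sequence == 0.0
        assert b.S_r_k == pytest.approx((2 * 100 / 10) * math.log(10), rel=1e-12)

    def test_fully_random_reduces_to_uniform(self):
        state = uniform_state(4, 100, 10, 5, 1.0, pk=(0.25,) * 4, a=(0.1,) * 10)
        b = entropy_general(state)
        u = entropy_uniform(4, 100, 10, 5, 1.0)
        assert b.S_r_k == pytest.approx(u.S_r_k, rel=1e-12)

    def test_missing_profile_errors(self):
        with pytest.raises(ParameterError, match="entropy_two_level"):
            entropy_general(uniform_state(4, 100, 10, 5, 1.0))


class TestEntropyTwoLevel:
    def test_p_zero_kills_sequence_term(self):
        b = entropy_two_level(uniform_state(4, 100, 10, 5, 0.0))
        assert b.term_sequence == 0.0

    def test_p_one_equals_uniform(self):
        b = entropy_two_level(uniform_state(4, 100, 10, 5, 1.0))
        u = entropy_uniform(4, 100, 10, 5, 1.0)
        assert b.S_r_k == pytest.approx(u.S_r_k, rel=1e-12)

    def test_frozen_example(self):
        b = entropy_two_level(uniform_state(4, 1000, 20, 10, 0.5))
        assert b.S_r_k == pytest.approx(TWO_LEVEL_EXAMPLE_SRK, rel=1e-12)
        # guard the frozen constant against the independent oracle
        assert float(dec_entropy_uniform(4, 1000, 20, 10, 0.5)) == pytest.approx(
            TWO_LEVEL_EXAMPLE_SRK, rel=1e-12)


class TestEntropyUniform:
    def test_case1_one_mol(self, one_mol):
        b = entropy_uniform(4, one_mol, 1, 0, 1)
        assert b.S_r_JK == pytest.approx(CASE1_ONE_MOL_JK, rel=1e-12)
        assert float(f"{b.S_r_JK:.5g}") == 11.526

    def test_case1_independent_of_M_when_L1_p1(self, one_mol):
        assert entropy_uniform(4, one_mol, 1, 10, 1).S_r_JK == pytest.approx(
            entropy_uniform(4, one_mol, 1, 0, 1).S_r_JK, rel=1e-12)

    def test_single_letter_monomer_is_zero(self):
        assert entropy_uniform(1, 100, 1, 0, 1).S_r_k == 0.0

    def test_defined_chains_one_mol(self, one_mol):
        b = entropy_uniform(4, one_mol, 20, 0, 0)
        assert b.S_r_JK == pytest.approx(CASE4_L20_ONE_MOL_JK, rel=1e-12)

    def test_breakdown_sums(self):
        b = entropy_uniform(4, 1000, 20, 10, 0.5)
        assert b.S_r_k == pytest.approx(
            b.term_mixing + b.term_contact + b.term_sequence, rel=1e-9)
        assert b.order_KJ * b.S_r_JK == pytest.approx(1.0, rel=1e-12)


class TestLimitingCases:
    def test_pure_monomer_one_mol(self, one_mol):
        s = limiting_case_entropy("pure_monomer", 4, one_mol)
        assert s * BOLTZMANN == pytest.approx(CASE1_ONE_MOL_JK, rel=1e-12)

    def test_crystals(self):
        assert limiting_case_entropy("crystals", 7, 100, 100) == pytest.approx(
            2 * math.log(100), rel=1e-12)

    def test_random_chains_is_sum_of_cases(self):
        # oracle: sum of the crystal and pure-monomer forms
        expected = (limiting_case_entropy("crystals", 4, 100, 10)
                    + limiting_case_entropy("pure_monomer", 4, 100))
        got = limiting_case_entropy("random_chains", 4, 100, 10)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(184.68113797186998, rel=1e-12)

    def test_unknown_case(self):
        with pytest.raises(ParameterError, match="case"):
            limiting_case_entropy("glass", 4, 100, 10)

    @given(n=st.integers(2, 6), N=st.floats(1, 1e6), L=st.floats(1, 100),
           M=st.floats(0, 100))
    def test_eq3_reproduces_all_limits(self, n, N, L, M):
        # L=1, p=1 -> N ln n for any M
        assert entropy_uniform(n, N, 1, M, 1).S_r_k == pytest.approx(
            N * math.log(n), rel=1e-12)
        # M=0, p=0 -> (2N/L) ln L
        assert entropy_uniform(n, N, L, 0, 0).S_r_k == pytest.approx(
            limiting_case_entropy("defined_chains", n, N, L), rel=1e-12, abs=1e-12)
        # M=0, p=1 -> (2N/L) ln L + N ln n
        assert entropy_uniform(n, N, L, 0, 1).S_r_k == pytest.approx(
            limiting_case_entropy("random_chains", n, N, L), rel=1e-12)


class TestOrderParameter:
    def test_reciprocal_of_case1(self):
        assert order_parameter(CASE1_ONE_MOL_JK) == pytest.approx(
            0.0867581650880888, rel=1e-12)

    def test_identity(self):
        assert order_parameter(1.0) == 1.0

    def test_zero_entropy_guard(self):
        with pytest.raises(InfiniteOrderError):
            order_parameter(0.0)


class TestLivingDeadGap:
    def test_one_mol_equals_case1(self, one_mol):
        assert living_dead_gap(4, one_mol) * BOLTZMANN == pytest.approx(
            CASE1_ONE_MOL_JK, rel=1e-12)

    def test_single_letter_is_zero(self):
        assert living_dead_gap(1, 1e6) == 0.0

    def test_equals_random_minus_defined(self):
        gap = living_dead_gap(4, 100)
        diff = (entropy_uniform(4, 100, 10, 0, 1).S_r_k
                - entropy_uniform(4, 100, 10, 0, 0).S_r_k)
        assert gap == pytest.approx(diff, rel=1e-12)


@settings(max_examples=200)
@given(n=st.integers(2, 6), N=st.floats(1, 1e6), L=st.floats(1, 100),
       M=st.floats(0, 100), p=st.floats(0, 1))
def test_reduction_chain(n, N, L, M, p):
    """general (uniform profiles, two-level pk mix) == two_level == uniform."""
    state = SystemState(Alphabet(n), N=N, L=L, M=M, p=p)
    two = entropy_two_level(state)
    uni = entropy_uniform(n, N, L, M, p)
    assert two.S_r_k == pytest.approx(uni.S_r_k, rel=1e-12, abs=1e-300)
    # fully random profile equals uniform at p=1
    full = entropy_general(state.with_(p=1.0, pk=(1.0 / n,) * n))
    assert full.S_r_k == pytest.approx(
        entropy_uniform(n, N, L, M, 1.0).S_r_k, rel=1e-12)


@given(n=st.integers(2, 6), N=st.floats(1, 1e6), L=st.floats(1.5, 100),
       M=st.floats(0, 100), p=st.floats(0, 0.98))
def test_strictly_increasing_in_p(n, N, L, M, p):
    lo = entropy_uniform(n, N, L, M, p).S_r_k
    hi = entropy_uniform(n, N, L, M, min(1.0, p + 0.02)).S_r_k
    assert hi > lo


@given(n=st.integers(2, 6), N=st.floats(1, 1e6), L=st.floats(1, 100),
       M=st.floats(0, 100), p=st.floats(0, 1))
def test_terms_nonnegative_and_positive_total(n, N, L, M, p):
    b = entropy_uniform(n, N, L, M, p)
    assert b.term_mixing >= 0 and b.term_contact >= 0 and b.term_sequence >= 0
    if n >= 2 and (L > 1 or p > 0 or M > 0):
        assert b.S_r_k > 0
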