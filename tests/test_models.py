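"""CME engine: generator structure, propagation, steady states, moments."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import telegraphkit as tk
from telegraphkit import (GeneModelSpec, ProbabilityVector, StateSpace,
                          TruncationWarning, Variant)


def hand_enumerated_generator():
    """ONE_STEP, M=2, k_on=1, k_off=2, k_t=3, k_d=4: every reaction by hand.

    States indexed (s, m) -> 3 s + m with s the number of active alleles.
    Off-diagonal entries listed reaction by reaction; diagonals close the
    columns to zero.
    """
    entries = {
        (3, 0): 2.0,                      # (0,0) activation x2 alleles
        (4, 1): 2.0, (0, 1): 4.0,         # (0,1) activation, degradation
        (5, 2): 2.0, (1, 2): 8.0,         # (0,2)
        (6, 3): 1.0, (0, 3): 2.0, (4, 3): 3.0,             # (1,0)
        (7, 4): 1.0, (1, 4): 2.0, (5, 4): 3.0, (3, 4): 4.0,  # (1,1)
        (8, 5): 1.0, (2, 5): 2.0, (4, 5): 8.0,             # (1,2): no tx at M
        (3, 6): 4.0, (7, 6): 6.0,                          # (2,0)
        (4, 7): 4.0, (8, 7): 6.0, (6, 7): 4.0,             # (2,1)
        (5, 8): 4.0, (7, 8): 8.0,                          # (2,2)
    }
    R = np.zeros((9, 9))
    for (i, j), v in entries.items():
        R[i, j] = v
    np.fill_diagonal(R, -R.sum(axis=0))
    return R


class TestStateSpace:
    def test_sizes_match_variant_family(self):
        assert StateSpace("one_step", 2000).size == 3 * 2001 == 6003
        assert StateSpace("two_step_silent", 2000).size == 6 * 2001
        assert StateSpace("one_step_leak", 10).size == 33

    def test_index_bijection(self):
        space = StateSpace("two_step_permissive", 5)
        seen = set()
        for cfg in space.configs:
            for m in range(6):
                seen.add(space.index_of(cfg, m))
        assert seen == set(range(space.size))
        # unordered: both orderings address the same state
        assert space.index_of((2, 0), 3) == space.index_of((0, 2), 3)

    def test_bad_lookups_rejected(self):
        space = StateSpace("one_step", 5)
        with pytest.raises(KeyError):
            space.index_of((0, 2), 0)  # state 2 not in a one-step allele
        with pytest.raises(IndexError):
            space.index_of((0, 0), 6)


class TestSpecValidation:
    def test_irrelevant_rates_must_be_zero(self):
        with pytest.raises(ValueError):
            GeneModelSpec("one_step", 1, 1, 1, 1, t_on=0.1)
        with pytest.raises(ValueError):
            GeneModelSpec("two_step_silent", 1, 1, 1, 1, k_0=0.5)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            GeneModelSpec("one_step", -0.1, 1, 1, 1)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            GeneModelSpec("three_step", 1, 1, 1, 1)

    def test_json_round_trip(self):
        spec = GeneModelSpec("two_step_permissive", 0.09, 0.12, 11.7, 0.004,
                             t_on=0.008, t_off=0.05, k_0=3.0, M=500)
        assert GeneModelSpec.from_dict(spec.as_dict()) == spec
        assert set(spec.as_dict()) == {"variant", "k_on", "k_off", "t_on",
                                       "t_off", "k_0", "k_t", "k_d", "M"}


class TestRateMatrix:
    def test_hand_enumerated_nine_state_generator(self):
        spec = GeneModelSpec("one_step", k_on=1, k_off=2, k_t=3, k_d=4, M=2)
        R = tk.build_rate_matrix(spec).toarray()
        np.testing.assert_allclose(R, hand_enumerated_generator(), atol=0)

    def test_all_zero_rates_give_zero_matrix(self):
        spec = GeneModelSpec("one_step", 0, 0, 0, 0, M=3)
        assert tk.build_rate_matrix(spec).nnz == 0

    def test_leak_transcribes_in_every_gene_state(self):
        spec = GeneModelSpec("one_step_leak", k_on=0, k_off=0, k_t=0,
                             k_d=0, k_0=1.5, M=2)
        R = tk.build_rate_matrix(spec).toarray()
        space = StateSpace(spec.variant, 2)
        # both-off cells still transcribe at 2 k_0
        assert R[space.index_of((0, 0), 1), space.index_of((0, 0), 0)] == 3.0

    def test_permissive_vs_silent_intermediate(self):
        common = dict(k_on=0.1, k_off=0.2, k_t=5.0, k_d=0.01,
                      t_on=0.05, t_off=0.05, M=2)
        silent = GeneModelSpec("two_step_silent", **common)
        perm = GeneModelSpec("two_step_permissive", k_0=2.0, **common)
        space = StateSpace("two_step_silent", 2)
        i_from = space.index_of((1, 1), 0)  # both alleles intermediate
        i_to = space.index_of((1, 1), 1)
        assert tk.build_rate_matrix(silent).toarray()[i_to, i_from] == 0.0
        space_p = StateSpace("two_step_permissive", 2)
        assert tk.build_rate_matrix(perm).toarray()[
            space_p.index_of((1, 1), 1), space_p.index_of((1, 1), 0)] == 4.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.sampled_from(list(Variant)),
           st.lists(st.floats(0.0, 5.0), min_size=7, max_size=7))
    def test_columns_sum_to_zero(self, variant, rates):
        kw = dict(zip(("k_on", "k_off", "k_t", "k_d", "t_on", "t_off", "k_0"),
                      rates))
        if not Variant(variant).is_two_step:
            kw["t_on"] = kw["t_off"] = 0.0
        if variant in (Variant.ONE_STEP, Variant.TWO_STEP_SILENT):
            kw["k_0"] = 0.0
        spec = GeneModelSpec(variant, M=6, **kw)
        R = tk.build_rate_matrix(spec)
        colsums = np.asarray(R.sum(axis=0)).ravel()
        assert np.abs(colsums).max() < 1e-12


class TestPropagate:
    def test_t_zero_is_identity(self, small_spec):
        p0 = tk.default_initial_state(StateSpace(small_spec.variant,
                                                 small_spec.M))
        p = tk.propagate(small_spec, p0, 0.0)
        np.testing.assert_array_equal(p.values, p0.values)

    def test_pure_decay_is_binomial_thinning(self):
        spec = GeneModelSpec("one_step", 0, 0, 0, k_d=0.05, M=10)
        space = StateSpace(spec.variant, spec.M)
        vals = np.zeros(space.size)
        vals[space.index_of((0, 0), 5)] = 1.0
        p0 = ProbabilityVector(vals, 0.0, space)
        t = 30.0
        marg = tk.marginal_mrna(tk.propagate(spec, p0, t))
        expected = stats.binom.pmf(np.arange(11), 5, np.exp(-0.05 * t))
        np.testing.assert_allclose(marg, expected, atol=1e-9)

    def test_probability_conserved_across_times(self, small_spec):
        p0 = tk.default_initial_state(StateSpace(small_spec.variant,
                                                 small_spec.M))
        for t in (1.0, 180.0, 360.0):
            p = tk.propagate(small_spec, p0, t)
            assert abs(p.values.sum() - 1.0) < 1e-8

    def test_truncation_warning_when_m_too_small(self):
        spec = GeneModelSpec("one_step", k_on=1.0, k_off=0.01, k_t=5.0,
                             k_d=0.01, M=20)
        p0 = tk.default_initial_state(StateSpace(spec.variant, spec.M))
        with pytest.warns(TruncationWarning):
            tk.propagate(spec, p0, 200.0)

    def test_negative_time_rejected(self, small_spec):
        p0 = tk.default_initial_state(StateSpace(small_spec.variant,
                                                 small_spec.M))
        with pytest.raises(ValueError):
            tk.propagate(small_spec, p0, -1.0)


class TestInitialState:
    @pytest.mark.parametrize("variant", ["one_step", "two_step_permissive"])
    def test_mass_on_fully_inactive_origin(self, variant):
        if variant == "two_step_permissive":
            spec = GeneModelSpec(variant, 0.1, 0.1, 1, 0.1, t_on=0.1,
                                 t_off=0.1, k_0=0.5, M=4)
        else:
            spec = GeneModelSpec(variant, 0.1, 0.1, 1, 0.1, M=4)
        space = StateSpace(spec.variant, spec.M)
        p0 = tk.default_initial_state(space)
        assert p0.values.sum() == 1.0
        assert p0.values[space.index_of((0, 0), 0)] == 1.0
        # no mass on intermediate configurations
        assert np.count_nonzero(p0.values) == 1


class TestSteadyState:
    def test_always_on_gene_is_poisson(self):
        spec = GeneModelSpec("one_step", k_on=0.5, k_off=0.0, k_t=5.0,
                             k_d=0.05, M=380)
        marg = tk.marginal_mrna(tk.steady_state(spec))
        lam = 2 * 5.0 / 0.05
        np.testing.assert_allclose(
            marg, stats.poisson.pmf(np.arange(381), lam), atol=1e-8)
        assert abs(tk.moments(marg).fano - 1.0) < 1e-6

    def test_matches_closed_form_at_tnf_rates(self, tnf_spec):
        ms = tk.moments(tk.steady_state(tnf_spec))
        mu, var = tk.steady_state_moments(tnf_spec)
        assert abs(ms.mean - mu) / mu < 1e-3
        assert abs(ms.variance - var) / var < 1e-3

    def test_no_transcription_collapses_to_zero(self):
        spec = GeneModelSpec("one_step", 0.1, 0.1, 0.0, 0.05, M=10)
        marg = tk.marginal_mrna(tk.steady_state(spec))
        assert marg[0] == pytest.approx(1.0)

    def test_propagation_cross_check(self, small_spec):
        a = tk.steady_state(small_spec, method="nullspace")
        b = tk.steady_state(small_spec, method="propagate")
        assert np.abs(a.values - b.values).max() < 1e-7
        assert a.time == tk.STEADY

    def test_kd_zero_rejected(self):
        spec = GeneModelSpec("one_step", 0.1, 0.1, 1.0, 0.0, M=10)
        with pytest.raises(ValueError):
            tk.steady_state(spec)


class TestMomentsAndMarginal:
    def test_point_mass_moments(self):
        space = StateSpace("one_step", 10)
        vals = np.zeros(space.size)
        vals[space.index_of((0, 1), 7)] = 1.0
        ms = tk.moments(ProbabilityVector(vals, 0.0, space))
        assert (ms.mean, ms.variance) == (7.0, 0.0)

    def test_zero_mean_flags_undefined_noise(self):
        space = StateSpace("one_step", 5)
        p0 = tk.default_initial_state(space)
        ms = tk.moments(p0)
        assert ms.cv is None and ms.fano is None

    def test_marginal_sums_gene_states(self):
        space = StateSpace("one_step", 3)
        vals = np.zeros(space.size)
        for cfg in space.configs:  # uniform over gene states at m=2
            vals[space.index_of(cfg, 2)] = 1.0 / 3
        marg = tk.marginal_mrna(ProbabilityVector(vals, 0.0, space))
        assert marg[2] == pytest.approx(1.0)

    def test_marginal_preserves_moments(self, small_spec):
        p = tk.steady_state(small_spec)
        assert tk.moments(p) == tk.moments(tk.marginal_mrna(p))


class TestFastMarginal:
    """The allele-convolution shortcut must agree with the full CME."""

    def test_matches_full_propagation_one_step(self, small_spec):
        p0 = tk.default_initial_state(StateSpace(small_spec.variant,
                                                 small_spec.M))
        full = tk.marginal_mrna(tk.propagate(small_spec, p0, 90.0))
        fast = tk.transient_marginal(small_spec, 90.0)
        L = min(full.size, fast.size)
        assert np.abs(full[:L] - fast[:L]).max() < 1e-10

    def test_matches_full_propagation_two_step(self, two_step_spec):
        p0 = tk.default_initial_state(StateSpace(two_step_spec.variant,
                                                 two_step_spec.M))
        full = tk.marginal_mrna(tk.propagate(two_step_spec, p0, 120.0))
        fast = tk.transient_marginal(two_step_spec, 120.0)
        L = min(full.size, fast.size)
        # residual difference is the full solver's own truncation tail
        assert np.abs(full[:L] - fast[:L]).max() < 1e-8


class TestSensitivity:
    def test_unused_parameter_rejected(self, small_spec):
        with pytest.raises(ValueError):
            tk.sensitivity_index(small_spec, "k_0")

    def test_deterministic_and_matches_recomputation(self, small_spec):
        idx1 = tk.sensitivity_index(small_spec, "k_t", t=60.0)
        idx2 = tk.sensitivity_index(small_spec, "k_t", t=60.0)
        assert idx1 == idx2
        space = StateSpace(small_spec.variant, small_spec.M)
        p0 = tk.default_initial_state(space)
        cv0 = tk.moments(tk.propagate(small_spec, p0, 60.0)).cv
        cv1 = tk.moments(tk.propagate(
            small_spec.replace(k_t=small_spec.k_t * 1.1), p0, 60.0)).cv
        assert idx1 == pytest.approx(1.0 - cv1 / cv0, abs=1e-12)
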