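"""Tests of the exact stem-lineage mutation recurrence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemrisk.wu import (
    RateSchedule,
    WuConfig,
    cancer_probability,
    initial_distribution,
    mutagen_cancer_probability,
    per_gene_closed_form,
    pr_mutagen,
    relative_risk,
    step_distribution,
    terminal_distribution,
)
from stemrisk._numeric import complement_power


class TestStepDistribution:
    def test_zero_rates_leave_distribution_unchanged(self):
        dist = initial_distribution(3)
        out = step_distribution(dist, 0.0, 0.0, 3)
        np.testing.assert_array_equal(out, dist)

    def test_single_gene_bernoulli(self):
        out = step_distribution(initial_distribution(1), 0.5, 0.0, 1)
        assert out[1, 0] == pytest.approx(0.5)
        assert out[0, 0] == pytest.approx(0.5)

    def test_two_gene_trinomial_expansion(self):
        # (0.1 + 0.2 + 0.7)^2 expanded term by term
        out = step_distribution(initial_distribution(2), 0.1, 0.2, 2)
        expected = {
            (0, 0): 0.49,
            (1, 0): 0.14,
            (0, 1): 0.28,
            (2, 0): 0.01,
            (1, 1): 0.04,
            (0, 2): 0.04,
        }
        for (s, m), value in expected.items():
            assert out[s, m] == pytest.approx(value, abs=1e-15)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            step_distribution(initial_distribution(1), 0.7, 0.5, 1)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    k=st.integers(1, 5),
    n=st.integers(1, 30),
    u_s=st.floats(0.0, 0.4),
    u_m=st.floats(0.0, 0.4),
    seed=st.integers(0, 2**16),
)
def test_recurrence_matches_per_gene_closed_form(k, n, u_s, u_m, seed):
    """Genes are i.i.d., so the recurrence must equal the multinomial law
    built from the per-gene three-state absorbing chain."""
    rng = np.random.default_rng(seed)
    scale = rng.uniform(0.0, 1.0, size=n)
    schedule = RateSchedule(u_s * scale, u_m * scale)
    config = WuConfig(1, n - 1, k)
    recurrence = terminal_distribution(config, schedule)
    closed = per_gene_closed_form(config, schedule)
    np.testing.assert_allclose(recurrence, closed, atol=1e-12)
    assert recurrence.sum() == pytest.approx(1.0, abs=1e-12)


class TestCancerProbability:
    def test_zero_rates_give_zero(self):
        config = WuConfig(5, 5, 2)
        schedule = RateSchedule.constant(10, 0.0, 0.0)
        assert cancer_probability(config, schedule) == 0.0

    def test_two_lineage_hand_calculation(self):
        # k=1, two divisions at u=0.5: per-gene survival 0.25, two lineages
        config = WuConfig(1, 1, 1)
        schedule = RateSchedule(np.array([0.5, 0.5]), np.zeros(2))
        assert cancer_probability(config, schedule) == pytest.approx(1 - 0.25**2)

    def test_schedule_length_checked(self):
        config = WuConfig(2, 3, 1)
        with pytest.raises(ValueError):
            cancer_probability(config, RateSchedule.constant(4, 1e-3))

    def test_monotone_in_rates_and_divisions(self):
        base = cancer_probability(WuConfig(4, 8, 2), RateSchedule.constant(12, 1e-3))
        more_rate = cancer_probability(WuConfig(4, 8, 2), RateSchedule.constant(12, 2e-3))
        more_lineages = cancer_probability(WuConfig(5, 8, 2), RateSchedule.constant(13, 1e-3))
        higher_k = cancer_probability(WuConfig(4, 8, 3), RateSchedule.constant(12, 1e-3))
        assert more_rate > base
        assert more_lineages > base
        assert higher_k < base

    def test_matches_direct_lineage_simulation(self):
        """2^n1 independent k-gene lineages simulated head-on."""
        config = WuConfig(4, 16, 2)
        schedule = RateSchedule.constant(20, 0.01, 0.02, onset_fraction=0.5)
        exact = cancer_probability(config, schedule)

        rng = np.random.default_rng(2024)
        n_rep, n_lineages = 4000, 16
        # per-gene terminal state across all lineages and replicates
        state = np.zeros((n_rep, n_lineages, config.k), dtype=np.int8)  # 0=none,1=S,2=M
        for u_s, u_m in zip(schedule.u_s, schedule.u_m):
            u = rng.random(state.shape)
            fresh = state == 0
            state[fresh & (u < u_s)] = 1
            state[fresh & (u >= u_s) & (u < u_s + u_m)] = 2
        mutated = (state > 0).all(axis=2)
        p_hat = mutated.any(axis=1).mean()
        se = math.sqrt(p_hat * (1 - p_hat) / n_rep)
        assert abs(p_hat - exact) < 3 * se


class TestMutagenQuantities:
    def test_no_mutagen_means_no_attributable_cancer(self):
        config = WuConfig(5, 10, 2)
        schedule = RateSchedule.constant(15, 1e-3, 0.0)
        assert mutagen_cancer_probability(config, schedule) == 0.0
        assert pr_mutagen(config, schedule) == 0.0
        assert relative_risk(config, schedule) == pytest.approx(1.0)

    def test_pure_mutagen_attributes_everything(self):
        config = WuConfig(5, 10, 2)
        schedule = RateSchedule(np.zeros(15), np.full(15, 1e-3))
        assert mutagen_cancer_probability(config, schedule) == pytest.approx(
            cancer_probability(config, schedule)
        )
        assert pr_mutagen(config, schedule) == pytest.approx(1.0)

    def test_single_gene_first_event_classification(self):
        """k=1, three divisions, mutagen active only on the last: brute-force
        the per-gene Markov chain."""
        config = WuConfig(1, 2, 1)
        u_s, u_m = 0.1, 0.2
        schedule = RateSchedule(np.full(3, u_s), np.array([0.0, 0.0, u_m]))
        # chain: P(gene mutagen-mutated) = survive two spont. divisions * u_m
        p_m = (1 - u_s) ** 2 * u_m
        expected = complement_power(p_m, 2)
        assert mutagen_cancer_probability(config, schedule) == pytest.approx(expected, rel=1e-12)

    def test_conditional_undefined_when_no_cancer_possible(self):
        config = WuConfig(3, 3, 2)
        schedule = RateSchedule.constant(6, 0.0, 0.0)
        assert math.isnan(pr_mutagen(config, schedule))

    def test_attributable_never_exceeds_total(self):
        for u_m in (1e-9, 5e-9, 1e-8):
            config = WuConfig(20, 1390, 3)
            schedule = RateSchedule.constant(1410, 1e-8, u_m)
            assert mutagen_cancer_probability(config, schedule) <= cancer_probability(
                config, schedule
            )


@pytest.mark.parametrize("n1,n2", [(27, 960), (28, 5840), (20, 1390)])
@pytest.mark.parametrize("k", [2, 3, 4])
def test_small_rate_limits(n1, n2, k):
    """At u -> 0 with onset ~ N/3 and u_M = c u_S, the per-gene first-event
    argument gives RR -> (1 + 2c/3)^k and Pr_M -> 1 - (3 / (3 + 2c))^k.
    Checked on the long-N sites, where the exposed fraction of divisions is
    within O(1/N) of exactly two thirds."""
    n = n1 + n2
    assert n % 3 == 0
    c = 0.5
    u_s = 1e-10  # far from saturation at every site
    config = WuConfig(n1, n2, k)
    schedule = RateSchedule.constant(n, u_s, c * u_s)
    rr = relative_risk(config, schedule)
    prm = pr_mutagen(config, schedule)
    assert rr == pytest.approx((1 + 2 * c / 3) ** k, rel=0.01)
    assert prm == pytest.approx(1 - (3 / (3 + 2 * c)) ** k, rel=0.01)


def test_complement_power_precision():
    # tiny probabilities must not underflow to 0 through (1-p)**n
    assert complement_power(1e-300, 2.0**27) == pytest.approx(2.0**27 * 1e-300, rel=1e-10)
    assert complement_power(0.0, 10) == 0.0
    assert complement_power(1.0, 3) == 1.0
    with pytest.raises(ValueError):
        complement_power(1.5, 2)
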