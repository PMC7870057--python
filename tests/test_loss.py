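import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import limdil as ld

LAM76 = -math.log(20 / 96)  # 1.5686, from 76 of 96 populated wells


def fisher_bruteforce(table):
    """Independent oracle: sum hypergeometric pmf over tables no more
    probable than the observed one, margins fixed."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        return 1.0
    support = range(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = {k: stats.hypergeom.pmf(k, n, col1, row1) for k in support}
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7))


class TestPSensitive:
    def test_single_cell_limit(self):
        assert ld.p_sensitive(0.0, 0.3) == 0.3
        assert ld.p_sensitive(1e-9, 0.3) == pytest.approx(0.3, abs=1e-6)

    def test_closed_form_at_observed_fraction(self):
        # consistent with 6/76 observed sensitive wells at q ~ 0.167
        assert ld.p_sensitive(LAM76, 0.167) == pytest.approx(0.0789, abs=2e-4)

    @pytest.mark.parametrize("lam", [0.2, 1.5, 4.0])
    def test_endpoints(self, lam):
        assert ld.p_sensitive(lam, 0.0) == 0.0
        assert ld.p_sensitive(lam, 1.0) == pytest.approx(1.0)

    @given(st.floats(0.01, 5.0), st.floats(0.0, 0.99), st.floats(1e-6, 0.2))
    def test_strictly_increasing_in_q(self, lam, q, dq):
        if q + dq <= 1.0:
            assert ld.p_sensitive(lam, q + dq) > ld.p_sensitive(lam, q)


class TestQMle:
    @pytest.mark.parametrize(
        "s, n, lam, expected",
        [
            (0, 71, 1.346, 0.0),
            (6, 76, LAM76, 0.1673),
            (76, 76, LAM76, 1.0),
        ],
    )
    def test_values(self, s, n, lam, expected):
        assert ld.q_mle(s, n, lam) == pytest.approx(expected, abs=5e-4)

    def test_matches_bisection_oracle(self):
        """Closed form agrees with numeric root-finding of p_sensitive."""
        from scipy.optimize import brentq

        for s, n, lam in [(6, 76, LAM76), (30, 80, 0.7), (3, 90, 3.0)]:
            oracle = brentq(lambda q: ld.p_sensitive(lam, q) - s / n, 0, 1, xtol=1e-12)
            assert ld.q_mle(s, n, lam) == pytest.approx(oracle, abs=1e-9)

    @given(
        st.integers(1, 95),
        st.integers(0, 96),
        st.floats(0.05, 5.0),
    )
    def test_exact_inverse_of_p_sensitive(self, n, s, lam):
        s = min(s, n)
        q = ld.q_mle(s, n, lam)
        assert abs(ld.p_sensitive(lam, q) - s / n) < 1e-10

    def test_rejects_bad_lambda(self):
        with pytest.raises(ValueError):
            ld.q_mle(3, 10, 0.0)


class TestLambdaSe:
    @pytest.mark.parametrize(
        "k, w, expected",
        [
            (76, 96, 0.1990),
            (48, 96, math.sqrt(0.5 / (96 * 0.5))),  # 0.1021
        ],
    )
    def test_delta_method_values(self, k, w, expected):
        assert ld.lambda_se(k, w) == pytest.approx(expected, abs=1e-4)

    def test_matches_parametric_bootstrap(self, rng):
        """Bootstrap spread of lambda_hat reproduces the delta-method SE."""
        k, w = 76, 96
        lam = ld.lambda_mle(k, w)
        ks = rng.binomial(w, 1 - math.exp(-lam), size=40_000)
        ks = ks[ks < w]
        boot = np.std(-np.log1p(-ks / w))
        assert ld.lambda_se(k, w) == pytest.approx(boot, rel=0.05)

    def test_vanishes_for_large_plates(self):
        assert ld.lambda_se(50_000, 100_000) < 0.01

    @pytest.mark.parametrize("k", [0, 96])
    def test_undefined_at_edges(self, k):
        with pytest.raises(ValueError):
            ld.lambda_se(k, 96)


class TestLossCi:
    def test_no_sensitive_wells_one_sided(self, noninduced_experiment, small_config):
        est = ld.loss_ci(noninduced_experiment, small_config)
        assert est.one_sided and est.ci_lo == 0.0
        assert est.q_hat == 0.0
        assert est.ci_hi <= 0.08

    def test_induced_interval(self, induced_experiment, small_config):
        est = ld.loss_ci(induced_experiment, small_config)
        assert not est.one_sided
        assert est.ci_lo <= est.q_hat <= est.ci_hi
        assert round(est.ci_lo, 1) == 0.1 and round(est.ci_hi, 1) == 0.3

    def test_all_sensitive_upper_endpoint_is_one(self, small_config):
        exp = ld.LossExperiment("c", "i", 96, 40, 40)
        est = ld.loss_ci(exp, small_config)
        assert est.ci_hi == 1.0 and est.one_sided

    def test_interval_contains_point_estimate(self, small_config, rng):
        for s, n in [(2, 50), (10, 60), (55, 70)]:
            est = ld.loss_ci(ld.LossExperiment("c", "i", 96, n, s), small_config)
            assert est.ci_lo <= est.q_hat <= est.ci_hi

    def test_upper_bound_tightens_with_more_wells(self, small_config):
        """At fixed per-well density, more populated wells with zero
        sensitives pin q harder (one-sided bound non-increasing in n)."""
        bounds = [
            ld.loss_ci(ld.LossExperiment("c", "n", w, n, 0), small_config).ci_hi
            for n, w in ((21, 28), (45, 60), (90, 120))  # lambda_hat = ln 4 each
        ]
        assert bounds[0] >= bounds[1] >= bounds[2]

    def test_unconditional_variant_is_wider_or_equal(self, induced_experiment, small_config):
        cond = ld.loss_ci(induced_experiment, small_config)
        uncond = ld.loss_ci(induced_experiment, small_config, resimulate_populated=True)
        assert uncond.ci_hi - uncond.ci_lo >= cond.ci_hi - cond.ci_lo - 0.02

    def test_fallback_lambda_needed_when_unidentified(self, small_config):
        exp = ld.LossExperiment("c", "i", 96, 96, 10)
        with pytest.raises(ValueError):
            ld.loss_ci(exp, small_config)
        est = ld.loss_ci(
            ld.LossExperiment("c", "i", 96, 96, 10, nominal_lambda=1.5), small_config
        )
        assert 0 <= est.ci_lo <= est.ci_hi <= 1


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, printed",
        [
            ([[0, 71], [6, 70]], 0.03),
            ([[11, 185], [0, 71]], 0.04),
            ([[1, 1], [1, 1]], 1.0),
        ],
    )
    def test_reported_p_values(self, table, printed):
        assert round(ld.fisher_exact_two_sided(table), 2) == printed

    @pytest.mark.parametrize(
        "table",
        [
            [[0, 71], [6, 70]],
            [[11, 185], [0, 71]],
            [[3, 9], [7, 2]],
            [[20, 30], [40, 10]],
            [[0, 0], [5, 9]],
            [[1, 99], [2, 98]],
        ],
    )
    def test_agrees_with_bruteforce_enumeration(self, table):
        assert ld.fisher_exact_two_sided(table) == pytest.approx(
            fisher_bruteforce(table), abs=1e-9
        )

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            ld.fisher_exact_two_sided([[1, -2], [3, 4]])


class TestPerGenerationLoss:
    @pytest.mark.parametrize(
        "p_total, dur, dbl, expected",
        [
            (0.0, 48, 10.3, 0.0),
            (0.17, 48, 10.3, 0.039),  # 17% over 48 h at 10.3 h doubling
            (0.5, 24, 24, 0.5),
        ],
    )
    def test_values(self, p_total, dur, dbl, expected):
        assert ld.per_generation_loss(p_total, dur, dbl) == pytest.approx(
            expected, abs=5e-4
        )

    def test_total_loss_propagates(self):
        assert ld.per_generation_loss(1.0, 48, 10.3) == 1.0

    @given(st.floats(0.0, 0.99), st.floats(1.0, 100.0), st.floats(1.0, 100.0))
    def test_bounded_by_total(self, p, dur, dbl):
        out = ld.per_generation_loss(p, dur, dbl)
        if dbl <= dur:
            assert 0.0 <= out <= p + 1e-12
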