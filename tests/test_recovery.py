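import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import recotherm as rt
from recotherm.errors import UndefinedRatioError, ValidationError

from conftest import random_pairs


class TestLogRatios:
    def test_identical_messages_give_zero(self, channel):
        for y in range(3):
            assert rt.log_likelihood_ratio(channel, y, 1, 1) == 0.0

    @pytest.mark.parametrize(
        "y, x, x_alt, num, den",
        [(0, 0, 1, 0.4410, 0.5558), (2, 2, 1, 0.5371, 0.0594)],
    )
    def test_printed_entries(self, channel, y, x, x_alt, num, den):
        got = rt.log_likelihood_ratio(channel, y, x, x_alt)
        assert got == pytest.approx(math.log(num / den), abs=1e-12)

    def test_zero_handling(self):
        ch = rt.Channel(np.array([[0.0, 0.5], [1.0, 0.5]]))
        assert rt.log_likelihood_ratio(ch, 0, 1, 0) == math.inf
        assert rt.log_likelihood_ratio(ch, 0, 0, 1) == -math.inf
        ch2 = rt.Channel(np.array([[0.0, 0.0, 1.0], [1.0, 1.0, 0.0]]))
        with pytest.raises(UndefinedRatioError):
            rt.log_likelihood_ratio(ch2, 0, 0, 1)

    def test_map_ratio_adds_prior_term(self, channel, prior):
        gamma = math.log(prior[0] / prior[1])
        assert gamma == pytest.approx(1.8119, abs=5e-5)
        r = rt.map_log_ratio(channel, prior, 0, 0, 1)
        l = rt.log_likelihood_ratio(channel, 0, 0, 1)
        assert r == pytest.approx(l + gamma, abs=1e-14)
        assert r == pytest.approx(1.5806, abs=5e-5)

    def test_map_ratio_equals_log_posterior_ratio(self, channel, prior):
        for y in range(3):
            post = rt.posterior(channel, prior, y)
            for x in range(3):
                for z in range(3):
                    assert rt.map_log_ratio(channel, prior, y, x, z) == (
                        pytest.approx(math.log(post[x] / post[z]), abs=1e-12)
                    )

    def test_map_ratio_antisymmetry(self, channel, prior):
        r = rt.map_log_ratio
        assert r(channel, prior, 2, 0, 2) == pytest.approx(
            -r(channel, prior, 2, 2, 0), abs=1e-14
        )

    def test_uniform_prior_reduces_to_likelihood_ratio(self, channel):
        u = rt.Prior.uniform(3)
        for y in range(3):
            assert rt.map_log_ratio(channel, u, y, 0, 2) == pytest.approx(
                rt.log_likelihood_ratio(channel, y, 0, 2), abs=1e-14
            )

    def test_pointwise_split_into_i_and_ie(self, channel, prior):
        """l(y, x, x') == i(x, y) + i_e(x', y) at every triple."""
        from recotherm.recovery import (
            stochastic_error_information,
            stochastic_mutual_information,
        )

        for y in range(3):
            for x in range(3):
                for z in range(3):
                    l = rt.log_likelihood_ratio(channel, y, x, z)
                    i = stochastic_mutual_information(channel, prior, x, y)
                    ie = stochastic_error_information(channel, prior, z, y)
                    assert l == pytest.approx(i + ie, abs=1e-12)


class TestDecisions:
    def test_ml_decodings_on_example(self, channel):
        assert rt.decide_ml(channel, 2) == (2, False)
        assert rt.decide_ml(channel, 0) == (1, False)

    def test_map_disagrees_with_ml_under_skewed_prior(self, channel, prior):
        # the skewed prior flips the decoding of the first received message
        assert rt.decide_ml(channel, 0).label == 1
        assert rt.decide_map(channel, prior, 0).label == 0
        assert rt.decide_map(channel, prior, 2).label == 2

    def test_uniform_prior_makes_rules_agree(self):
        for b in random_pairs(50, start_seed=100):
            u = rt.Prior.uniform(b.channel.n_src)
            for y in range(b.channel.n_rcv):
                assert (
                    rt.decide_map(b.channel, u, y).label
                    == rt.decide_ml(b.channel, y).label
                )

    def test_total_tie_flags_lowest_label(self):
        c = np.array([0.3, 0.7])
        ch = rt.Channel(np.column_stack([c, c, c]))
        d = rt.decide_ml(ch, 0)
        assert d.label == 0 and d.tie


class TestEnsembleQuantities:
    def test_identical_columns_all_vanish(self):
        c = np.array([0.25, 0.35, 0.4])
        ch = rt.Channel(np.column_stack([c, c, c]))
        pr = rt.Prior(np.array([0.2, 0.3, 0.5]))
        assert rt.recoverability(ch, pr) == 0.0
        assert rt.mutual_information(ch, pr) == pytest.approx(0.0, abs=1e-14)
        assert rt.error_information(ch, pr) == pytest.approx(0.0, abs=1e-14)

    def test_noiseless_channel_mutual_information(self):
        ch = rt.Channel(np.eye(3))
        assert rt.mutual_information(ch, rt.Prior.uniform(3)) == pytest.approx(
            math.log(3), abs=1e-14
        )
        # KL from the output marginal to a point-mass column diverges
        assert rt.error_information(ch, rt.Prior.uniform(3)) == math.inf
        assert rt.recoverability(ch, rt.Prior.uniform(3)) == math.inf

    def test_recoverability_matches_exhaustive_triple_sum(self, channel, prior):
        # oracle: the 27-term sum written out in plain Python
        total = 0.0
        for x in range(3):
            for z in range(3):
                for y in range(3):
                    total += (
                        prior[x]
                        * prior[z]
                        * channel.q[y, x]
                        * math.log(channel.q[y, x] / channel.q[y, z])
                    )
        assert rt.recoverability(channel, prior) == pytest.approx(total, abs=1e-12)

    def test_decomposition_identity_on_random_ensemble(self):
        for b in random_pairs(300, start_seed=1000):
            R = rt.recoverability(b.channel, b.prior)
            I = rt.mutual_information(b.channel, b.prior)
            Ie = rt.error_information(b.channel, b.prior)
            assert R >= 0 and I >= 0 and Ie >= 0
            assert abs(R - I - Ie) < 1e-10

    def test_permutation_invariance(self, channel, prior):
        rng = np.random.default_rng(3)
        R0 = rt.recoverability(channel, prior)
        I0 = rt.mutual_information(channel, prior)
        Ie0 = rt.error_information(channel, prior)
        for _ in range(5):
            ps = rng.permutation(3)
            pr_ = rng.permutation(3)
            ch2 = rt.Channel(channel.q[np.ix_(pr_, ps)])
            p2 = rt.Prior(prior.probs[ps])
            assert rt.recoverability(ch2, p2) == pytest.approx(R0, abs=1e-12)
            assert rt.mutual_information(ch2, p2) == pytest.approx(I0, abs=1e-12)
            assert rt.error_information(ch2, p2) == pytest.approx(Ie0, abs=1e-12)

    def test_two_source_closed_form_value(self):
        ch = rt.compose_channel(
            rt.StrengthDecomposition(np.full(3, 1 / 3), np.array([0.1, -0.1, 0.0]))
        )
        got = rt.recoverability(ch, rt.Prior.two_point(0.5))
        # oracle: R = 2 p (1-p) sum_y d_y log[(m+d)/(m-d)]
        expected = 2 * 0.25 * (
            0.1 * math.log((1 / 3 + 0.1) / (1 / 3 - 0.1))
            - 0.1 * math.log((1 / 3 - 0.1) / (1 / 3 + 0.1))
        )
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.0619, abs=5e-5)

    def test_info_summary_bundles_identity(self, channel, prior):
        s = rt.InfoSummary.from_channel(channel, prior)
        assert s.R == pytest.approx(s.I + s.Ie, abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), n_src=st.integers(2, 5), n_rcv=st.integers(2, 5))
    def test_identity_property_random_shapes(self, seed, n_src, n_rcv):
        b = rt.generate_random_fixture(n_src, n_rcv, seed=seed)
        R = rt.recoverability(b.channel, b.prior)
        I = rt.mutual_information(b.channel, b.prior)
        Ie = rt.error_information(b.channel, b.prior)
        assert R >= -1e-15 and I >= -1e-15 and Ie >= -1e-15
        assert abs(R - I - Ie) < 1e-10

    def test_size_mismatch_rejected(self, channel):
        with pytest.raises(ValidationError):
            rt.recoverability(channel, rt.Prior.two_point(0.5))
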