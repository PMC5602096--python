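"""PSSM construction, matching scores, magnitude and posterior oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad

from synsplice import (
    PWMModel,
    build_pssm,
    magnitude,
    matching_score,
    posterior_gain_loss,
    rbp_feature_summary,
    scan_variant,
)
from synsplice.errors import (
    DegenerateVariance,
    InvalidAlphabet,
    LengthMismatch,
    WindowTooShort,
)
from synsplice.pwm import column_frequency_sums, max_window_score

LOG2_2P6 = np.log2(2.6)   # s_{1,A} = log2((3.25/5)/0.25)
LOG2_0P2 = np.log2(0.2)   # zero-count cells: log2((0.25/5)/0.25)
LOG2_3P4 = np.log2(3.4)   # s_{2,G} = log2((4.25/5)/0.25)


class TestBuildPssm:
    def test_uniform_pwm_gives_all_zero_model(self, uniform_model):
        assert np.all(uniform_model.pssm == 0.0)
        assert uniform_model.binding_mean == 0.0
        assert uniform_model.binding_var == 0.0
        assert uniform_model.nonbinding_mean == 0.0
        assert uniform_model.nonbinding_var == 0.0

    def test_hand_evaluated_pssm(self, hand_model):
        # column 1: (3.25, 1.25, 0.25, 0.25) / 5 against background 1/4
        expected = np.array(
            [
                [LOG2_2P6, 0.0, LOG2_0P2, LOG2_0P2],
                [LOG2_0P2, LOG2_0P2, LOG2_3P4, LOG2_0P2],
            ]
        )
        np.testing.assert_allclose(hand_model.pssm, expected, atol=1e-12)

    def test_hand_evaluated_moments(self, hand_model):
        # f = 2^s/4 per cell; binding moments summed cell by cell
        f = np.array([[0.65, 0.25, 0.05, 0.05], [0.05, 0.05, 0.85, 0.05]])
        s = hand_model.pssm
        np.testing.assert_allclose(hand_model.binding_freq, f, atol=1e-12)
        assert hand_model.binding_mean == pytest.approx(np.sum(f * s), abs=1e-12)
        assert hand_model.binding_mean == pytest.approx(1.8162551, abs=1e-6)
        assert hand_model.binding_var == pytest.approx(
            np.sum(f * s**2 - (f * s) ** 2), abs=1e-12
        )
        assert hand_model.binding_var == pytest.approx(2.1101945, abs=1e-6)
        assert hand_model.nonbinding_mean == pytest.approx(0.25 * s.sum(), abs=1e-12)

    def test_frequency_normalisation_diagnostic(self, hand_model):
        # count totals equal n_sites here, so the f_ij sums are exactly 1
        np.testing.assert_allclose(column_frequency_sums(hand_model), 1.0, atol=1e-12)

    def test_unbalanced_counts_flagged_not_renormalised(self):
        # column total (2) below n_sites (10): f-sums deviate from 1
        pwm = PWMModel("lowcount", np.array([[2.0, 0, 0, 0]]), n_sites=10)
        model = build_pssm(pwm)
        assert column_frequency_sums(model)[0] < 1.0


class TestMatchingScore:
    def test_uniform_model_scores_zero(self, uniform_model):
        assert matching_score(uniform_model, "ACG") == 0.0
        assert matching_score(uniform_model, "TTT") == 0.0

    def test_hand_score_and_additivity(self, hand_model):
        assert matching_score(hand_model, "AG") == pytest.approx(
            LOG2_2P6 + LOG2_3P4, abs=1e-12
        )
        assert matching_score(hand_model, "CG") == pytest.approx(LOG2_3P4, abs=1e-12)
        # additive over positions
        assert matching_score(hand_model, "AG") == pytest.approx(
            matching_score(hand_model, "AT")
            - LOG2_0P2
            + LOG2_3P4,
            abs=1e-12,
        )

    def test_u_maps_to_t(self, hand_model):
        assert matching_score(hand_model, "AU") == matching_score(hand_model, "AT")

    def test_errors(self, hand_model):
        with pytest.raises(LengthMismatch):
            matching_score(hand_model, "AGG")
        with pytest.raises(InvalidAlphabet):
            matching_score(hand_model, "AN")


def _quadrature_magnitude(s_r, s_a, model):
    """Independent oracle: evaluate the four integrals numerically."""
    sd_b = np.sqrt(model.binding_var)
    sd_nb = np.sqrt(model.nonbinding_var)

    def gauss(mean, sd):
        return lambda x: np.exp(-0.5 * ((x - mean) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))

    lo = min(model.binding_mean, model.nonbinding_mean) - 12 * max(sd_b, sd_nb)
    cdf_b_a = quad(gauss(model.binding_mean, sd_b), lo, s_a)[0]
    cdf_b_r = quad(gauss(model.binding_mean, sd_b), lo, s_r)[0]
    cdf_nb_a = quad(gauss(model.nonbinding_mean, sd_nb), lo, s_a)[0]
    cdf_nb_r = quad(gauss(model.nonbinding_mean, sd_nb), lo, s_r)[0]
    return np.log2(
        (cdf_b_a / (1 - cdf_nb_a)) / (cdf_b_r / (1 - cdf_nb_r))
    )


class TestMagnitude:
    def test_zero_at_equal_scores(self, hand_model):
        assert magnitude(1.3, 1.3, hand_model) == 0.0

    def test_antisymmetry(self, hand_model):
        m = magnitude(0.5, 2.0, hand_model)
        assert m == pytest.approx(-magnitude(2.0, 0.5, hand_model), abs=1e-9)

    def test_degenerate_variance_raises(self, uniform_model):
        with pytest.raises(DegenerateVariance):
            magnitude(0.0, 1.0, uniform_model)

    def test_matches_quadrature_oracle_on_random_draws(self, hand_model):
        rng = np.random.default_rng(42)
        for _ in range(200):
            s_r, s_a = rng.normal(hand_model.binding_mean, 2.0, size=2)
            got = magnitude(s_r, s_a, hand_model)
            want = _quadrature_magnitude(s_r, s_a, hand_model)
            assert got == pytest.approx(want, abs=1e-6)

    @settings(max_examples=60, deadline=None)
    @given(
        s_r=st.floats(-4, 6),
        delta=st.floats(0.01, 4),
    )
    def test_sign_tracks_score_ordering(self, hand_model, s_r, delta):
        assert magnitude(s_r, s_r + delta, hand_model) > 0  # gain
        assert magnitude(s_r, s_r - delta, hand_model) < 0  # loss


class TestPosterior:
    def test_uninformative_limit_closed_form(self, hand_model):
        # P(S|B) == P(S|NB) for both alleles when the two Gaussians coincide:
        # build such a model by hand with equal binding/non-binding moments.
        from synsplice.pwm import BindingScoreModel

        model = BindingScoreModel(
            rbp_id="flat",
            pssm=hand_model.pssm,
            binding_freq=hand_model.binding_freq,
            binding_mean=0.0,
            binding_var=1.0,
            nonbinding_mean=0.0,
            nonbinding_var=1.0,
        )
        # E[2 B (1-B)] under Beta(2, 20) = 2 (2/22 - 6/506)
        expected = 2 * (2 / 22 - 6 / 506)
        got = posterior_gain_loss(0.3, -0.8, model, prior=(2, 20))
        assert got == pytest.approx(expected, abs=1e-6)

    def test_prior_concentrated_at_zero_kills_posterior(self, hand_model):
        p = posterior_gain_loss(0.5, 3.0, hand_model, prior=(1.001, 50000.0))
        assert p < 1e-3
        # and tightening the concentration monotonically shrinks it
        looser = posterior_gain_loss(0.5, 3.0, hand_model, prior=(1.001, 5000.0))
        assert p < looser

    @settings(max_examples=40, deadline=None)
    @given(
        s_r=st.floats(-6, 8),
        s_a=st.floats(-6, 8),
        alpha=st.floats(1.1, 5),
    )
    def test_posterior_is_probability(self, hand_model, s_r, s_a, alpha):
        beta = (alpha - 1) / 0.05 - alpha + 2  # keep mode at 0.05
        p = posterior_gain_loss(s_r, s_a, hand_model, prior=(alpha, beta))
        assert 0.0 <= p <= 1.0

    def test_opposite_scores_give_high_posterior(self, hand_model):
        # ref deep in non-binding, alt deep in binding territory
        p = posterior_gain_loss(-5.0, hand_model.binding_mean, hand_model)
        assert p > posterior_gain_loss(-5.0, -5.0, hand_model)


class TestScanVariant:
    def test_degenerate_identical_windows(self, hand_model):
        d = scan_variant(hand_model, "AAGA", "AAGA", 1)
        assert d.magnitude == 0.0
        assert d.score_ref == d.score_alt

    def test_allele_swap_negates_m_in_symmetric_mode(self, hand_model):
        d1 = scan_variant(hand_model, "TAGT", "TCGT", 1, mode="best_either")
        d2 = scan_variant(hand_model, "TCGT", "TAGT", 1, mode="best_either")
        assert d1.magnitude == pytest.approx(-d2.magnitude, abs=1e-9)

    def test_gain_of_consensus_site_is_positive(self, hand_model):
        # consensus is AG; ref has CG at the central offset, alt creates AG
        d = scan_variant(hand_model, "TTCGTT", "TTAGTT", 2)
        assert d.score_alt > d.score_ref
        assert d.magnitude > 0
        assert d.magnitude == pytest.approx(
            _quadrature_magnitude(d.score_ref, d.score_alt, hand_model), abs=1e-6
        )

    def test_best_ref_offset_maximises_wild_score(self, hand_model):
        d = scan_variant(hand_model, "AGAGA", "AGCGA", 2)
        # offsets 1..2 overlap index 2; wild "GA"(1) vs "AG"(2)? offsets 1,2
        # give windows ref[1:3]='GA', ref[2:4]='AG'; AG scores highest.
        assert d.offset == 2

    def test_window_too_short(self, hand_model):
        with pytest.raises(WindowTooShort):
            scan_variant(hand_model, "A", "G", 0)


class TestFeatureSummary:
    def test_zero_information_panel_scores_zero(self, uniform_model):
        feats = rbp_feature_summary("ACGTACGT", "ACTTACGT", 2, [uniform_model])
        for sid in ("sfrs1", "sfrs2", "sfrs5", "sfrs6"):
            assert feats[f"{sid}_max_score_wild"] == 0.0
            assert feats[f"{sid}_max_score_mut"] == 0.0
        assert feats["rbp_max_abs_magnitude"] == 0.0
        assert feats["rbp_n_binding_flips"] == 0.0

    def test_destroyed_consensus_lowers_mut_max(self, hand_pwm):
        model = build_pssm(
            PWMModel("SFRS1", hand_pwm.counts, n_sites=hand_pwm.n_sites)
        )
        ref_exon = "TTTAGTTT"  # consensus AG at offset 3
        alt_exon = "TTTCGTTT"  # variant destroys it
        feats = rbp_feature_summary(ref_exon, alt_exon, 3, [model])
        assert feats["sfrs1_max_score_mut"] < feats["sfrs1_max_score_wild"]
        assert feats["sfrs1_max_score_wild"] == pytest.approx(
            max_window_score(model, ref_exon)
        )

    def test_null_fixture_has_no_flips(self, hand_pwm):
        weak = build_pssm(PWMModel("SFRS2", np.full((2, 4), 5.0), n_sites=20))
        feats = rbp_feature_summary("ACGTACAC", "ACATACAC", 2, [weak])
        assert feats["rbp_n_binding_flips"] == 0.0
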