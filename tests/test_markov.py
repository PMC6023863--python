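"""Transition-matrix propagation, estimation, and propensity partitioning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hulakin import (
    CompositionSeries,
    Motion,
    TransitionMatrix,
    fit_transition_matrix,
    propagate,
    propensity_shares,
    quantum_yield_ratio_check,
)
from hulakin.errors import ValidationError
from hulakin.photokin import QuantumYieldMatrix
from hulakin.synth import NoiseModel, generate_share_dataset


class TestPropagate:
    def test_identity_fixes_everything(self):
        x0 = np.array([0.1, 0.2, 0.3, 0.4])
        assert np.allclose(propagate(np.eye(4), x0, 11), x0)

    def test_deterministic_hop(self):
        m = np.eye(4)
        m[0] = [0, 0, 1, 0]
        assert np.allclose(propagate(m, [1, 0, 0, 0], 1), [0, 0, 1, 0])

    def test_matches_iterated_single_steps(self, random_transition_matrix):
        rng = np.random.default_rng(3)
        x0 = rng.dirichlet(np.ones(4))
        v = x0.copy()
        for _ in range(7):
            v = v @ random_transition_matrix.M
        assert np.abs(propagate(random_transition_matrix, x0, 7) - v).max() < 1e-12

    def test_preserves_simplex(self, random_transition_matrix):
        out = propagate(random_transition_matrix, [0.25, 0.25, 0.25, 0.25], 50)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(out >= 0)

    def test_negative_steps_rejected(self):
        with pytest.raises(ValidationError):
            propagate(np.eye(4), [1, 0, 0, 0], -1)


class TestRowStochasticValidation:
    def test_bad_row_sum_rejected(self):
        m = np.eye(4)
        m[0, 1] = 0.1
        with pytest.raises(ValidationError):
            TransitionMatrix(m)


class TestFit:
    def test_noise_free_recovery_all_rows(self, random_transition_matrix,
                                          four_pure_start_series):
        res = fit_transition_matrix(four_pure_start_series)
        assert np.abs(res.matrix.M - random_transition_matrix.M).max() < 1e-4
        assert res.identity_rows == []

    def test_partial_identifiability_flags_unpopulated_rows(self):
        m = np.eye(4)
        m[0] = [0.95, 0.05, 0.0, 0.0]  # only A->B active
        t = np.arange(0.0, 31.0)
        frac = np.vstack([propagate(m, [1.0, 0, 0, 0], int(k)) for k in t])
        res = fit_transition_matrix([CompositionSeries(t, frac)])
        assert res.matrix.entry("A", "B") == pytest.approx(0.05, abs=1e-3)
        flagged = {r.value for r in res.identity_rows}
        assert {"C", "D"} <= flagged
        assert res.warnings

    def test_stationary_data_returns_identity(self):
        t = np.arange(0.0, 11.0)
        frac = np.tile([0.25, 0.25, 0.25, 0.25], (11, 1))
        res = fit_transition_matrix([CompositionSeries(t, frac)])
        assert np.abs(res.matrix.M - np.eye(4)).max() < 1e-6
        assert any("flat" in w for w in res.warnings)

    def test_non_integer_times_interpolated_and_flagged(self, random_transition_matrix):
        t_obs = np.array([0.0, 1.5, 3.5, 5.5, 9.5, 14.5, 20.5])
        grid = np.arange(0.0, 21.0)
        frac = np.vstack([propagate(random_transition_matrix, [1.0, 0, 0, 0], int(k))
                          for k in grid])
        obs = np.column_stack([np.interp(t_obs, grid, frac[:, j]) for j in range(4)])
        res = fit_transition_matrix([CompositionSeries.normalized(t_obs, obs)])
        assert res.interpolated

    def test_noisy_recovery_stays_close_over_replicates(self):
        """Gaussian mole-fraction noise (sigma = 0.01) moves recovered source-row
        entries by a few noise-scaled standard errors at most."""
        m_true = np.eye(4)
        m_true[1] = [0.0, 0.95, 0.038, 0.012]
        devs = []
        for seed in range(20):
            s = generate_share_dataset("B", {Motion.HT: 0.76, Motion.DBI: 0.24, Motion.SBR: 0.0},
                                       overall_rate=0.05, noise=NoiseModel(0.01, seed))
            res = fit_transition_matrix([s], fit_rows=["B"])
            devs.append(np.abs(res.matrix.M[1] - m_true[1]).max())
        assert np.median(devs) < 0.01
        assert max(devs) < 0.03

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            fit_transition_matrix([])


class TestRatioCheck:
    def test_proportional_rows_have_zero_deviation(self, benzene_phi):
        m = np.eye(4)
        for i in range(4):
            m[i] = 0.02 * benzene_phi.phi[i]
            m[i, i] = 1.0 - m[i].sum()
        res = quantum_yield_ratio_check(TransitionMatrix(m), benzene_phi)
        assert res.max_relative_deviation < 1e-9

    def test_scale_invariance_of_ratios(self):
        """Off-diagonal ratios mirror quantum-yield ratios regardless of the
        overall conversion scale per step."""
        phi = QuantumYieldMatrix.from_channels(
            {("A", "B"): 0.09, ("A", "C"): 0.31, ("A", "D"): 0.008})
        for c in (0.01, 0.1, 1.0):
            m = np.eye(4)
            m[0] = [0.0, 0.009 * c, 0.031 * c, 0.0008 * c]
            m[0, 0] = 1.0 - m[0].sum()
            res = quantum_yield_ratio_check(TransitionMatrix(m), phi)
            assert res.max_relative_deviation < 1e-12

    def test_perturbation_is_detected(self, benzene_phi):
        m = np.eye(4)
        for i in range(4):
            m[i] = 0.02 * benzene_phi.phi[i]
            m[i, i] = 1.0 - m[i].sum()
        m[0, 1] *= 1.10
        m[0, 0] = 1.0 - m[0, 1] - m[0, 2] - m[0, 3]
        res = quantum_yield_ratio_check(TransitionMatrix(m), benzene_phi)
        assert res.max_relative_deviation == pytest.approx(0.10, abs=1e-6)

    def test_zero_channels_skipped_and_reported(self):
        phi = QuantumYieldMatrix.from_channels({("A", "B"): 0.1, ("A", "C"): 0.2})
        m = np.eye(4)
        m[0] = [0.90, 0.04, 0.06, 0.0]
        res = quantum_yield_ratio_check(TransitionMatrix(m), phi)
        assert res.skipped  # pairs involving the closed A->D channel
        assert np.isfinite(res.max_relative_deviation)


class TestPropensityShares:
    def test_three_way_shares_from_yield_row(self):
        # A-row yields 9% SBR(B), 31% DBI(C), 0.8% HT(D)
        ps = propensity_shares("A", [0.0, 0.09, 0.31, 0.008])
        assert 100 * ps.share(Motion.SBR) == pytest.approx(9 / 40.8 * 100, abs=0.05)
        assert 100 * ps.share(Motion.DBI) == pytest.approx(31 / 40.8 * 100, abs=0.05)
        assert 100 * ps.share(Motion.HT) == pytest.approx(0.8 / 40.8 * 100, abs=0.05)
        assert sum(ps.shares.values()) == pytest.approx(1.0, abs=1e-12)

    def test_pairwise_renormalization(self):
        ps = propensity_shares("A", [0.0, 0.09, 0.31, 0.008],
                               mode="pairwise", pair=(Motion.DBI, Motion.SBR))
        assert 100 * ps.share(Motion.DBI) == pytest.approx(77.5, abs=1e-9)
        assert 100 * ps.share(Motion.SBR) == pytest.approx(22.5, abs=1e-9)

    def test_single_channel_gets_full_share(self):
        ps = propensity_shares("B", {"C": 0.2})
        assert ps.share(Motion.HT) == 1.0

    @given(scale=st.floats(1e-6, 1e6))
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_positive_rescaling(self, scale):
        base = np.array([0.0, 0.09, 0.31, 0.008])
        a = propensity_shares("A", base)
        b = propensity_shares("A", base * scale)
        for m in (Motion.SBR, Motion.DBI, Motion.HT):
            assert a.share(m) == pytest.approx(b.share(m), rel=1e-9)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValidationError):
            propensity_shares("A", [0.0, 0.0, 0.0, 0.0])
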