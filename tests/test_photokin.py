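"""Forward photokinetic model: photon partitioning, integration, stationary state."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hulakin import (
    CompositionSeries,
    PhotoConditions,
    QuantumYieldMatrix,
    excitation_rates,
    photostationary_state,
    simulate_photokinetics,
)
from hulakin.errors import ValidationError


def make_cond(flux=1e-10, eps=8000.0, conc=1.25e-4, volume=5e-4):
    return PhotoConditions(
        wavelength_nm=405.0, photon_flux=flux, path_length_cm=1.0,
        volume_l=volume, epsilon=np.full(4, float(eps)), total_conc=conc,
    )


class TestExcitationRates:
    def test_equal_mixture_half_absorbed(self):
        # A_tot = 0.30103 makes the photokinetic factor exactly 1/2
        conc = 0.30103 / (8000.0 * 1.0)
        cond = make_cond(conc=conc)
        rates = excitation_rates([0.5, 0.5, 0, 0], cond)
        assert rates[0] == pytest.approx(0.25 * cond.photon_flux, rel=1e-12)
        assert rates[1] == pytest.approx(0.25 * cond.photon_flux, rel=1e-12)
        assert rates[2] == rates[3] == 0.0

    def test_transparent_sample_absorbs_nothing(self):
        cond = PhotoConditions(
            wavelength_nm=405, photon_flux=1e-9, path_length_cm=1.0,
            volume_l=1e-3, epsilon=np.zeros(4), total_conc=1e-4,
        )
        assert np.all(excitation_rates([1, 0, 0, 0], cond) == 0.0)

    def test_total_absorption_limit(self):
        cond = make_cond(eps=1e7)  # A_tot = 1250
        rates = excitation_rates([1, 0, 0, 0], cond)
        assert rates[0] == pytest.approx(cond.photon_flux, rel=1e-12)

    def test_negative_composition_rejected(self):
        with pytest.raises(ValidationError):
            excitation_rates([1.1, -0.1, 0, 0], make_cond())

    @given(
        x=st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4).filter(lambda v: sum(v) > 0.1),
        eps=st.lists(st.floats(0.0, 2e4), min_size=4, max_size=4),
    )
    @settings(max_examples=50, deadline=None)
    def test_total_absorbed_never_exceeds_flux(self, x, eps):
        x = np.asarray(x) / sum(x)
        cond = PhotoConditions(
            wavelength_nm=405, photon_flux=1e-9, path_length_cm=1.0,
            volume_l=1e-3, epsilon=np.asarray(eps), total_conc=1e-4,
        )
        rates = excitation_rates(x, cond)
        assert rates.sum() <= cond.photon_flux * (1 + 1e-12)
        assert np.all(rates >= 0)

    def test_dilute_limit_matches_linearized_form(self):
        """For A_tot <= 0.01 the partition formula agrees with
        rate_i = ln(10) * F * A_i to about 1.2% (first-order Beer-Lambert)."""
        cond = make_cond(conc=0.01 / 8000.0)
        x = np.array([0.4, 0.3, 0.2, 0.1])
        a = cond.epsilon * cond.path_length_cm * cond.total_conc * x
        linear = np.log(10.0) * cond.photon_flux * a
        full = excitation_rates(x, cond)
        assert np.all(np.abs(full - linear) <= 0.012 * linear)


class TestSimulate:
    def test_no_photochemistry_is_stationary(self):
        s = simulate_photokinetics([0.3, 0.3, 0.2, 0.2], np.zeros((4, 4)),
                                   make_cond(), np.linspace(0, 60, 7))
        assert np.allclose(s.fractions, s.fractions[0])

    def test_single_channel_exact_exponential(self):
        """With equal molar absorptivities the A_tot stays constant, so a lone
        A->C channel decays A as an exact exponential; the trace must match the
        closed form to 1e-6."""
        cond = make_cond()
        phi_ac = 0.2
        phi = QuantumYieldMatrix.from_channels({("A", "C"): phi_ac})
        t = np.linspace(0.0, 40.0, 41)
        s = simulate_photokinetics([1, 0, 0, 0], phi, cond, t)
        a_tot = 8000.0 * 1.0 * 1.25e-4
        k = (phi_ac * cond.photon_flux * (1 - 10 ** (-a_tot)) / a_tot
             * cond.epsilon[0] * cond.path_length_cm * cond.total_conc / cond.total_moles)
        expected = np.exp(-k * t * 60.0)
        assert np.abs(s.fraction_of("A") - expected).max() < 1e-6

    def test_mass_conservation(self, benzene_phi, photo_conditions):
        s = simulate_photokinetics([1, 0, 0, 0], benzene_phi, photo_conditions,
                                   np.arange(0.0, 31.0))
        assert np.abs(s.fractions.sum(axis=1) - 1.0).max() < 1e-8
        assert np.all(s.fractions >= 0.0)

    def test_monotone_channel_response(self):
        """More quantum yield on A->C cannot produce less C at short time."""
        cond = make_cond(conc=1e-6)  # dilute
        t = np.array([0.0, 2.0])
        formed = []
        for val in (0.05, 0.10, 0.20):
            phi = QuantumYieldMatrix.from_channels({("A", "C"): val, ("A", "B"): 0.05})
            s = simulate_photokinetics([1, 0, 0, 0], phi, cond, t)
            formed.append(s.fraction_of("C")[-1])
        assert formed[0] < formed[1] < formed[2]

    def test_long_time_reaches_photostationary_state(self, benzene_phi, photo_conditions):
        pss = photostationary_state(benzene_phi, photo_conditions)
        s = simulate_photokinetics([1, 0, 0, 0], benzene_phi, photo_conditions,
                                   np.array([0.0, 2e5]))
        assert np.abs(s.fractions[-1] - pss).max() < 1e-6


class TestPhotostationaryState:
    def test_symmetric_two_state_gives_half_half(self):
        phi = QuantumYieldMatrix.from_channels({("A", "C"): 0.1, ("C", "A"): 0.1})
        pss = photostationary_state(phi, make_cond(), x0=[0.5, 0, 0.5, 0])
        assert pss[0] == pytest.approx(0.5, abs=1e-8)
        assert pss[2] == pytest.approx(0.5, abs=1e-8)

    def test_absorbing_state(self):
        phi = QuantumYieldMatrix.from_channels({("A", "C"): 0.2})
        pss = photostationary_state(phi, make_cond(), x0=[1, 0, 0, 0])
        assert np.allclose(pss, [0, 0, 1, 0], atol=1e-8)

    def test_matches_embedded_markov_chain_stationary_distribution(self):
        """With equal absorptivities the master equation is linear, so the
        stationary composition equals the stationary distribution of the
        small-step embedded chain M = I + dt*G."""
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.2, (4, 4))
        np.fill_diagonal(p, 0.0)
        pss = photostationary_state(p, make_cond())
        gen = p.copy()
        np.fill_diagonal(gen, -p.sum(axis=1))
        m = np.eye(4) + 1e-4 * gen
        w, v = np.linalg.eig(m.T)
        st_vec = np.real(v[:, np.argmin(np.abs(w - 1.0))])
        st_vec /= st_vec.sum()
        assert np.abs(pss - st_vec).max() < 1e-6


class TestCompositionSeries:
    def test_rejects_bad_shapes_and_sums(self):
        with pytest.raises(ValidationError):
            CompositionSeries(np.array([0.0, 1.0]), np.array([[1, 0, 0, 0]]))
        with pytest.raises(ValidationError):
            CompositionSeries(np.array([0.0]), np.array([[0.5, 0.1, 0.1, 0.1]]))
        with pytest.raises(ValidationError):
            CompositionSeries(np.array([1.0]), np.array([[1, 0, 0, 0]]))

    def test_normalized_constructor_repairs_noise(self):
        s = CompositionSeries.normalized(np.array([0.0]), np.array([[0.52, 0.49, 0.0, 0.02]]))
        assert s.fractions.sum() == pytest.approx(1.0, abs=1e-12)
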