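import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esptools.errors import (DataError, SingularityError, UnidentifiableError)
from esptools.titration import (ProtonationModel, TitrationSeries,
                                fit_multi_equilibrium, fit_single_equilibrium,
                                rank_estimate, species_fractions)
from esptools.synthetic import BandSpec, gen_titration, generate_preset

CHROMIS = ProtonationModel([5.5, 3.5, 1.2])


class TestSpeciesFractions:
    def test_monoprotic_half_way(self):
        f = species_fractions(ProtonationModel([4.49]), 4.49)
        assert f == pytest.approx([0.5, 0.5], abs=1e-12)

    @pytest.mark.parametrize("ph,f0", [(7.0, 0.9693), (5.5, 0.4975)])
    def test_triprotic_closed_form(self, ph, f0):
        # frozen from direct evaluation of beta_j 10^(-j pH) / sum
        assert species_fractions(CHROMIS, ph)[0] == pytest.approx(f0, abs=1e-4)

    @given(st.lists(st.floats(min_value=-2, max_value=14), min_size=1,
                    max_size=4),
           st.floats(min_value=-5, max_value=19))
    @settings(derandomize=True, max_examples=100)
    def test_fractions_normalized_everywhere(self, pkas, ph):
        pkas = sorted(pkas, reverse=True)
        f = species_fractions(ProtonationModel(pkas), ph)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(f >= 0)

    def test_monotone_in_ph(self):
        ph = np.linspace(-2, 10, 200)
        f = species_fractions(CHROMIS, ph)
        # fully deprotonated grows with pH, fully protonated decays
        assert np.all(np.diff(f[:, 0]) >= 0)
        assert np.all(np.diff(f[:, -1]) <= 0)

    def test_non_descending_pkas_warn(self):
        with pytest.warns(UserWarning, match="descending"):
            ProtonationModel([3.0, 5.0])


class TestSingleEquilibriumFit:
    def test_noiseless_recovery_exact(self, titration_1b_noiseless):
        series, truth = titration_1b_noiseless
        fit = fit_single_equilibrium(series)
        assert fit.pKa_estimates[0] == pytest.approx(truth["pKa"][0],
                                                     abs=1e-6)

    def test_component_spectra_recovered(self, titration_1b_noiseless):
        series, truth = titration_1b_noiseless
        fit = fit_single_equilibrium(series)
        E_true, E_fit = truth["component_spectra"], fit.component_spectra
        for s in range(2):
            scale = (E_fit[s] @ E_true[s]) / (E_true[s] @ E_true[s])
            assert np.allclose(E_fit[s], scale * E_true[s],
                               rtol=1e-6, atol=1e-6 * E_true[s].max())
            assert scale == pytest.approx(1.0, abs=1e-6)

    def test_monte_carlo_recovery_and_bias(self):
        errs = []
        for seed in range(200):
            series, _ = generate_preset("1b-abs", seed=seed)
            fit = fit_single_equilibrium(series)
            errs.append(fit.pKa_estimates[0] - 4.49)
        errs = np.array(errs)
        assert np.quantile(np.abs(errs), 0.95) < 0.05
        assert abs(errs.mean()) < 0.01

    def test_identical_spectra_singular(self):
        lam = np.linspace(250, 500, 100)
        row = np.exp(-((lam - 350) / 40.0) ** 2)
        series = TitrationSeries(np.linspace(3, 6, 6),
                                 np.tile(row, (6, 1)), lam)
        with pytest.raises(SingularityError):
            fit_single_equilibrium(series)

    def test_transition_outside_window_unidentifiable(self):
        series, _ = gen_titration(
            [6.5], [[BandSpec(346., 60., 2.3e4)], [BandSpec(397., 60., 2.5e4)]],
            np.linspace(3.2, 5.6, 12), noise_sigma=0.002, seed=5)
        with pytest.raises(UnidentifiableError):
            fit_single_equilibrium(series)

    def test_invariance_to_permutation_and_scaling(self):
        series, _ = generate_preset("1b-abs", seed=11)
        ref = fit_single_equilibrium(series).pKa_estimates[0]
        rng = np.random.default_rng(0)
        perm = rng.permutation(series.axis.size)
        permuted = TitrationSeries(series.pH_values,
                                   series.response_matrix[:, perm],
                                   series.axis[perm],
                                   series.path_length, series.total_conc)
        scaled = TitrationSeries(series.pH_values,
                                 7.3 * series.response_matrix, series.axis,
                                 series.path_length, series.total_conc)
        assert fit_single_equilibrium(permuted).pKa_estimates[0] == \
            pytest.approx(ref, abs=1e-8)
        assert fit_single_equilibrium(scaled).pKa_estimates[0] == \
            pytest.approx(ref, abs=1e-8)

    def test_emission_requires_isosbestic_assertion(self):
        series, _ = generate_preset("1b-em", seed=0)
        with pytest.raises(DataError, match="isosbestic"):
            fit_single_equilibrium(series)
        fit = fit_single_equilibrium(series,
                                     assume_isosbestic_excitation=True)
        assert fit.pKa_estimates[0] == pytest.approx(4.51, abs=0.05)

    def test_bootstrap_se_available(self):
        series, _ = generate_preset("1b-abs", seed=3)
        fit = fit_single_equilibrium(series, n_bootstrap=50, rng=1)
        assert 0 < fit.pKa_se[0] < 0.1


class TestMultiEquilibriumFit:
    def test_noiseless_triprotic_recovery(self):
        series, truth = generate_preset("chromis1", seed=0, noise_sigma=0.0)
        fit = fit_multi_equilibrium(series, 3)
        assert fit.pKa_estimates == pytest.approx(truth["pKa"], abs=1e-4)

    def test_single_step_reduces_to_scalar_path(self, titration_1b_noiseless):
        series, _ = titration_1b_noiseless
        a = fit_single_equilibrium(series)
        b = fit_multi_equilibrium(series, 1)
        assert b.pKa_estimates[0] == a.pKa_estimates[0]

    def test_overlapping_steps_report_wide_errors(self):
        bands = [[BandSpec(340., 55., 2.3e4)], [BandSpec(370., 55., 2.4e4)],
                 [BandSpec(400., 55., 2.5e4)]]
        overlap, _ = gen_titration([4.6, 4.4], bands,
                                   np.linspace(2.5, 6.5, 14),
                                   noise_sigma=0.002, seed=2)
        separated, _ = gen_titration([5.5, 3.5], bands,
                                     np.linspace(1.5, 7.5, 14),
                                     noise_sigma=0.002, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # ordering warning is incidental
            fit_o = fit_multi_equilibrium(overlap, 2)
        fit_s = fit_multi_equilibrium(separated, 2)
        assert np.all(np.isfinite(fit_o.pKa_estimates))
        assert np.all(np.isfinite(fit_o.pKa_se))
        # nearly coincident steps are less well determined than separated ones
        assert fit_o.pKa_se.max() > fit_s.pKa_se.max()


class TestRankEstimate:
    def test_two_species_rank(self, titration_1b_noiseless):
        series, _ = titration_1b_noiseless
        assert rank_estimate(series) == 2

    def test_four_species_rank(self):
        series, _ = generate_preset("chromis1", seed=0, noise_sigma=0.0)
        assert rank_estimate(series) == 4

    def test_noise_does_not_inflate_structured_rank(self):
        series, _ = generate_preset("1b-abs", seed=4)
        assert rank_estimate(series) == 2
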