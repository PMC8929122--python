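"""Hill-model simulation and IC50 estimation."""

import numpy as np
import pytest

from pepfunnel import (
    DoseResponseDataset,
    HillModelParams,
    SimulationConfig,
    fit_ic50,
    inhibition_model,
    load_dose_response,
    potency_ratio,
    simulate_dataset,
)


class TestInhibitionModel:
    @pytest.mark.parametrize("h", [0.5, 1.0, 2.7])
    def test_fifty_percent_at_ic50(self, h):
        params = HillModelParams(ic50=57.7, hill_slope=h)
        assert inhibition_model(57.7, params) == pytest.approx(50.0)

    def test_zero_concentration(self):
        assert inhibition_model(0.0, HillModelParams(ic50=100.0)) == 0.0

    def test_three_times_ic50_slope_one(self):
        params = HillModelParams(ic50=100.0, hill_slope=1.0)
        assert inhibition_model(300.0, params) == pytest.approx(75.0)

    def test_strictly_increasing(self):
        params = HillModelParams(ic50=50.0, hill_slope=1.3)
        grid = np.logspace(-2, 4, 50)
        values = inhibition_model(grid, params)
        assert np.all(np.diff(values) > 0)

    @pytest.mark.parametrize("kwargs", [
        {"ic50": 0.0}, {"ic50": -5.0}, {"ic50": 10.0, "hill_slope": 0.0},
    ])
    def test_invalid_params(self, kwargs):
        with pytest.raises(ValueError):
            HillModelParams(**kwargs)


class TestSimulateDataset:
    def test_noise_free_equals_model(self):
        cfg = SimulationConfig(HillModelParams(ic50=57.7), noise_sd=0.0,
                               seed=3)
        data = simulate_dataset(cfg)
        expected = inhibition_model(cfg.grid(), cfg.true_params)
        assert np.allclose(data.inhibition, expected[:, None])

    def test_seed_reproducibility(self):
        cfg = SimulationConfig(HillModelParams(ic50=57.7), seed=11)
        a, b = simulate_dataset(cfg), simulate_dataset(cfg)
        assert np.array_equal(a.inhibition, b.inhibition)

    def test_noise_free_means_monotone(self):
        cfg = SimulationConfig(HillModelParams(ic50=57.7), noise_sd=0.0,
                               seed=0)
        assert np.all(np.diff(simulate_dataset(cfg).means) >= 0)

    def test_shape(self):
        cfg = SimulationConfig(HillModelParams(ic50=100.0), n_levels=8,
                               replicates=3, seed=1)
        assert simulate_dataset(cfg).inhibition.shape == (8, 3)


class TestFitIC50:
    def test_exact_recovery_noise_free(self):
        cfg = SimulationConfig(HillModelParams(ic50=100.0), noise_sd=0.0,
                               seed=0)
        fit = fit_ic50(simulate_dataset(cfg))
        assert fit.ic50_estimate == pytest.approx(100.0, rel=1e-6)
        assert fit.hill_estimate == pytest.approx(1.0, rel=1e-6)

    def test_interpolation_midpoint(self):
        data = DoseResponseDataset(
            concentrations=np.array([10.0, 1000.0]),
            inhibition=np.array([[25.0], [75.0]]),
        )
        fit = fit_ic50(data, method="interpolation")
        assert fit.ic50_estimate == pytest.approx(100.0)
        assert fit.method == "interpolation"

    def test_interpolation_requires_bracketing(self):
        data = DoseResponseDataset(
            concentrations=np.array([1.0, 10.0]),
            inhibition=np.array([[5.0], [20.0]]),
        )
        with pytest.raises(ValueError, match="bracket"):
            fit_ic50(data, method="interpolation")

    def test_interpolation_agrees_with_nls_on_clean_data(self):
        cfg = SimulationConfig(HillModelParams(ic50=57.7), noise_sd=0.0,
                               seed=0)
        data = simulate_dataset(cfg)
        nls = fit_ic50(data, method="nls").ic50_estimate
        interp = fit_ic50(data, method="interpolation").ic50_estimate
        assert interp == pytest.approx(nls, rel=0.10)

    def test_scale_equivariance(self):
        k = 7.5
        base = SimulationConfig(HillModelParams(ic50=40.0, hill_slope=1.4),
                                noise_sd=0.0, seed=0)
        scaled = SimulationConfig(
            HillModelParams(ic50=40.0 * k, hill_slope=1.4),
            c_min=base.c_min * k, c_max=base.c_max * k, noise_sd=0.0, seed=0)
        f1, f2 = (fit_ic50(simulate_dataset(c)) for c in (base, scaled))
        assert f2.ic50_estimate == pytest.approx(f1.ic50_estimate * k,
                                                 rel=1e-6)
        assert f2.hill_estimate == pytest.approx(f1.hill_estimate, rel=1e-6)

    def test_needs_four_levels(self):
        data = DoseResponseDataset(
            concentrations=np.array([1.0, 10.0, 100.0]),
            inhibition=np.array([[10.0], [50.0], [90.0]]),
        )
        with pytest.raises(ValueError, match="4 concentration levels"):
            fit_ic50(data)

    def test_extrapolation_flagged(self):
        cfg = SimulationConfig(HillModelParams(ic50=5000.0), noise_sd=0.0,
                               c_max=100.0, seed=0)
        fit = fit_ic50(simulate_dataset(cfg))
        assert fit.extrapolated


class TestPotencyRatio:
    def _fit_at(self, ic50, cmax=1000.0):
        cfg = SimulationConfig(HillModelParams(ic50=ic50), noise_sd=0.0,
                               c_max=cmax, seed=0)
        return fit_ic50(simulate_dataset(cfg))

    def test_printed_potency_quotients(self):
        sapi, sipr, fvph = (self._fit_at(v, cmax)
                            for v, cmax in ((57.7, 1000.0), (189.0, 1000.0),
                                            (480.6, 5000.0)))
        assert potency_ratio(sipr, sapi) == pytest.approx(3.28, abs=0.01)
        assert potency_ratio(fvph, sapi) == pytest.approx(8.33, abs=0.01)

    def test_identical_fits(self):
        fit = self._fit_at(100.0)
        assert potency_ratio(fit, fit) == 1.0


class TestDoseResponseIO:
    def test_round_trip(self, tmp_path):
        cfg = SimulationConfig(HillModelParams(ic50=57.7), seed=4)
        data = simulate_dataset(cfg, peptide_id="SAPI")
        path = tmp_path / "assay.csv"
        data.long_format().to_csv(path, index=False)
        back = load_dose_response(path)["SAPI"]
        assert np.allclose(back.concentrations, data.concentrations)
        assert np.allclose(np.sort(back.inhibition, axis=1),
                           np.sort(data.inhibition, axis=1))
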