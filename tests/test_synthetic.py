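import numpy as np
import pytest
from dataclasses import replace

from nircal import (ConfigurationError, ParameterError, default_config,
                    draw_concentrations, make_validation_fixture,
                    simulate_spectra)
from nircal.synthetic import AnalyteSpec, BandSpec, SyntheticConfig


def simple_config(n=1000, seed=0, **kw):
    a = AnalyteSpec("A", "u", 10.0, 2.0, -90.0, 110.0)   # clipping negligible
    b = AnalyteSpec("B", "u", 5.0, 1.0, -45.0, 55.0)
    corr = np.array([[1.0, 0.4], [0.4, 1.0]])
    base = dict(
        analytes=[a, b],
        correlation=corr,
        bands_per_analyte={
            "A": [BandSpec(2054, 16, 0.01)],
            "B": [BandSpec(1696, 12, 0.02)],
        },
        matrix_components={"water": [BandSpec(1920, 40, 0.4)]},
        n_samples=n,
        seed=seed,
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestDrawConcentrations:
    def test_seeded_determinism_bit_identical(self):
        cfg = default_config(seed=9, n_samples=50)
        a = draw_concentrations(cfg)
        b = draw_concentrations(default_config(seed=9, n_samples=50))
        np.testing.assert_array_equal(a.values, b.values)
        assert a.sample_ids == b.sample_ids

    def test_degenerate_variance_collapses_to_means(self):
        cfg = simple_config(n=20)
        cfg = replace(cfg, analytes=[
            AnalyteSpec("A", "u", 10.0, 1e-9, -90.0, 110.0),
            AnalyteSpec("B", "u", 5.0, 1e-9, -45.0, 55.0),
        ], correlation=np.eye(2))
        refs = draw_concentrations(cfg)
        np.testing.assert_allclose(refs.column("A"), 10.0, atol=1e-6)
        np.testing.assert_allclose(refs.column("B"), 5.0, atol=1e-6)

    def test_imposed_correlation_recovered_without_clipping(self):
        # wide ranges -> clipping never triggers; r converges to the target
        cfg = simple_config(n=50000, seed=3)
        cfg = replace(cfg, correlation=np.array([[1.0, 0.9], [0.9, 1.0]]))
        refs = draw_concentrations(cfg)
        r = np.corrcoef(refs.column("A"), refs.column("B"))[0, 1]
        assert abs(r - 0.9) <= 0.01

    def test_moment_recovery_at_large_n(self):
        cfg = simple_config(n=10000, seed=4)
        refs = draw_concentrations(cfg)
        for spec in cfg.analytes:
            x = refs.column(spec.name)
            assert x.mean() == pytest.approx(spec.mean, rel=0.02)
            assert np.std(x, ddof=1) == pytest.approx(spec.sd, rel=0.05)

    def test_values_respect_configured_ranges(self):
        refs = draw_concentrations(default_config(seed=6, n_samples=2000))
        cfg = default_config(seed=6, n_samples=2000)
        specs = {a.name: a for a in cfg.analytes}
        specs[cfg.sum_analyte.name] = cfg.sum_analyte
        for name in refs.names:
            x = refs.column(name)
            assert x.min() >= specs[name].low - 1e-12
            assert x.max() <= specs[name].high + 1e-12

    def test_total_is_sum_of_parts_plus_remainder(self):
        refs = draw_concentrations(default_config(seed=7, n_samples=500))
        rem = (refs.column("TGLs") - refs.column("GRA")
               - refs.column("GLSAT") - refs.column("GER"))
        # remainder ("other glucosinolates") is non-negative wherever the
        # total was not clipped at its range bounds
        assert np.quantile(rem, 0.05) > -1e-9

    def test_non_psd_correlation_raises(self):
        bad = np.array([[1.0, 0.95, -0.95], [0.95, 1.0, 0.95],
                        [-0.95, 0.95, 1.0]])  # wildly inconsistent triple
        with pytest.raises(ConfigurationError):
            a = AnalyteSpec("A", "u", 0, 1.0, -9, 9)
            c = SyntheticConfig(
                analytes=[replace(a, name="A"), replace(a, name="B"),
                          replace(a, name="C")],
                correlation=bad,
                bands_per_analyte={"A": [BandSpec(2054, 16, 1)],
                                   "B": [BandSpec(1696, 12, 1)],
                                   "C": [BandSpec(1450, 24, 1)]},
                n_samples=10,
            )
            draw_concentrations(c)

    def test_invalid_analyte_spec_raises(self):
        with pytest.raises(ConfigurationError):
            AnalyteSpec("A", "u", 5.0, 1.0, 10.0, 2.0)  # high <= low


class TestSimulateSpectra:
    def test_identical_concentrations_give_identical_spectra(self):
        cfg = simple_config(n=2, noise_sd=0.0)
        refs = draw_concentrations(cfg)
        refs.values[1] = refs.values[0]
        s = simulate_spectra(refs, cfg)
        np.testing.assert_array_equal(s.absorbance[0], s.absorbance[1])

    def test_spectrum_is_linear_in_concentration(self):
        cfg = simple_config(n=2, noise_sd=0.0, matrix_components={})
        refs = draw_concentrations(cfg)
        refs.values[:, :] = [[1.0, 0.0], [2.0, 0.0]]
        s = simulate_spectra(refs, cfg)
        np.testing.assert_allclose(s.absorbance[1], 2 * s.absorbance[0],
                                   atol=1e-12)

    def test_noise_free_rank_bounded_by_component_count(self):
        cfg = default_config(seed=8, n_samples=40, noise_sd=0.0,
                             scatter_sd=0.0, baseline_offset_sd=0.0,
                             baseline_slope_sd=0.0)
        refs = draw_concentrations(cfg)
        s = simulate_spectra(refs, cfg)
        # 5 spectrally active constituents + fixed matrix (rank 1 after
        # stacking constant rows)
        sv = np.linalg.svd(s.absorbance, compute_uv=False)
        n_active = len(cfg.analytes) + 1 + 1  # + remainder + matrix constant
        assert (sv > sv[0] * 1e-9).sum() <= n_active

    def test_missing_bands_raise(self):
        cfg = simple_config(n=5)
        cfg.bands_per_analyte = {"A": [BandSpec(2054, 16, 0.01)]}  # B missing
        refs = draw_concentrations(cfg)
        with pytest.raises(ConfigurationError, match="'B'"):
            simulate_spectra(refs, cfg)

    def test_seeded_determinism_of_spectra(self):
        cfg = default_config(seed=10, n_samples=20)
        refs = draw_concentrations(cfg)
        a = simulate_spectra(refs, cfg).absorbance
        b = simulate_spectra(refs, cfg).absorbance
        np.testing.assert_array_equal(a, b)

    def test_stage_streams_are_independent_of_each_other(self):
        # regenerating spectra after redrawing concentrations at the same
        # seed gives identical artefact noise (per-stage counter streams)
        cfg = simple_config(n=10, noise_sd=0.01)
        refs = draw_concentrations(cfg)
        s1 = simulate_spectra(refs, cfg)
        draw_concentrations(cfg)  # consuming the concentration stream again
        s2 = simulate_spectra(refs, cfg)
        np.testing.assert_array_equal(s1.absorbance, s2.absorbance)


class TestSnvDtRationale:
    def test_snv_dt_restores_scatter_corrupted_calibration(self, rocket_world):
        # calibrating on scatter-corrupted spectra with SNV-DT comes within
        # 15% of the clean-spectra SECV; without SNV-DT it is worse than with
        from nircal import MathTreatment, cross_validate
        cfg, refs, corrupt = rocket_world
        clean_cfg = replace(cfg, scatter_sd=0.0, baseline_offset_sd=0.0,
                            baseline_slope_sd=0.0)
        clean = simulate_spectra(refs, clean_cfg)
        y = refs.column("GRA")
        t_corr = MathTreatment(2, 5, 5, 2, "snv-dt")
        t_raw = MathTreatment(2, 5, 5, 2, "none")
        secv_clean = cross_validate(clean, y, t_corr, 4, 12).SECV
        secv_snvdt = cross_validate(corrupt, y, t_corr, 4, 12).SECV
        secv_none = cross_validate(corrupt, y, t_raw, 4, 12).SECV
        assert secv_snvdt <= 1.15 * secv_clean
        assert secv_snvdt <= secv_none


class TestValidationFixture:
    def test_prescribed_moments_are_exact(self):
        y, yhat = make_validation_fixture(30, target_sd=7.63, target_sep=4.80,
                                          target_bias=0.25, mean=23.56)
        e = yhat - y
        assert np.std(y, ddof=1) == pytest.approx(7.63, abs=1e-12)
        assert y.mean() == pytest.approx(23.56, abs=1e-12)
        assert e.mean() == pytest.approx(0.25, abs=1e-12)
        assert np.std(e, ddof=1) == pytest.approx(4.80, abs=1e-12)

    def test_range_target_is_exact(self):
        y, _ = make_validation_fixture(30, target_range=(5.80, 11.80),
                                       target_sep=0.48)
        assert y.min() == pytest.approx(5.80, abs=1e-12)
        assert y.max() == pytest.approx(11.80, abs=1e-12)

    def test_construction_is_deterministic(self):
        a = make_validation_fixture(30, target_sd=1.0, target_sep=0.5)
        b = make_validation_fixture(30, target_sd=1.0, target_sep=0.5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    @pytest.mark.parametrize("kwargs", [
        dict(target_sd=1.0),                       # n too small below
        dict(target_sd=-1.0, target_sep=0.5),
        dict(target_sep=0.5),                      # neither sd nor range
    ])
    def test_invalid_parameters_raise(self, kwargs):
        n = 2 if "target_sd" in kwargs and kwargs.get("target_sd") == 1.0 else 30
        with pytest.raises(ParameterError):
            make_validation_fixture(n, **kwargs)
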