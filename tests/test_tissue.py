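"""Glucose pools, compartment mixing, Rician noise, offset resampling."""

import numpy as np
import pytest

from dsdge import tissue as ts
from dsdge.bm_core import ValidationError, ZSpectrum
from dsdge.lineshape import fit_lorentzian, lorentzian_model


class TestGlucosePools:
    def test_zero_concentration_empty_pools(self, table):
        pools = ts.glucose_pools(0.0, config=table.hydroxyl)
        assert [p.proton_fraction for p in pools] == [0.0] * 4

    def test_proton_fraction_arithmetic(self, table):
        # 3 protons at 1.28 ppm: 3 * 5.55 mM / 111,000 mM = 1.5e-4
        pools = ts.glucose_pools(5.55, config=table.hydroxyl)
        by_shift = {p.chemical_shift_ppm: p for p in pools}
        assert by_shift[1.28].proton_fraction == pytest.approx(1.5e-4)
        assert by_shift[0.66].proton_fraction == pytest.approx(0.5e-4)
        assert by_shift[2.08].proton_fraction == pytest.approx(0.36 * 0.5e-4)
        assert by_shift[2.88].proton_fraction == pytest.approx(0.64 * 0.5e-4)

    def test_acidic_regime_slows_every_pool(self, table):
        normal = ts.glucose_pools(5.0, "normal", table.hydroxyl)
        acidic = ts.glucose_pools(5.0, "tumor_acidic", table.hydroxyl)
        for n, a in zip(normal, acidic):
            assert a.exchange_rate_hz < n.exchange_rate_hz

    def test_negative_concentration_rejected(self, table):
        with pytest.raises(ValidationError):
            ts.glucose_pools(-1.0, config=table.hydroxyl)


class TestCompartmentSpectra:
    def test_csf_much_narrower_than_venous_blood(self, table, train, protocol):
        csf = ts.compartment_zspectrum(table.compartments["EES_CSF"],
                                       ts.NORMOGLYCEMIA, train, protocol,
                                       table.hydroxyl)
        ven = ts.compartment_zspectrum(table.compartments["venous"],
                                       ts.NORMOGLYCEMIA, train, protocol,
                                       table.hydroxyl)
        lw_csf = fit_lorentzian(ts.resample_offsets(csf)).fwhm_hz
        lw_ven = fit_lorentzian(ts.resample_offsets(ven)).fwhm_hz
        assert lw_csf < 0.3 * lw_ven

    def test_hyperglycemia_broadens_noiseless_spectrum(self, table, train,
                                                       protocol):
        comp = table.compartments["EES_TUMOR"]
        ngl = ts.compartment_zspectrum(comp, ts.NORMOGLYCEMIA, train, protocol,
                                       table.hydroxyl)
        hgl = ts.compartment_zspectrum(comp, ts.HYPERGLYCEMIA, train, protocol,
                                       table.hydroxyl)
        # at the fully saturated line centre, extra exchange back-feeds a
        # few 1e-5 of Mz from the unsaturated hydroxyl pools; off-centre the
        # hyperglycemic spectrum is strictly more saturated
        near = (np.abs(ngl.offsets_ppm) <= 2.5) & (np.abs(ngl.offsets_ppm) > 0.1)
        assert np.all(hgl.intensities[near] <= ngl.intensities[near] + 1e-9)
        assert np.all(hgl.intensities <= ngl.intensities + 1e-3)

    def test_without_glucose_states_identical(self, table, train, protocol):
        comp = table.compartments["EES_GM"]
        comp0 = comp.with_concentration(
            ts.NORMOGLYCEMIA, 0.0).with_concentration(ts.HYPERGLYCEMIA, 0.0)
        a = ts.compartment_zspectrum(comp0, ts.NORMOGLYCEMIA, train, protocol,
                                     table.hydroxyl)
        b = ts.compartment_zspectrum(comp0, ts.HYPERGLYCEMIA, train, protocol,
                                     table.hydroxyl)
        assert np.array_equal(a.intensities, b.intensities)


class TestMixing:
    def _const(self, offsets, value):
        return ZSpectrum(offsets, np.full(len(offsets), value))

    def test_pure_ees_tissue_returns_ees_spectrum(self, table, train, protocol):
        csf = table.tissue("CSF")
        ees = ts.compartment_zspectrum(csf.EES, ts.NORMOGLYCEMIA, train,
                                       protocol, table.hydroxyl)
        mixed = ts.mix_tissue_zspectrum(csf, {"EES": ees})
        assert np.allclose(mixed.intensities, ees.intensities)

    def test_identical_components_pass_through(self, table):
        gm = table.tissue("GM")
        offsets = np.linspace(-5, 5, 11)
        spectra = {k: self._const(offsets, 0.8) for k in gm.compartments()}
        mixed = ts.mix_tissue_zspectrum(gm, spectra)
        # weights-with-densities cancel up to the rho_tis bookkeeping
        expected = 0.8 * (
            gm.blood_fraction * 0.856 + gm.EES_fraction * 0.938
            + gm.cell_fraction * 0.809
        ) / gm.tissue_water_density
        assert np.allclose(mixed.intensities, expected)
        assert expected == pytest.approx(0.8, rel=0.01)

    def test_gm_weighted_sum_hand_computed(self, table):
        gm = table.tissue("GM")
        offsets = np.linspace(-5, 5, 11)
        spectra = {
            "arterial": self._const(offsets, 1.0),
            "venous": self._const(offsets, 0.5),
            "EES": self._const(offsets, 0.8),
            "cell": self._const(offsets, 0.2),
        }
        mixed = ts.mix_tissue_zspectrum(gm, spectra)
        expected = (
            0.038 * 0.856 * (0.3 * 1.0 + 0.7 * 0.5)
            + 0.22 * 0.938 * 0.8
            + 0.742 * 0.809 * 0.2
        ) / 0.839
        assert np.allclose(mixed.intensities, expected)

    def test_offset_grid_mismatch_rejected(self, table):
        csf = table.tissue("CSF")
        ees = self._const(np.linspace(-5, 5, 11), 0.9)
        ees_bad = self._const(np.linspace(-4, 4, 11), 0.9)
        ts.mix_tissue_zspectrum(csf, {"EES": ees})
        with pytest.raises(ValidationError):
            ts.mix_tissue_zspectrum(
                table.tissue("GM"),
                {"arterial": ees, "venous": ees_bad, "EES": ees, "cell": ees},
            )

    def test_mixture_bounded_by_components(self, table, train, protocol):
        gm = table.tissue("GM")
        spectra = {
            k: ts.compartment_zspectrum(c, ts.NORMOGLYCEMIA, train, protocol,
                                        table.hydroxyl)
            for k, c in gm.compartments().items()
        }
        mixed = ts.mix_tissue_zspectrum(gm, spectra)
        stack = np.stack([s.intensities for s in spectra.values()])
        # allow the ~0.2% rho_tis bookkeeping slack
        assert np.all(mixed.intensities >= stack.min(axis=0) - 0.005)
        assert np.all(mixed.intensities <= stack.max(axis=0) + 0.005)


class TestRicianNoise:
    def test_zero_sigma_is_identity(self):
        spec = ZSpectrum(np.linspace(-5, 5, 9), np.linspace(0.2, 1.0, 9))
        out = ts.add_rician_noise(spec, 0.0, rng=1)
        assert np.array_equal(out.intensities, spec.intensities)

    def test_seeded_reproducibility(self):
        spec = ZSpectrum(np.linspace(-5, 5, 9), np.full(9, 0.7))
        a = ts.add_rician_noise(spec, 0.02, rng=42)
        b = ts.add_rician_noise(spec, 0.02, rng=42)
        assert np.array_equal(a.intensities, b.intensities)

    def test_positive_bias_matches_monte_carlo(self, rng):
        """Rician magnitude noise on S=1 is positively biased."""
        n = 100_000
        spec = ZSpectrum(np.zeros(n), np.ones(n))
        noisy = ts.add_rician_noise(spec, 0.02, rng=rng)
        # independent Monte-Carlo of the same magnitude construction
        rng2 = np.random.default_rng(5)
        mc = np.sqrt((1 + rng2.normal(0, 0.02, n)) ** 2
                     + rng2.normal(0, 0.02, n) ** 2)
        assert noisy.intensities.mean() > 1.0
        assert noisy.intensities.mean() == pytest.approx(mc.mean(), abs=3e-4)


class TestResampling:
    def test_identity_on_same_grid(self):
        offsets = np.linspace(-5, 5, 15)
        spec = ZSpectrum(offsets, np.cos(offsets / 5))
        out = ts.resample_offsets(spec, offsets)
        assert np.allclose(out.intensities, spec.intensities)

    def test_lorentzian_interpolation_accuracy(self):
        source = np.asarray(ts.OFFSETS_41PT)
        z = lorentzian_model(source, 0.8, 0.0, 0.5, 1.0)
        spec = ZSpectrum(source, z)
        out = ts.resample_offsets(spec)
        expected = lorentzian_model(out.offsets_ppm, 0.8, 0.0, 0.5, 1.0)
        assert np.allclose(out.intensities, expected, atol=1e-3)

    def test_default_target_is_28_points_within_5ppm(self):
        spec = ZSpectrum(np.asarray(ts.OFFSETS_41PT),
                         np.ones(len(ts.OFFSETS_41PT)))
        out = ts.resample_offsets(spec)
        assert out.offsets_ppm.size == 28
        assert np.max(np.abs(out.offsets_ppm)) == 5.0

    def test_extrapolation_rejected(self):
        spec = ZSpectrum(np.linspace(-5, 5, 11), np.ones(11))
        with pytest.raises(ValidationError):
            ts.resample_offsets(spec, [0.0, 6.0])


class TestShippedTable:
    def test_volume_fraction_constraints(self, table):
        for tis in table.tissues.values():
            assert tis.blood_fraction + tis.EES_fraction + tis.cell_fraction \
                == pytest.approx(1.0, abs=1e-9)
            assert tis.arterial_subfraction + tis.venous_subfraction \
                == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("name", ["GM", "WM", "TUMOR"])
    def test_water_density_consistency(self, table, name):
        tis = table.tissue(name)
        total = (tis.blood_fraction * 0.856
                 + tis.EES_fraction * tis.EES.water_density
                 + tis.cell_fraction * tis.cell.water_density)
        assert total == pytest.approx(tis.tissue_water_density, abs=0.01)

    def test_hyperglycemia_never_narrows_any_tissue(self, table, train,
                                                    protocol):
        """Exchange broadening direction on noiseless full-depth spectra."""
        cache = {}
        for name in ("arterial", "venous", "CSF"):
            lw = {}
            for state in (ts.NORMOGLYCEMIA, ts.HYPERGLYCEMIA):
                spec = ts.tissue_zspectrum(table.tissue(name), state, train,
                                           protocol, table.hydroxyl,
                                           _cache=cache)
                lw[state] = fit_lorentzian(ts.resample_offsets(spec)).fwhm_hz
            assert lw[ts.HYPERGLYCEMIA] >= lw[ts.NORMOGLYCEMIA]

    def test_overrides_merge_by_key(self):
        t = ts.load_tissue_table(
            {"compartments": {"EES_CSF": {"T2_s": 2.0}}})
        assert t.compartments["EES_CSF"].T2_water_s == 2.0
        assert t.compartments["EES_CSF"].T1_water_s == 3.48
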