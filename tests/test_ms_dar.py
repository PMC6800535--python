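import numpy as np
import pytest

from adcdar.errors import ConfigurationError, NoPeakError, SpectrumParseError
from adcdar.ms_dar import (
    PROTON_MASS_DA,
    MassSpectrum,
    PipelineConfig,
    baseline_subtract,
    dar_from_mass,
    dar_from_spectrum,
    load_spectrum,
    main_peak_centroid,
    neutral_mass,
    smooth,
)
from adcdar.synthetic_data import InstrumentModel, LoadDistribution, gen_maldi_spectrum

MZ_RANGE = (138_000.0, 165_000.0)


def _gaussian_spectrum(center=148_000.0, sigma=200.0, amp=1000.0,
                       offset=0.0, lo=140_000.0, hi=156_000.0, step=2.0):
    mz = np.arange(lo, hi, step)
    intensity = amp * np.exp(-((mz - center) ** 2) / (2 * sigma**2)) + offset
    return MassSpectrum(mz, intensity)


class TestLoadSpectrum:
    def test_tsv(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("".join(f"{100 + i}\t{i + 1}\n" for i in range(12)))
        s = load_spectrum(path)
        assert len(s.mz) == 12
        assert s.mz[0] == 100.0 and s.intensity[-1] == 12.0

    def test_too_few_points(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("100\t1\n200\t2\n300\t3\n")
        with pytest.raises(SpectrumParseError, match="3 points"):
            load_spectrum(path)

    def test_unsorted_input_sorted_and_merged(self, tmp_path):
        lines = [f"{mz}\t1\n" for mz in (110, 105, 120, 105, 130, 101,
                                         140, 150, 160, 170, 180)]
        path = tmp_path / "s.tsv"
        path.write_text("".join(lines))
        s = load_spectrum(path)
        assert np.all(np.diff(s.mz) > 0)
        # the duplicated 105 merges, summing intensities
        assert s.intensity[list(s.mz).index(105.0)] == 2.0
        assert s.intensity.sum() == 11.0

    def test_malformed_line_number(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("100\t1\n200\toops\n")
        with pytest.raises(SpectrumParseError, match="line 2"):
            load_spectrum(path)

    def test_unsupported_format(self, tmp_path):
        with pytest.raises(SpectrumParseError):
            load_spectrum(tmp_path / "s.xyz", format="xyz")

    def test_mzml_matches_tsv_twin(self, smcc_design, tmp_path):
        load = LoadDistribution("poisson", 2.0, 8)
        s = gen_maldi_spectrum(smcc_design, load, InstrumentModel(), MZ_RANGE, 1)
        s.write_tsv(tmp_path / "s.tsv")
        s.write_mzml(tmp_path / "s.mzml")
        tsv = load_spectrum(tmp_path / "s.tsv")
        mzml = load_spectrum(tmp_path / "s.mzml")
        np.testing.assert_allclose(mzml.mz, tsv.mz, rtol=1e-6)
        np.testing.assert_allclose(mzml.intensity, tsv.intensity, rtol=1e-6,
                                   atol=1e-9)


class TestBaseline:
    def test_flat_baseline_removed(self):
        mz = np.arange(100_000.0, 120_000.0, 2.0)
        s = MassSpectrum(mz, np.full_like(mz, 37.0))
        out = baseline_subtract(s, 2_000.0)
        assert np.allclose(out.intensity, 0.0)

    def test_gaussian_plus_offset(self):
        s = _gaussian_spectrum(offset=50.0)
        out = baseline_subtract(s, 10_000.0)
        apex = out.intensity.max()
        # residual floor far from the peak stays under 1% of peak height
        far = np.abs(out.mz - 148_000.0) > 5_000.0
        assert np.max(out.intensity[far]) < 0.01 * apex
        assert apex == pytest.approx(1000.0, rel=0.01)

    def test_baseline_free_unchanged(self):
        s = _gaussian_spectrum()
        out = baseline_subtract(s, 10_000.0)
        np.testing.assert_allclose(out.intensity, s.intensity, atol=1e-6)

    def test_window_exceeding_span(self):
        s = _gaussian_spectrum(lo=147_000.0, hi=149_000.0)
        with pytest.raises(ConfigurationError):
            baseline_subtract(s, 5_000.0)


class TestSmooth:
    def test_polynomial_reproduced_exactly(self):
        mz = np.arange(1000.0, 2000.0, 1.0)
        poly = 3.0 + 0.5 * mz + 2e-4 * mz**2
        s = MassSpectrum(mz, poly)
        out = smooth(s, 21, poly_order=2)
        np.testing.assert_allclose(out.intensity, poly, rtol=1e-9)

    def test_noise_variance_reduced(self, rng):
        mz = np.arange(0.0, 5000.0) + 1.0
        noise = rng.normal(0.0, 1.0, size=mz.shape)
        s = MassSpectrum(mz, noise)
        out = smooth(s, 21, poly_order=0)
        assert np.var(noise) / np.var(out.intensity) >= 5.0

    def test_window_one_is_identity(self):
        s = _gaussian_spectrum()
        out = smooth(s, 1)
        np.testing.assert_array_equal(out.intensity, s.intensity)

    def test_even_window_rejected(self):
        s = _gaussian_spectrum()
        with pytest.raises(ConfigurationError):
            smooth(s, 20)


class TestCentroid:
    def test_single_gaussian(self):
        s = _gaussian_spectrum(center=148_000.0)
        assert main_peak_centroid(s, 0.10) == pytest.approx(148_000.0, rel=1e-4)

    def test_overlapping_mixture_weighted_mean(self):
        mz = np.arange(140_000.0, 156_000.0, 2.0)
        w, c1, c2, sigma = 0.3, 147_800.0, 148_200.0, 500.0
        intensity = w * np.exp(-((mz - c1) ** 2) / (2 * sigma**2)) + (
            1 - w
        ) * np.exp(-((mz - c2) ** 2) / (2 * sigma**2))
        s = MassSpectrum(mz, intensity)
        expected = w * c1 + (1 - w) * c2
        assert main_peak_centroid(s, 0.01) == pytest.approx(expected, rel=5e-4)

    def test_high_threshold_hits_apex(self):
        s = _gaussian_spectrum(center=148_000.0, step=2.0)
        apex_mz = s.mz[np.argmax(s.intensity)]
        assert abs(main_peak_centroid(s, 0.99) - apex_mz) <= 2.0

    def test_all_zero_spectrum(self):
        mz = np.arange(0.0, 100.0) + 1.0
        with pytest.raises(NoPeakError):
            main_peak_centroid(MassSpectrum(mz, np.zeros_like(mz)), 0.1)

    def test_invariant_under_intensity_scaling(self):
        s = _gaussian_spectrum()
        scaled = MassSpectrum(s.mz, s.intensity * 7.3)
        assert main_peak_centroid(scaled, 0.1) == main_peak_centroid(s, 0.1)


class TestNeutralMass:
    def test_single_charge(self):
        assert neutral_mass(147_837.9, 1) == pytest.approx(147_836.89, abs=0.01)

    def test_charge_consistency(self):
        m1 = neutral_mass(147_837.9, 1)
        mz2 = (m1 + 2 * PROTON_MASS_DA) / 2
        assert neutral_mass(mz2, 2) == pytest.approx(m1, abs=1e-9)

    def test_zero_proton_identity(self):
        assert neutral_mass(1234.5, 1, proton_mass_Da=0.0) == 1234.5


class TestDarFromMass:
    def test_kadcyla_row(self):
        res = dar_from_mass(150_832.2, 147_836.9, 957.4)
        assert res.mass_shift_display == 2995.3
        assert res.dar_display == 3.1

    def test_tspd12_row(self):
        res = dar_from_mass(149_148.6, 147_836.9, 1_488.7)
        assert res.mass_shift_display == 1311.7
        assert res.dar_display == 0.9

    def test_zero_shift(self):
        res = dar_from_mass(147_836.9, 147_836.9, 957.4)
        assert res.dar == 0.0

    def test_linearity_in_conjugate_mass(self):
        delta, pdm = 1234.5, 957.4
        a = dar_from_mass(150_000.0, 147_836.9, pdm).dar
        b = dar_from_mass(150_000.0 + delta, 147_836.9, pdm).dar
        assert b - a == pytest.approx(delta / pdm, rel=1e-12)

    def test_nonpositive_per_drug_mass(self):
        with pytest.raises(ConfigurationError):
            dar_from_mass(150_000.0, 147_836.9, 0.0)


class TestDarFromSpectrum:
    def _pair(self, design, load, noise_frac=0.0, seed=42):
        clean = gen_maldi_spectrum(design, load, InstrumentModel(), MZ_RANGE, 0)
        inst = InstrumentModel(noise_sd=noise_frac * clean.intensity.max())
        conj = gen_maldi_spectrum(design, load, inst, MZ_RANGE, seed)
        ref = gen_maldi_spectrum(
            design, LoadDistribution("fixed", 0, 0), inst, MZ_RANGE, seed + 1
        )
        return conj, ref

    def test_noisy_poisson_recovery(self, smcc_design):
        load = LoadDistribution("poisson", 3.5, 8)
        conj, ref = self._pair(smcc_design, load, noise_frac=0.01)
        res = dar_from_spectrum(conj, ref, smcc_design)
        assert res.dar == pytest.approx(load.truncated_mean(), abs=0.15)

    def test_fixed_load_two(self, smcc_design):
        load = LoadDistribution("fixed", 2, 8)
        conj, ref = self._pair(smcc_design, load)
        res = dar_from_spectrum(conj, ref, smcc_design)
        assert res.dar == pytest.approx(2.00, abs=0.05)

    def test_identical_spectra_give_zero(self, smcc_design):
        load = LoadDistribution("poisson", 3.5, 8)
        conj, _ = self._pair(smcc_design, load)
        res = dar_from_spectrum(conj, conj, smcc_design)
        assert res.dar == pytest.approx(0.0, abs=0.02)

    @pytest.mark.parametrize("lam", [1.0, 2.0, 3.5, 6.0])
    def test_noiseless_recovery_within_two_percent(self, smcc_design, lam):
        load = LoadDistribution("poisson", lam, 8)
        conj, ref = self._pair(smcc_design, load)
        res = dar_from_spectrum(conj, ref, smcc_design)
        true = load.truncated_mean()
        assert abs(res.dar - true) / true < 0.02

    def test_reference_as_number(self, smcc_design):
        load = LoadDistribution("fixed", 3, 8)
        conj, _ = self._pair(smcc_design, load)
        ref_mass = smcc_design.antibody.mw_measured_Da
        res = dar_from_spectrum(conj, ref_mass, smcc_design)
        assert res.dar == pytest.approx(3.0, abs=0.05)

    def test_needs_design_or_mass(self, smcc_design):
        load = LoadDistribution("fixed", 1, 8)
        conj, ref = self._pair(smcc_design, load)
        with pytest.raises(ConfigurationError):
            dar_from_spectrum(conj, ref)


class TestMassSpectrumValidation:
    def test_mz_strictly_increasing(self):
        with pytest.raises(ConfigurationError):
            MassSpectrum(np.array([1.0, 1.0, 2.0]), np.ones(3))

    def test_finite_intensities(self):
        with pytest.raises(ConfigurationError):
            MassSpectrum(np.array([1.0, 2.0, 3.0]), np.array([1.0, np.nan, 2.0]))
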