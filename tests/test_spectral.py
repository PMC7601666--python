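"""PSD estimation, unit-bin integration and band contrasts vs direct oracles."""

import numpy as np
import pandas as pd
import pytest

from comareact import spectral
from comareact.io_formats import EpochSet
from comareact.montage import ELECTRODES
from comareact.spectral import PERIODOGRAM, WindowSpec

RATE = 250.0


def dft_periodogram(x, rate):
    """Independent one-sided PSD oracle: direct DFT, rectangular window."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    X = np.fft.rfft(x, axis=-1)
    psd = (np.abs(X) ** 2) / (rate * n)
    psd[..., 1:] *= 2.0
    if n % 2 == 0:
        psd[..., -1] /= 2.0
    return np.fft.rfftfreq(n, 1.0 / rate), psd


class TestComputePsd:
    def test_zero_epoch_gives_zero_spectrum(self):
        _, psd = spectral.compute_psd(np.zeros((3, 2500)), RATE)
        assert np.all(psd == 0)

    def test_matches_direct_dft_periodogram(self, rng):
        x = rng.normal(size=(4, 2500))
        f1, p1 = spectral.compute_psd(x, RATE, PERIODOGRAM)
        f2, p2 = dft_periodogram(x, RATE)
        np.testing.assert_allclose(f1, f2)
        np.testing.assert_allclose(p1, p2, rtol=1e-9)

    def test_parseval_total_power_equals_variance(self, rng):
        x = rng.normal(size=(2, 2500))
        f, psd = spectral.compute_psd(x, RATE, PERIODOGRAM)
        total = psd.sum(axis=-1) * (f[1] - f[0])
        mean_square = (x ** 2).mean(axis=-1)
        np.testing.assert_allclose(total, mean_square, rtol=0.01)

    def test_pure_tone_power_is_localized(self):
        t = np.arange(2500) / RATE
        x = np.sin(2 * np.pi * 10.0 * t)[None, :]
        f, psd = spectral.compute_psd(x, RATE, PERIODOGRAM)
        in_range = (f >= 2) & (f < 20)
        near = (f >= 9.5) & (f <= 10.5)
        assert psd[0, near].sum() / psd[0, in_range].sum() >= 0.95

    def test_rejects_nan_and_short_epochs(self):
        with pytest.raises(ValueError, match="NaN"):
            spectral.compute_psd(np.full((1, 2500), np.nan), RATE)
        with pytest.raises(ValueError, match="2 s"):
            spectral.compute_psd(np.zeros((1, 100)), RATE)
        with pytest.raises(ValueError, match="shorter"):
            spectral.compute_psd(np.zeros((1, 625)), RATE,
                                 WindowSpec(segment_seconds=4.0))


class TestNormalizeAndBins:
    def test_normalized_bins_sum_to_one(self, rng):
        x = rng.normal(size=(3, 2500))
        f, psd = spectral.compute_psd(x, RATE)
        bins = spectral.integrate_bins(f, spectral.normalize_spectrum(f, psd))
        np.testing.assert_allclose(bins.sum(axis=-1), 1.0, rtol=1e-12)

    def test_scale_invariance_of_relative_power(self, rng):
        x = rng.normal(size=(2, 2500))
        f, psd1 = spectral.compute_psd(x, RATE)
        _, psd2 = spectral.compute_psd(10.0 * x, RATE)
        n1 = spectral.normalize_spectrum(f, psd1)
        n2 = spectral.normalize_spectrum(f, psd2)
        np.testing.assert_allclose(n1, n2, rtol=1e-12)

    def test_passthrough_mode_is_identity(self, rng):
        x = rng.normal(size=(2, 2500))
        f, psd = spectral.compute_psd(x, RATE)
        assert spectral.normalize_spectrum(f, psd, mode="none") is psd

    def test_zero_power_is_an_error(self):
        f = np.linspace(0, 125, 1251)
        with pytest.raises(ValueError, match="degenerate"):
            spectral.normalize_spectrum(f, np.zeros((1, 1251)))

    def test_point_mass_lands_in_its_bin(self):
        f = np.arange(0, 125.5, 0.5)
        psd = np.zeros((1, len(f)))
        psd[0, np.argmin(np.abs(f - 4.5))] = 7.0
        bins = spectral.integrate_bins(f, psd)
        assert bins[0, 2] > 0  # bin [4,5)
        assert bins[0].sum() == pytest.approx(bins[0, 2])

    def test_uniform_density_gives_equal_bins(self):
        f = np.arange(0, 125.5, 0.5)
        c = 3.7
        bins = spectral.integrate_bins(f, np.full((1, len(f)), c))
        np.testing.assert_allclose(bins, c, rtol=1e-12)

    def test_bin_sum_equals_direct_quadrature(self, rng):
        x = rng.normal(size=(2, 2500))
        f, psd = spectral.compute_psd(x, RATE)
        bins = spectral.integrate_bins(f, psd)
        direct = spectral._integral(f, psd, 2.0, 20.0)
        np.testing.assert_allclose(bins.sum(axis=-1), direct, rtol=1e-9)

    def test_coarse_grid_rejected(self):
        f = np.arange(0, 126, 2.0)
        with pytest.raises(ValueError, match="coarser"):
            spectral.integrate_bins(f, np.ones((1, len(f))))

    @pytest.mark.parametrize("f0", [4.5, 10.5, 17.5])
    def test_half_integer_tone_localizes_to_its_unit_bin(self, f0):
        t = np.arange(2500) / RATE
        x = np.sin(2 * np.pi * f0 * t)[None, :]
        f, psd = spectral.compute_psd(x, RATE, PERIODOGRAM)
        bins = spectral.integrate_bins(f, spectral.normalize_spectrum(f, psd))
        assert bins[0, int(f0 - 2.0)] >= 0.90
        # Welch's Hann taper spreads the mainlobe into adjacent bins but
        # the target bin still dominates
        f2, psd2 = spectral.compute_psd(x, RATE)
        bins2 = spectral.integrate_bins(
            f2, spectral.normalize_spectrum(f2, psd2))
        assert bins2[0, int(f0 - 2.0)] >= 0.75
        assert bins2[0, int(f0 - 2.0)] == bins2[0].max()


class TestBandPower:
    def test_theta_is_mean_of_bins_4_5_and_5_6(self, rng):
        bins = rng.uniform(size=(2, 18))
        expected = (bins[:, 2] + bins[:, 3]) / 2
        np.testing.assert_allclose(
            spectral.band_power(bins, (4.0, 6.0)), expected)

    def test_single_bin_band_is_that_bin(self, rng):
        bins = rng.uniform(size=18)
        assert spectral.band_power(bins, (7.0, 8.0)) == bins[5]

    def test_beta_matches_brute_force_mean(self, rng):
        bins = rng.uniform(size=18)
        brute = np.mean([bins[15], bins[16], bins[17]])
        assert spectral.band_power(bins, (17.0, 20.0)) == pytest.approx(brute)

    def test_band_outside_range_or_misaligned_rejected(self):
        bins = np.ones(18)
        with pytest.raises(ValueError, match="outside"):
            spectral.band_power(bins, (18.0, 22.0))
        with pytest.raises(ValueError, match="integer"):
            spectral.band_power(bins, (4.5, 6.0))


def _epoch_set(rng, n_per_condition, n_samp=2500, repeat_epoch=False):
    epochs = {}
    for cond, n in n_per_condition.items():
        if repeat_epoch:
            one = rng.normal(size=(1, 19, n_samp))
            epochs[cond] = np.repeat(one, n, axis=0)
        else:
            epochs[cond] = rng.normal(size=(n, 19, n_samp))
    return EpochSet("S1", "patient", ELECTRODES, RATE, epochs)


class TestConditionTable:
    def test_identical_epochs_equal_single_epoch_value(self, rng):
        es10 = _epoch_set(rng, {"rest": 10}, repeat_epoch=True)
        es1 = EpochSet("S1", "patient", ELECTRODES, RATE,
                       {"rest": es10.epochs["rest"][:1]})
        t10 = spectral.condition_table([es10])
        t1 = spectral.condition_table([es1])
        np.testing.assert_allclose(t10["power"], t1["power"], rtol=1e-12)

    def test_valence_pair_merge_covers_200_seconds(self, rng):
        es = _epoch_set(rng, {"rest": 4, "slow_soft": 10, "fast_soft": 10,
                              "slow_hard": 10, "fast_hard": 10})
        merged = spectral.merged_conditions("valence-pairs")
        seconds = sum(es.epochs[c].shape[0] for c in merged["pleasant"]) * 10.0
        assert seconds == 200.0
        table = spectral.condition_table([es], merge_rule="valence-pairs")
        assert set(table["condition"]) == {"rest", "pleasant", "unpleasant"}

    def test_matches_brute_force_epoch_loop(self, rng):
        es = _epoch_set(rng, {"rest": 3, "slow_soft": 2})
        table = spectral.condition_table([es])
        # independent recomputation: loop epochs, average raw spectra,
        # then normalize, bin and band-average
        for cond in ("rest", "slow_soft"):
            stack = es.epochs[cond]
            psds = []
            for e in range(stack.shape[0]):
                f, p = spectral.compute_psd(stack[e], RATE)
                psds.append(p)
            mean_psd = np.mean(psds, axis=0)
            bins = spectral.integrate_bins(
                f, spectral.normalize_spectrum(f, mean_psd))
            theta = spectral.band_power(bins, (4.0, 6.0))
            got = table[(table.condition == cond) & (table.band == "theta")]
            np.testing.assert_allclose(
                got.set_index("electrode")["power"][list(ELECTRODES)],
                theta, rtol=1e-10)


class TestContrast:
    def test_identical_conditions_give_zero_contrast(self, rng):
        es = _epoch_set(rng, {"rest": 3}, repeat_epoch=False)
        epochs = {"rest": es.epochs["rest"],
                  "slow_soft": es.epochs["rest"].copy()}
        es2 = EpochSet("S1", "patient", ELECTRODES, RATE, epochs)
        table = spectral.condition_table([es2])
        delta = spectral.contrast(table, "theta")
        np.testing.assert_allclose(delta.to_numpy(), 0.0, atol=1e-14)

    def test_manual_two_electrode_arithmetic(self):
        rows = []
        for cond, powers in (("rest", {"Fp1": 0.4, "O2": 0.2}),
                             ("slow_soft", {"Fp1": 0.3, "O2": 0.25}),
                             ("fast_soft", {"Fp1": 0.1, "O2": 0.15})):
            for el, p in powers.items():
                rows.append(("S1", "patient", cond, el, "theta", p))
        table = pd.DataFrame(rows, columns=["subject", "group", "condition",
                                            "electrode", "band", "power"])
        delta = spectral.contrast(table, "theta")
        assert delta.loc["S1", "Fp1"] == pytest.approx(0.2 - 0.4)
        assert delta.loc["S1", "O2"] == pytest.approx(0.2 - 0.2)

    def test_suppressed_patients_show_negative_theta_contrast(
            self, patient_theta_contrast, recovery_cohort):
        # generator ground truth: every patient has d > 0.15, so the mean
        # contrast across electrodes should be negative for nearly all
        means = patient_theta_contrast.mean(axis=1)
        assert (means < 0).mean() >= 0.9

    def test_missing_band_is_an_error(self, rng):
        es = _epoch_set(rng, {"rest": 2, "slow_soft": 2})
        table = spectral.condition_table([es])
        with pytest.raises(ValueError, match="gamma"):
            spectral.contrast(table, "gamma")
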