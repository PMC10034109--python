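"""Feature measures against independent oracles and their invariants."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rtmspredict import (
    BANDS,
    bispec_features,
    bispectrum,
    cordance,
    correlation_dimension,
    extract_features,
    generate_source,
    higuchi_fd,
    lempel_ziv,
    permutation_entropy,
    welch_band_power,
)
from rtmspredict.features import FeatureTable, _lz76_complexity
from rtmspredict.synthetic import SourceSpec

RNG = np.random.default_rng(12345)
FS = 250.0
T = np.arange(3000) / FS


class TestWelchPower:
    def test_single_tone_lands_in_its_band(self):
        x = np.sin(2 * np.pi * 10 * T)
        alpha = welch_band_power(x, FS, (8.0, 12.0))
        total = welch_band_power(x, FS, (0.0, FS / 2))
        assert alpha / total > 0.95

    def test_parseval_band_sum_matches_variance(self):
        x = RNG.standard_normal(30_000)
        total = welch_band_power(x, FS, (0.0, FS / 2))
        assert total == pytest.approx(np.var(x), rel=0.1)

    def test_zero_signal(self):
        assert welch_band_power(np.zeros(1000), FS, (8.0, 12.0)) == 0.0


class TestCordance:
    def test_site_with_both_maxima_scores_one(self):
        P = pd.DataFrame({"delta": [1, 1], "theta": [5, 1], "alpha": [1, 1],
                          "beta": [1, 1]}, index=["a", "b"], dtype=float)
        assert cordance(P).cordance.loc["a", "theta"] == pytest.approx(1.0)

    def test_identical_sites_all_score_one(self):
        P = pd.DataFrame(np.ones((3, 4)), columns=list(BANDS), dtype=float)
        assert np.allclose(cordance(P).cordance.values, 1.0)

    def test_three_site_hand_computation(self):
        # theta powers {4,2,1}, all other bands 1: worked by hand through
        # relative power, per-band max-normalization, and the combination
        P = pd.DataFrame({"delta": [1, 1, 1], "theta": [4, 2, 1],
                          "alpha": [1, 1, 1], "beta": [1, 1, 1]},
                         index=["s1", "s2", "s3"], dtype=float)
        c = cordance(P).cordance["theta"]
        # s1: (4/4-0.5)+( (4/7)/(4/7) -0.5) = 1.0
        # s2: (2/4-0.5)+( (2/5)/(4/7) -0.5) = 0.2
        # s3: (1/4-0.5)+( (1/4)/(4/7) -0.5) = -0.3125
        assert c.to_numpy() == pytest.approx([1.0, 0.2, -0.3125])

    def test_all_zero_band_rejected(self):
        P = pd.DataFrame(np.zeros((2, 4)), columns=list(BANDS))
        with pytest.raises(ValueError, match="cordance"):
            cordance(P)


class TestPermutationEntropy:
    def test_monotone_series_is_fully_regular(self):
        assert permutation_entropy(np.arange(500.0), m=2, tau=1) == pytest.approx(0.0)

    def test_seven_point_worked_example(self):
        # (4,7,9,10,6,11,3), m=2: 4 rises, 2 falls
        expected = (-(4 / 6) * math.log(4 / 6) - (2 / 6) * math.log(2 / 6)) / math.log(2)
        got = permutation_entropy(np.array([4, 7, 9, 10, 6, 11, 3]), m=2, tau=1)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(0.918, abs=1e-3)

    def test_random_series_near_one(self):
        assert permutation_entropy(RNG.standard_normal(30_000), m=3, tau=1) > 0.99

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="m!"):
            permutation_entropy(np.array([1.0, 2.0]), m=3, tau=1)


class TestHiguchiFD:
    def test_straight_line(self):
        assert higuchi_fd(np.arange(3000.0)) == pytest.approx(1.0, abs=0.02)

    def test_white_noise(self):
        vals = [higuchi_fd(np.random.default_rng(s).standard_normal(3000)) for s in range(5)]
        assert np.mean(vals) == pytest.approx(2.0, abs=0.1)

    def test_well_sampled_sine_near_one(self):
        assert higuchi_fd(np.sin(2 * np.pi * 2 * T)) < 1.1

    def test_constant_series_sentinel(self):
        with pytest.warns(RuntimeWarning, match="constant"):
            assert higuchi_fd(np.full(3000, 3.0)) == 1.0


class TestLempelZiv:
    def test_alternating_sequence_is_simple(self):
        assert lempel_ziv(np.tile([0, 1], 500)) < 0.1

    def test_sixteen_bit_hand_parse(self):
        # 0.001.10.100.1000.101 -> 6 words
        bits = np.array([int(c) for c in "0001101001000101"])
        assert _lz76_complexity(bits) == 6

    def test_agrees_with_independent_parser(self):
        def brute_ks(seq):  # Kaspar-Schuster formulation, independent path
            s = list(seq)
            n = len(s)
            i, k, l, c, kmax = 0, 1, 1, 1, 1
            while True:
                if s[i + k - 1] == s[l + k - 1]:
                    k += 1
                    if l + k > n:
                        return c + 1
                else:
                    kmax = max(k, kmax)
                    i += 1
                    if i == l:
                        c += 1
                        l += kmax
                        if l + 1 > n:
                            return c
                        i, k, kmax = 0, 1, 1
                    else:
                        k = 1

        rng = np.random.default_rng(0)
        for _ in range(50):
            bits = (rng.random(rng.integers(10, 300)) > 0.5).astype(int)
            assert _lz76_complexity(bits) == brute_ks(bits)

    def test_random_bits_near_one(self):
        vals = [lempel_ziv((np.random.default_rng(s).random(3000) > 0.5).astype(int))
                for s in range(3)]
        assert np.mean(vals) == pytest.approx(1.0, abs=0.15)


class TestCorrelationDimension:
    def test_limit_cycle_dimension_one(self):
        x = np.sin(2 * np.pi * 5 * T)
        assert correlation_dimension(x) == pytest.approx(1.0, abs=0.15)

    def test_uniform_noise_at_m2_fills_the_plane(self):
        x = np.random.default_rng(3).random(3000)
        assert correlation_dimension(x, m_range=(2,), tau=1) == pytest.approx(2.0, abs=0.3)

    def test_invariant_to_point_duplication(self):
        x = np.sin(2 * np.pi * 5 * np.arange(1500) / FS)
        d1 = correlation_dimension(x, m_range=(2, 3), tau=12)
        d2 = correlation_dimension(np.repeat(x, 2), m_range=(2, 3), tau=24)
        assert abs(d1 - d2) < 0.05 + 0.1  # duplication halves the sample spacing

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            correlation_dimension(np.sin(T[:500]))


class TestBispectrum:
    def test_gaussian_noise_has_low_normalized_bispectrum(self):
        x = np.random.default_rng(0).standard_normal(256 * 64)
        b = bispectrum(x, 256.0)
        assert b.bis_norm[b.omega].mean() < 0.2

    def test_coupled_triplet_reaches_the_coupling_limit(self):
        spec = SourceSpec(np.zeros(3), [0, 0, 1.0], "coupled_triplet", (4, 20), 1.0,
                          params={"f1": 6.0, "f2": 10.0, "coupling": 1.0})
        x = generate_source(spec, 256 * 60, 256.0, rng_seed=0)
        b = bispectrum(x, 256.0)
        i6, i10 = 6, 10  # 1 Hz bins at nfft=256, fs=256
        assert b.bis_norm[i10, i6] ** 2 > 0.9

    def test_random_sum_phase_destroys_coupling(self):
        spec = SourceSpec(np.zeros(3), [0, 0, 1.0], "coupled_triplet", (4, 20), 1.0,
                          params={"f1": 6.0, "f2": 10.0, "coupling": 0.0})
        x = generate_source(spec, 256 * 60, 256.0, rng_seed=0)
        b = bispectrum(x, 256.0)
        assert b.bis_norm[10, 6] ** 2 < 0.2

    def test_normalized_magnitude_bounded(self):
        x = np.random.default_rng(5).standard_normal(256 * 16)
        b = bispectrum(x, 256.0)
        assert b.bis_norm.max() <= 1.05

    def test_nfft_smaller_than_segment_rejected(self):
        with pytest.raises(ValueError, match="nfft"):
            bispectrum(np.zeros(4096), 256.0, nfft=128, segment_len=256)


class TestBispecFeatures:
    def _result_with_magnitudes(self, mags):
        """Minimal BispectrumResult whose in-band triangle holds ``mags``."""
        from rtmspredict.features import BispectrumResult

        n = 32
        freqs = np.arange(n, dtype=float)  # 1 Hz bins
        bis = np.zeros((n, n), dtype=complex)
        f_idx = np.arange(n)
        omega = (f_idx[None, :] <= f_idx[:, None]) & \
                ((f_idx[:, None] + f_idx[None, :]) <= n - 1)
        # place magnitudes on the theta-band diagonal-ish cells (4..7 Hz)
        cells = [(4, 4), (5, 4), (6, 4), (6, 5), (7, 4), (7, 5)][: len(mags)]
        for (i, j), m in zip(cells, mags):
            bis[i, j] = m
        return BispectrumResult(bis=bis, bis_norm=np.abs(bis), freqs=freqs,
                                omega=omega, fs=float(2 * n))

    def test_uniform_magnitudes_maximize_entropy(self):
        b = self._result_with_magnitudes([2.0] * 6)
        f = bispec_features(b, (4.0, 8.0))
        # entropy over the 10-cell in-band triangle: 6 equal cells of 10
        L = int((b.omega & (b.freqs[:, None] >= 4) & (b.freqs[:, None] < 8)
                 & (b.freqs[None, :] >= 4) & (b.freqs[None, :] < 8)).sum())
        expected_p1 = math.log(6) / math.log(L)
        assert f["p1"] == pytest.approx(expected_p1)
        assert f["mave"] == pytest.approx(2.0 * 6 / L)

    def test_single_bin_has_zero_entropy(self):
        b = self._result_with_magnitudes([5.0])
        f = bispec_features(b, (4.0, 8.0))
        assert f["p1"] == 0.0 and f["p2"] == 0.0

    def test_three_bin_hand_arithmetic(self):
        b = self._result_with_magnitudes([1.0, 2.0, 3.0])
        f = bispec_features(b, (4.0, 8.0))
        p = np.array([1, 2, 3]) / 6.0
        q = np.array([1, 4, 9]) / 14.0
        L = 10  # in-band triangle size for 4..7 Hz at 1 Hz bins
        assert f["p1"] == pytest.approx(float(-(p * np.log(p)).sum() / math.log(L)))
        assert f["p2"] == pytest.approx(float(-(q * np.log(q)).sum() / math.log(L)))
        assert f["diag_sum"] == pytest.approx(1.0)  # only (4,4) is diagonal


class TestScaleInvariance:
    @pytest.mark.parametrize("scale", [5.0, 0.2])
    def test_dimensionless_measures_unchanged_powers_scale(self, scale):
        x = generate_source(
            SourceSpec(np.zeros(3), [0, 0, 1.0], "band_limited_noise", (4.0, 20.0), 1.0),
            6000, FS, rng_seed=9,
        )
        y = scale * x
        assert permutation_entropy(y, 4, 1) == pytest.approx(permutation_entropy(x, 4, 1), rel=1e-6)
        assert lempel_ziv(y) == pytest.approx(lempel_ziv(x), rel=1e-6)
        assert higuchi_fd(y) == pytest.approx(higuchi_fd(x), rel=1e-6)
        assert correlation_dimension(y) == pytest.approx(correlation_dimension(x), rel=1e-6)
        assert welch_band_power(y, FS, (8.0, 12.0)) == pytest.approx(
            scale**2 * welch_band_power(x, FS, (8.0, 12.0)), rel=1e-9)
        bx, by = bispectrum(x, FS), bispectrum(y, FS)
        assert np.allclose(by.bis_norm, bx.bis_norm, atol=1e-9)
        fx = bispec_features(bx, (8.0, 12.0))
        fy = bispec_features(by, (8.0, 12.0))
        assert fy["p1"] == pytest.approx(fx["p1"], rel=1e-9)


class TestExtractFeatures:
    def test_row_shape_names_and_determinism(self, contrast_cohort):
        table = contrast_cohort["table"]
        assert table.features.shape[1] == 63
        assert not table.features.columns.duplicated().any()
        assert np.isfinite(table.features.to_numpy()).all()
        for fam, n in [("Non-Linear", 12), ("Power", 12), ("Bispectrum", 36),
                       ("Cordance", 3), ("Combination", 63)]:
            assert len(table.family_columns(fam)) == n

    def test_pure_beta_source_dominates_beta_band(self, montage):
        """A component holding a 20 Hz tone puts its maximum power in beta."""
        from rtmspredict.components import ComponentSet

        t = np.arange(8000) / FS
        series = np.vstack([
            np.sin(2 * np.pi * 20 * t),
            RNG.standard_normal(len(t)),
            np.sin(2 * np.pi * 6 * t),
        ])
        cs = ComponentSet(
            mixing=np.zeros((32, 3)), unmixing=np.zeros((3, 32)), series=series,
            lambda_weight=np.array([0.4, 0.3, 0.2]), fs=FS,
            labels=list(montage.labels), selected=[0, 1, 2],
        )
        row = extract_features(cs)
        powers = {b: row[f"IC1_power_{b}"] for b in BANDS}
        assert max(powers, key=powers.get) == "beta"

    def test_group_contrast_reaches_bispectral_features(self, contrast_cohort):
        """The injected coupling/amplitude contrasts show up in the
        bispectral family (the coupled triplet lives at (6,10) Hz, so the
        low-frequency bispectral summaries are where to look)."""
        from rtmspredict.selection import anova_screen

        table = contrast_cohort["table"]
        screen = anova_screen(table).table
        bisp = [c for c in table.features.columns if "_bisp_" in c]
        assert screen.loc[bisp, "keep"].any()
        low = [c for c in bisp if c.endswith(("delta", "theta"))]
        assert screen.loc[low, "p"].min() < 0.05
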