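"""Coupling measures: brute-force oracles, analytic limits, feature assembly."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import cardiocoupling as cc
from cardiocoupling.coupling import _delay_embed, fuzzy_membership
from conftest import random_pair, small_config


# --- independent reference implementations ---------------------------------

def ref_cross_entropy(x, y, m, r, fuzzy):
    """Direct double-loop transcription of the cross-entropy definition."""
    n = len(x)

    def match_mean(length):
        count = n - m          # same template count at both lengths
        total = 0.0
        for i in range(count):
            xi = x[i:i + length]
            for j in range(count):
                d = np.max(np.abs(xi - y[j:j + length]))
                if fuzzy:
                    total += math.exp(-math.log(2.0) * (d / r) ** 2)
                else:
                    total += 1.0 if d <= r else 0.0
        return total / count**2

    return -math.log(match_mean(m + 1) / match_mean(m))


def ref_doane(values):
    values = np.asarray(values, dtype=float)
    n = len(values)
    dev = values - values.mean()
    g1 = (dev**3).mean() / (dev**2).mean() ** 1.5
    sigma = math.sqrt(6.0 * (n - 2) / ((n + 1) * (n + 3)))
    return max(1, round(1 + math.log2(n) + math.log2(1 + abs(g1) / sigma)))


class TestCrossEntropies:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pair = random_pair(rng, int(rng.integers(60, 120)))
        assert cc.xsampen(pair) == pytest.approx(
            ref_cross_entropy(pair.x, pair.y, 2, 0.2, fuzzy=False), abs=1e-12)
        assert cc.xfuzzyen(pair) == pytest.approx(
            ref_cross_entropy(pair.x, pair.y, 2, 0.2, fuzzy=True), abs=1e-12)

    def test_huge_tolerance_gives_zero(self):
        pair = random_pair(np.random.default_rng(0), 150)
        assert cc.xsampen(pair, cc.EntropyParams(r=10.0)) == 0.0
        assert abs(cc.xfuzzyen(pair, cc.EntropyParams(r=10.0))) < 0.05

    def test_fuzzy_membership_half_at_tolerance(self):
        assert fuzzy_membership(0.2, 0.2) == pytest.approx(0.5, abs=1e-15)

    def test_periodic_signal_lower_entropy_than_noise(self):
        t = np.arange(300)
        sine = cc.znormalize(np.sin(2 * np.pi * t / 25))
        periodic = cc.SeriesPair("RRI", "STI", sine, sine)
        noisy = random_pair(np.random.default_rng(1), 300)
        assert cc.xsampen(periodic) < cc.xsampen(noisy)
        assert cc.xfuzzyen(periodic) < cc.xfuzzyen(noisy)

    def test_no_matches_raises_distinct_error(self):
        x = cc.znormalize(np.arange(40.0))
        y = -x
        pair = cc.SeriesPair("RRI", "STI", x, y)
        with pytest.raises(cc.UndefinedEntropyError):
            cc.xsampen(pair, cc.EntropyParams(r=0.001))

    def test_too_short_series_rejected(self):
        pair = cc.SeriesPair("RRI", "STI", np.array([0.1, -0.1, 0.2]),
                             np.array([0.0, 0.1, -0.2]))
        with pytest.raises(ValueError, match="too short"):
            cc.xsampen(pair, cc.EntropyParams(m=2))


class TestDoaneBins:
    def test_symmetric_power_of_two(self):
        # zero skewness and n = 1024: B = 1 + 10 + 0 = 11
        values = np.concatenate([np.arange(512), -np.arange(512)])
        assert cc.doane_bins(values) == 11

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_textbook_formula(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.gamma(shape=1.5, size=int(rng.integers(20, 500)))
        assert cc.doane_bins(values) == ref_doane(values)

    def test_positive_integer_and_min_n(self):
        assert cc.doane_bins([1.0, 2.0, 5.0]) >= 1
        with pytest.raises(ValueError):
            cc.doane_bins([1.0, 2.0])


class TestJDistEn:
    def test_bounded_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            val = cc.jdisten(random_pair(rng, int(rng.integers(40, 200))))
            assert 0.0 <= val <= 1.0

    def test_identical_series_reduces_to_distribution_entropy(self):
        z = cc.znormalize(np.random.default_rng(3).normal(size=200))
        val = cc.jdisten(cc.SeriesPair("RRI", "STI", z, z))
        # independent single-series computation on the same distance matrix
        emb = _delay_embed(z, 2, 3, 200 - 6)
        d = cdist(emb, emb, "chebyshev")
        d /= d.max()
        vals = d[np.triu_indices(len(d), k=1)]
        b = cc.doane_bins(vals)
        counts, _ = np.histogram(vals, bins=b, range=(0, 1))
        p = counts[counts > 0] / counts.sum()
        expected = -(p * np.log2(p)).sum() / math.log2(b)
        assert val == pytest.approx(expected, abs=1e-12)

    def test_degenerate_zero_distances(self):
        # almost-constant embedded geometry: all distances equal -> entropy 0
        z = np.zeros(100)
        z[0] = 1.0   # avoid the constant-series normalization error upstream
        pair = cc.SeriesPair("RRI", "STI", z, z)
        assert cc.jdisten(pair) >= 0.0

    def test_printed_product_form_differs(self):
        pair = random_pair(np.random.default_rng(4), 150)
        assert cc.jdisten(pair) != cc.jdisten(pair, geometric_mean=False)


class TestSpectral:
    def test_identical_series_full_coherence(self):
        pair = random_pair(np.random.default_rng(0), 300)
        same = cc.SeriesPair("RRI", "STI", pair.x, pair.x)
        _, curve, mean, sd = cc.mscf(same)
        np.testing.assert_allclose(curve, 1.0, atol=1e-10)
        assert mean == pytest.approx(1.0) and sd == pytest.approx(0.0, abs=1e-10)

    def test_coherence_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            _, curve, _, _ = cc.mscf(random_pair(rng, 300))
            assert np.all((curve >= 0) & (curve <= 1 + 1e-12))

    def test_white_noise_mean_matches_segment_bias(self):
        # Averaging L independent periodograms biases the coherence of
        # independent series to ~1/L.
        rng = np.random.default_rng(42)
        sp = cc.SpectralParams(nperseg=64, overlap=0.0, window="boxcar")
        means = [cc.mscf(random_pair(rng, 512), sp)[2] for _ in range(100)]
        assert np.mean(means) == pytest.approx(1 / 8, abs=0.01)

    def test_single_segment_rejected(self):
        pair = random_pair(np.random.default_rng(0), 100)
        with pytest.raises(ValueError, match="segments"):
            cc.mscf(pair, cc.SpectralParams(nperseg=100, overlap=0.0))

    def test_icpsd_zero_for_in_phase_and_anti_phase(self):
        pair = random_pair(np.random.default_rng(0), 300)
        same = cc.SeriesPair("RRI", "STI", pair.x, pair.x)
        flipped = cc.SeriesPair("RRI", "STI", pair.x, -pair.x)
        assert cc.icpsd(same)[2] == pytest.approx(0.0, abs=1e-10)
        assert cc.icpsd(flipped)[2] == pytest.approx(0.0, abs=1e-10)

    def test_icpsd_quadrature_tone_closed_form(self):
        # Unit-variance sinusoids in quadrature: with a boxcar window and
        # fs=1, the one-sided cross-spectral density peak is Ax*Ay*nperseg/2.
        n, nperseg = 256, 128
        f0 = 16 / nperseg
        t = np.arange(n)
        x = np.sqrt(2) * np.sin(2 * np.pi * f0 * t)
        y = np.sqrt(2) * np.cos(2 * np.pi * f0 * t)
        pair = cc.SeriesPair("RRI", "STI", x, y)
        sp = cc.SpectralParams(nperseg=nperseg, overlap=0.5, window="boxcar")
        freqs, curve, _, _ = cc.icpsd(pair, sp)
        peak = curve[np.argmin(np.abs(freqs - f0))]
        amp = np.sqrt(2)
        assert peak == pytest.approx(amp * amp * nperseg / 2, rel=1e-9)


class TestMutualInformation:
    def test_symmetric(self):
        pair = random_pair(np.random.default_rng(0), 200)
        swapped = cc.SeriesPair("RRI", "STI", pair.y, pair.x)
        assert cc.mutual_information(pair) == pytest.approx(
            cc.mutual_information(swapped), abs=1e-12)

    def test_strong_dependence_far_above_independence(self):
        rng = np.random.default_rng(1)
        z = cc.znormalize(rng.normal(size=300))
        coupled = cc.SeriesPair("RRI", "STI", z,
                                cc.znormalize(z + 0.1 * rng.normal(size=300)))
        indep = random_pair(rng, 300)
        assert cc.mutual_information(coupled) > cc.mutual_information(indep) + 1.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="N >= 50"):
            cc.mutual_information(random_pair(np.random.default_rng(0), 40))


@pytest.fixture(scope="module")
def valid_subject_series_class():
    return cc.gen_interval_series(small_config(n_beats=200), "cpnca", seed=11)


@pytest.fixture(scope="module")
def features(valid_subject_series_class):
    return cc.extract_features(valid_subject_series_class)


class TestFeatureAssembly:
    def test_sixty_four_finite_features(self, features):
        assert len(features.values) == 64
        assert features.values.notna().all()
        assert features.missing == ()

    def test_family_block_sizes(self, features):
        names = list(features.values.index)
        assert sum(n.endswith(("-XS", "-XF", "-JD")) for n in names) == 24
        assert sum("-MSCF-" in n for n in names) == 16
        assert sum("-ICPSD-" in n for n in names) == 16
        assert sum(n.endswith("-MI") for n in names) == 8

    def test_canonical_naming(self, features):
        assert list(features.values.index[:3]) == [
            "RRI-STI-XS", "RRI-STI-XF", "RRI-STI-JD"]
        assert "TpeI-DTI-JD" in features.values.index

    def test_family_restriction(self, valid_subject_series_class):
        fv = cc.extract_features(valid_subject_series_class,
                                 families=("entropy",))
        assert len(fv.values) == 24
        with pytest.raises(ValueError, match="unknown"):
            cc.extract_features(valid_subject_series_class,
                                families=("wavelet",))

    def test_impute_missing_uses_cohort_maximum(self):
        import pandas as pd
        frame = pd.DataFrame({
            "subject_id": ["a", "b", "c"],
            "group": ["severe"] * 3,
            "RRI-STI-XS": [1.0, np.nan, 3.0],
        })
        out = cc.impute_missing(frame)
        assert out["RRI-STI-XS"].tolist() == [1.0, 3.0, 3.0]
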