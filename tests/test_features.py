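"""Sample entropy, variance and the 20-column feature matrix."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somnoband.features import (
    FeatureMatrix,
    SampEnParams,
    extract_features,
    feature_layout,
    sample_entropy,
    variance,
)
from somnoband.io import EpochSet
from somnoband.synthetic import SyntheticConfig, generate

from .oracles import sampen_reference


class TestSampleEntropy:
    def test_constant_series_is_exactly_zero(self):
        assert sample_entropy(np.full(100, 5.0)) == 0.0

    @pytest.mark.parametrize("m", [1, 2, 3])
    @pytest.mark.parametrize("n", [30, 120, 400])
    def test_matches_reference_oracle(self, m, n):
        rng = np.random.default_rng(1000 * m + n)
        x = rng.standard_normal(n)
        ref = sampen_reference(x, m)
        if not np.isfinite(ref):
            # degenerate draw: definition gives -ln 0, we return the bound
            with pytest.warns(RuntimeWarning, match="upper bound"):
                ours = sample_entropy(x, SampEnParams(m=m))
            assert ours == pytest.approx(-np.log(2 / ((n - m - 1) * (n - m))))
        else:
            ours = sample_entropy(x, SampEnParams(m=m))
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_correlated_series_against_oracle(self):
        # AR(1) series: plenty of template matches, nontrivial value
        rng = np.random.default_rng(42)
        x = np.zeros(500)
        for i in range(1, 500):
            x[i] = 0.9 * x[i - 1] + rng.standard_normal()
        assert sample_entropy(x) == pytest.approx(sampen_reference(x), abs=1e-12)

    def test_periodic_below_noise_complexity(self):
        t = np.arange(400)
        sin = np.sin(2 * np.pi * t / 20)
        rng = np.random.default_rng(5)
        noise = rng.standard_normal(400)
        noise *= sin.std() / noise.std()
        assert sample_entropy(sin) < sample_entropy(noise)
        # the ordering is the oracle's too
        assert sampen_reference(sin) < sampen_reference(noise)

    def test_monotone_complexity_ordering(self):
        """noise > sinusoid > constant = 0, averaged over 20 seeds."""
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 300
            sin = np.sin(2 * np.pi * np.arange(n) / 25 + rng.uniform(0, 2 * np.pi))
            noise = rng.standard_normal(n) * sin.std()
            diffs.append(sample_entropy(noise) - sample_entropy(sin))
            assert sample_entropy(np.full(n, 3.3)) == 0.0
        assert np.mean(diffs) > 0
        assert np.all(np.asarray(diffs) > 0)

    @pytest.mark.parametrize("a", [2.0, 0.03125, 1024.0])
    def test_amplitude_invariance(self, a):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(250)
        assert sample_entropy(a * x) == sample_entropy(x)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            sample_entropy(np.arange(3.0), SampEnParams(m=2))

    def test_degenerate_no_matches_returns_finite_bound(self):
        # widely spaced values with a tiny radius: no template ever matches
        rng = np.random.default_rng(3)
        x = rng.standard_normal(50)
        with pytest.warns(RuntimeWarning, match="upper bound"):
            v = sample_entropy(x, SampEnParams(m=2, r_factor=1e-6))
        n, m = 50, 2
        assert v == pytest.approx(-np.log(2 / ((n - m - 1) * (n - m))))
        assert np.isfinite(v)


class TestVariance:
    def test_hand_computed_example(self):
        assert variance([2, 4, 6]) == pytest.approx(8 / 3, abs=1e-15)

    def test_constant_is_zero(self):
        assert variance(np.full(17, 4.2)) == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=40),
        st.sampled_from([2.0, 0.5, 8.0]),
    )
    def test_homogeneity_degree_two(self, xs, a):
        x = np.asarray(xs)
        assert variance(a * x) == pytest.approx(a * a * variance(x), rel=1e-9, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            variance(np.array([]))


class TestFeatureMatrix:
    def test_twenty_columns_with_table_layout(self, small_epochs):
        fm = extract_features(small_epochs)
        assert fm.values.shape == (small_epochs.n_epochs, 20)
        combos = [(c.feature, c.channel, c.band) for c in fm.columns]
        assert len(set(combos)) == 20
        # variance block first, channel-major, band-minor
        assert combos[0] == ("variance", "C3", "delta")
        assert combos[4] == ("variance", "C3", "beta")
        assert combos[5] == ("variance", "C4", "delta")
        assert combos[10] == ("sample_entropy", "C3", "delta")
        assert combos[19] == ("sample_entropy", "C4", "beta")
        assert [c.index for c in fm.columns] == list(range(1, 21))

    def test_labels_and_row_order_carried(self, small_epochs):
        fm = extract_features(small_epochs)
        assert np.array_equal(fm.labels, small_epochs.labels)

    def test_values_finite_and_variance_nonnegative(self, small_epochs):
        fm = extract_features(small_epochs)
        assert np.all(np.isfinite(fm.values))
        assert np.all(fm.values[:, :10] >= 0)  # variance block
        assert np.all(fm.values[:, 10:] >= 0)  # entropy block

    def test_single_channel_gives_ten_columns(self, small_epochs):
        es = EpochSet(
            epochs=small_epochs.epochs[:, :1, :],
            labels=small_epochs.labels,
            fs=small_epochs.fs,
            channel_names=("C3-A2",),
            epoch_len_s=small_epochs.epoch_len_s,
        )
        fm = extract_features(es)
        assert fm.values.shape[1] == 10

    def test_csv_round_trip(self, small_epochs, tmp_path):
        fm = extract_features(small_epochs)
        path = tmp_path / "features.csv"
        fm.to_csv(path, SampEnParams())
        back = FeatureMatrix.from_csv(path)
        assert np.array_equal(back.labels, fm.labels)
        np.testing.assert_allclose(back.values, fm.values, rtol=1e-12)
        assert [c.name for c in back.columns] == [c.name for c in fm.columns]

    def test_empty_epochs_rejected(self, small_epochs):
        es = EpochSet(
            epochs=np.empty((0, 2, 500)),
            labels=np.array([], dtype=object),
            fs=100.0,
            channel_names=("C3-A2", "C4-A1"),
            epoch_len_s=5.0,
        )
        with pytest.raises(ValueError, match="empty"):
            extract_features(es)

    def test_layout_registry_is_exhaustive(self):
        cols = feature_layout(("C3-A2", "C4-A1"))
        feats = {(c.feature, c.channel, c.band) for c in cols}
        expected = {
            (f, ch, b)
            for f in ("variance", "sample_entropy")
            for ch in ("C3", "C4")
            for b in ("delta", "theta", "alpha", "sigma", "beta")
        }
        assert feats == expected
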