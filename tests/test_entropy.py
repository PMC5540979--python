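import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eegfatigue as ef
from eegfatigue.entropy import FEATURE_ORDER, feature_columns

from oracles import (
    naive_apen,
    naive_chebyshev,
    naive_embed,
    naive_fuzzyen,
    naive_sampen,
    naive_spectral_entropy,
)

PARAMS = ef.EntropyParams()  # m=2, s_coef=0.2, n=4


class TestEmbed:
    def test_direct_indexing(self):
        out = ef.embed([1, 2, 3, 4], m=2)
        np.testing.assert_array_equal(out, [[1, 2], [2, 3], [3, 4]])

    def test_centered_pair(self):
        out = ef.embed([1, 3], m=2, center=True)
        np.testing.assert_array_equal(out, [[-1, 1]])

    def test_matches_loop_oracle(self, rng):
        x = rng.standard_normal(20)
        for center in (False, True):
            ours = ef.embed(x, m=3, center=center)
            assert ours.shape == (18, 3)
            np.testing.assert_allclose(ours, naive_embed(x, 3, center), atol=1e-15)

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            ef.embed([1.0], m=2)


class TestChebyshev:
    def test_identity_is_zero(self):
        assert ef.chebyshev_distance([1.5, -2.0], [1.5, -2.0]) == 0.0

    def test_forced_example(self):
        assert ef.chebyshev_distance([0, 0], [1, -3]) == 3.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            ef.chebyshev_distance([1.0], [1.0, 2.0])

    @given(st.integers(1, 6), st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_random_pairs_match_loop(self, dim, seed):
        r = np.random.default_rng(seed)
        a, b = r.standard_normal(dim), r.standard_normal(dim)
        assert ef.chebyshev_distance(a, b) == pytest.approx(
            naive_chebyshev(a, b), abs=0
        )


class TestSpectralEntropy:
    def test_single_bin_sinusoid_is_zero(self):
        t = np.arange(64)
        x = np.sin(2 * np.pi * 8 * t / 64)  # exact bin, no leakage
        assert ef.spectral_entropy(x) < 1e-9

    def test_flat_spectrum_gives_log_bins(self):
        # build a 16-sample signal whose one-sided periodogram is flat
        # over the 8 nonzero bins (Nyquist magnitude scaled by sqrt(2)
        # to undo the one-sided doubling of interior bins)
        rng = np.random.default_rng(0)
        spec = np.zeros(9, dtype=complex)
        phases = np.exp(2j * np.pi * rng.random(7))
        spec[1:8] = phases
        spec[8] = np.sqrt(2.0)
        x = np.fft.irfft(spec, 16)
        assert ef.spectral_entropy(x) == pytest.approx(np.log(8), abs=1e-10)

    def test_constant_signal_returns_zero(self):
        assert ef.spectral_entropy(np.full(50, 3.7)) == 0.0

    def test_matches_independent_dft_oracle(self, rng):
        x = rng.standard_normal(64)
        assert ef.spectral_entropy(x) == pytest.approx(
            naive_spectral_entropy(x), abs=1e-10
        )

    def test_normalized_version_in_unit_interval(self, rng):
        x = rng.standard_normal(128)
        v = ef.spectral_entropy(x, normalize=True)
        assert 0.0 <= v <= 1.0


class TestMatchCountingEntropies:
    """ApEn / SampEn / FuzzyEn against the naive double-loop oracles."""

    @pytest.mark.parametrize("seed", range(10))
    def test_apen_matches_oracle(self, seed):
        x = np.random.default_rng(seed).standard_normal(50)
        assert ef.approximate_entropy(x, PARAMS) == pytest.approx(
            naive_apen(x, 2, 0.2), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_sampen_matches_oracle(self, seed):
        x = np.random.default_rng(seed).standard_normal(60)
        assert ef.sample_entropy(x, PARAMS) == pytest.approx(
            naive_sampen(x, 2, 0.2), abs=1e-12, nan_ok=True
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_fuzzyen_matches_oracle(self, seed):
        x = np.random.default_rng(seed).standard_normal(50)
        assert ef.fuzzy_entropy(x, PARAMS) == pytest.approx(
            naive_fuzzyen(x, 2, 0.2, 4), abs=1e-12
        )

    def test_constant_sequence_all_zero(self):
        x = np.full(100, 2.5)
        assert ef.approximate_entropy(x, PARAMS) == 0.0
        assert ef.sample_entropy(x, PARAMS) == 0.0
        assert ef.fuzzy_entropy(x, PARAMS) == 0.0

    @pytest.mark.parametrize("c", [0.5, 3.0, 1e4])
    def test_hard_threshold_scale_invariance(self, c, rng):
        """AE and SE are exactly scale invariant (tolerance tracks SD)."""
        x = rng.standard_normal(80)
        for fn in (ef.approximate_entropy, ef.sample_entropy):
            assert fn(c * x, PARAMS) == pytest.approx(fn(x, PARAMS), rel=1e-9)

    def test_fuzzy_offset_invariance_but_scale_sensitivity(self, rng):
        """FE is offset invariant (centering); its exp(-d^n/s) membership
        with n=4 makes it scale *sensitive*, unlike the hard-threshold
        estimators."""
        x = rng.standard_normal(80)
        assert ef.fuzzy_entropy(x + 100.0, PARAMS) == pytest.approx(
            ef.fuzzy_entropy(x, PARAMS), rel=1e-9
        )
        assert ef.fuzzy_entropy(3.0 * x, PARAMS) != pytest.approx(
            ef.fuzzy_entropy(x, PARAMS), rel=1e-3
        )
        # with a unit membership exponent the scale symmetry is restored
        p1 = ef.EntropyParams(n=1.0)
        assert ef.fuzzy_entropy(3.0 * x, p1) == pytest.approx(
            ef.fuzzy_entropy(x, p1), rel=1e-9
        )

    def test_apen_exclude_self_toggle_differs(self, rng):
        x = rng.standard_normal(60)
        inc = ef.approximate_entropy(x, PARAMS)
        exc = ef.approximate_entropy(x, PARAMS, exclude_self=True)
        assert inc != exc

    def test_sampen_undefined_returns_nan(self):
        # alternating doubling jumps: no template matches survive at m+1
        x = np.array([1, -1, 2, -2, 4, -4, 8, -8, 16, -16], dtype=float)
        assert np.isnan(ef.sample_entropy(x, PARAMS))

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            ef.sample_entropy(np.array([1.0, 2.0, 3.0]), PARAMS)

    @pytest.mark.parametrize("seed", range(20))
    def test_bounds_invariants(self, seed):
        x = np.random.default_rng(seed).standard_normal(100)
        se = ef.sample_entropy(x, PARAMS)
        if not np.isnan(se):
            assert se >= 0.0
        assert ef.fuzzy_entropy(x, PARAMS) >= -1e-9
        pe = ef.spectral_entropy(x)
        assert 0.0 <= pe <= np.log(51)  # 51 one-sided bins for L=100

    def test_noise_beats_sinusoid(self):
        """White noise is less regular than a sinusoid for all four estimators."""
        t = np.arange(1000)
        sine = np.sin(2 * np.pi * t / 25)
        wins = 0
        for seed in range(5):
            noise = np.random.default_rng(seed).standard_normal(1000)
            for fn in (ef.fuzzy_entropy, ef.sample_entropy, ef.approximate_entropy):
                assert fn(noise, PARAMS) > fn(sine, PARAMS)
            assert ef.spectral_entropy(noise) > ef.spectral_entropy(sine)
            wins += 1
        assert wins == 5


class TestFeatureTable:
    def make_epochs(self, n=10, L=100, seed=0, state="normal"):
        r = np.random.default_rng(seed)
        return [
            ef.Epoch(values=r.standard_normal(L), subject_id="S0",
                     channel="ch00", state=state, epoch_index=i)
            for i in range(n)
        ]

    def test_single_feature_shape(self):
        table = ef.extract_features(self.make_epochs(), "FE")
        assert feature_columns(table) == ["FE"]
        assert len(table) == 10
        assert set(table.columns) >= {"subject", "channel", "epoch_index", "state"}

    def test_combined_order(self):
        table = ef.extract_features(self.make_epochs(n=3), "combined")
        assert feature_columns(table) == list(FEATURE_ORDER)

    def test_compositional_against_single_ops(self):
        epochs = self.make_epochs(n=4)
        table = ef.extract_features(epochs, "combined")
        for i, ep in enumerate(epochs):
            assert table.loc[i, "FE"] == pytest.approx(ef.fuzzy_entropy(ep.values, PARAMS))
            assert table.loc[i, "SE"] == pytest.approx(ef.sample_entropy(ep.values, PARAMS))
            assert table.loc[i, "AE"] == pytest.approx(ef.approximate_entropy(ep.values, PARAMS))
            assert table.loc[i, "PE"] == pytest.approx(ef.spectral_entropy(ep.values))

    def test_empty_epoch_list_raises(self):
        with pytest.raises(ValueError, match="empty"):
            ef.extract_features([], "FE")

    def test_sentinel_rows_excluded_and_counted(self):
        # seeds chosen so the regular windows have defined SampEn at
        # L=40 while seed 1 has no surviving template matches
        defined = [
            ef.Epoch(values=np.random.default_rng(s).standard_normal(40),
                     subject_id="S0", channel="ch00", state="normal",
                     epoch_index=i)
            for i, s in enumerate([0, 2, 3, 8, 9])
        ]
        sentinel = ef.Epoch(values=np.random.default_rng(1).standard_normal(40),
                            subject_id="S0", channel="ch00", state="normal",
                            epoch_index=99)
        table = ef.extract_features(defined + [sentinel], "SE")
        assert len(table) == 5
        assert table.attrs["n_excluded"] == 1


class TestScaling:
    def make_table(self, values_by_group):
        import pandas as pd

        rows = []
        for (subj, ch), vals in values_by_group.items():
            for i, v in enumerate(vals):
                rows.append({"subject": subj, "channel": ch, "epoch_index": i,
                             "state": "normal", "FE": float(v)})
        return pd.DataFrame(rows)

    def test_affine_endpoints(self):
        out = ef.scale_features(self.make_table({("A", "c"): [2, 4, 6]}))
        np.testing.assert_allclose(out["FE"], [-1.0, 0.0, 1.0])

    def test_constant_group_maps_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = ef.scale_features(self.make_table({("A", "c"): [5, 5, 5]}))
        np.testing.assert_array_equal(out["FE"], [0.0, 0.0, 0.0])

    def test_groupwise_independence(self, rng):
        table = self.make_table({
            ("A", "c"): rng.standard_normal(5),
            ("B", "c"): 100 + rng.standard_normal(5),
        })
        out = ef.scale_features(table)
        for subj in ("A", "B"):
            grp = out[out["subject"] == subj]["FE"]
            assert grp.min() == pytest.approx(-1.0)
            assert grp.max() == pytest.approx(1.0)
        assert out.attrs["normalization_state"] == "scaled"

    def test_train_only_mode_fits_on_train(self):
        table = self.make_table({("A", "c"): [0, 1, 2, 3]})
        mask = np.array([True, True, True, False])
        out = ef.scale_features(table, mode="train_only", train_mask=mask,
                                clip=False)
        # train units 0..2 span [-1, 1]; unit 3 extrapolates beyond
        np.testing.assert_allclose(out["FE"], [-1.0, 0.0, 1.0, 2.0])
        clipped = ef.scale_features(table, mode="train_only", train_mask=mask)
        assert clipped["FE"].iloc[3] == 1.0


class TestEntropyFeaturizer:
    def test_transform_matches_functions(self, rng):
        X = rng.standard_normal((5, 40))
        tf = ef.EntropyFeaturizer(feature_set="combined").fit(X)
        out = tf.transform(X)
        assert out.shape == (5, 4)
        assert list(tf.get_feature_names_out()) == list(FEATURE_ORDER)
        for i in range(5):
            assert out[i, 0] == pytest.approx(ef.fuzzy_entropy(X[i], PARAMS))

    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone

        tf = ef.EntropyFeaturizer(feature_set="SE", m=3)
        cl = clone(tf)
        assert cl.get_params()["m"] == 3 and cl.get_params()["feature_set"] == "SE"
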