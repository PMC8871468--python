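"""Tests for the CPR and Hellinger synchronization measures and surrogates."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neurorqa.recurrence import TauRecurrenceSeries
from neurorqa.sync import (
    apply_theiler,
    block_shuffle,
    cpr_pearson,
    cpr_spearman,
    hellinger,
    surrogate_confidence_limit,
    sync_onset,
)


def _rr(values, dt=1.0):
    values = np.asarray(values, float)
    return TauRecurrenceSeries(np.arange(values.size), values, dt)


def _prob_vectors(n=8):
    return st.lists(
        st.floats(1e-6, 1.0), min_size=n, max_size=n
    ).map(lambda xs: np.asarray(xs) / np.sum(xs))


class TestTheilerWindow:
    def test_zero_window_is_identity(self):
        rr = _rr([1.0, 0.5, 0.2], dt=0.5)
        out = apply_theiler(rr, 0.0)
        assert np.array_equal(out.rr, rr.rr)

    def test_window_drops_expected_sample_count(self):
        rr = _rr(np.linspace(1, 0, 200), dt=0.5)
        out = apply_theiler(rr, 25.0)
        assert len(out) == 150  # tau = 0 .. 49 samples (< 25 ms) removed
        assert out.tau[0] == 50

    def test_window_beyond_span_rejected(self):
        with pytest.raises(ValueError):
            apply_theiler(_rr([1.0, 0.2], dt=1.0), 25.0)


class TestCPR:
    def test_identical_series_fully_correlated(self):
        rr = _rr([1.0, 0.2, 0.7, 0.1, 0.9, 0.3])
        assert cpr_pearson(rr, rr) == pytest.approx(1.0)
        assert cpr_spearman(rr, rr) == pytest.approx(1.0)

    def test_pearson_affine_invariance(self):
        a = _rr([0.9, 0.1, 0.6, 0.2, 0.8, 0.05])
        b = _rr(3.0 * a.rr + 0.4)
        assert cpr_pearson(a, b) == pytest.approx(1.0)

    def test_pearson_matches_textbook_formula(self):
        x = [0.9, 0.1, 0.6, 0.2, 0.8, 0.05]
        y = [0.7, 0.3, 0.5, 0.1, 0.9, 0.20]
        mx, my = sum(x) / 6, sum(y) / 6
        cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / 6
        sx = (sum((a - mx) ** 2 for a in x) / 6) ** 0.5
        sy = (sum((b - my) ** 2 for b in y) / 6) ** 0.5
        assert cpr_pearson(_rr(x), _rr(y)) == pytest.approx(cov / (sx * sy))

    def test_spearman_invariant_under_monotone_transform(self):
        a = _rr([0.9, 0.1, 0.6, 0.2, 0.8, 0.05])
        b = _rr(np.exp(4.0 * a.rr))
        assert cpr_spearman(a, b) == pytest.approx(1.0)

    def test_spearman_ties_use_average_ranks(self):
        x = np.array([0.5, 0.5, 0.2, 0.9, 0.2, 0.7])
        y = np.array([0.1, 0.4, 0.4, 0.8, 0.3, 0.6])

        def avg_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(v.size)
            i = 0
            sv = v[order]
            while i < v.size:
                j = i
                while j + 1 < v.size and sv[j + 1] == sv[i]:
                    j += 1
                ranks[order[i : j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        expect = np.corrcoef(rx, ry)[0, 1]
        assert cpr_spearman(_rr(x), _rr(y)) == pytest.approx(expect)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            cpr_pearson(_rr(np.ones(6)), _rr([0.5, 0.1, 0.2, 0.3, 0.4, 0.6]))


class TestHellinger:
    def test_identical_series_distance_zero(self):
        rr = _rr([0.4, 0.3, 0.2, 0.1])
        assert hellinger(rr, rr) == 0.0

    def test_disjoint_supports_distance_one(self):
        assert hellinger(_rr([1.0, 1.0, 0, 0]), _rr([0, 0, 1.0, 1.0])) == pytest.approx(1.0)

    def test_bhattacharyya_closed_form(self):
        got = hellinger(_rr([0.5, 0.5]), _rr([1.0, 0.0]))
        assert got == pytest.approx(np.sqrt(1.0 - np.sqrt(0.5)))

    def test_scale_invariance_of_unit_sum_normalization(self):
        a = _rr([0.4, 0.3, 0.2, 0.1])
        b = _rr([0.1, 0.2, 0.3, 0.4])
        assert hellinger(a, _rr(7.0 * b.rr)) == pytest.approx(hellinger(a, b))

    def test_rms_variant_skips_normalization(self):
        a, b = _rr([0.4, 0.1, 0.25, 0.25]), _rr([0.2, 0.3, 0.3, 0.2])
        expect = np.sqrt(0.5 * np.mean((np.sqrt(a.rr) - np.sqrt(b.rr)) ** 2))
        assert hellinger(a, b, normalization="rms") == pytest.approx(expect)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            hellinger(_rr([-0.1, 0.5]), _rr([0.5, 0.5]))

    @given(p=_prob_vectors(), q=_prob_vectors(), r=_prob_vectors())
    def test_metric_axioms_on_probability_vectors(self, p, q, r):
        def H(a, b):
            return hellinger(_rr(a), _rr(b))

        assert H(p, p) == pytest.approx(0.0, abs=1e-12)
        assert H(p, q) == pytest.approx(H(q, p))
        assert 0.0 <= H(p, q) <= 1.0 + 1e-12
        assert H(p, r) <= H(p, q) + H(q, r) + 1e-9


class TestBlockShuffle:
    def test_multiset_preserved_and_blocks_intact(self, rng):
        x = np.arange(10.0)
        out = block_shuffle(x, 5, rng)
        assert np.array_equal(np.sort(out), x)
        pairs = out.reshape(5, 2)
        assert all(b[1] - b[0] == 1.0 and b[0] % 2 == 0 for b in pairs)

    def test_non_identity_enforced(self, rng):
        x = np.arange(10.0)
        for _ in range(25):
            assert not np.array_equal(block_shuffle(x, 5, rng), x)

    def test_fixed_seed_reproducible(self):
        x = np.sin(np.arange(100.0))
        a = block_shuffle(x, 5, np.random.default_rng(42))
        b = block_shuffle(x, 5, np.random.default_rng(42))
        assert np.array_equal(a, b)

    def test_random_cut_mode_preserves_full_multiset(self, rng):
        x = np.arange(37.0)
        out = block_shuffle(x, 5, rng, mode="random_cuts")
        assert out.size == x.size
        assert np.array_equal(np.sort(out), x)
        assert not np.array_equal(out, x)

    def test_single_block_rejected(self):
        with pytest.raises(ValueError):
            block_shuffle(np.arange(10.0), 1)

    def test_more_blocks_than_samples_rejected(self):
        with pytest.raises(ValueError):
            block_shuffle(np.arange(3.0), 5)


class TestSurrogateEnsemble:
    @staticmethod
    def _noisy_pair(rng, n=400):
        t = np.arange(n) * 1.0
        v1 = np.sin(0.3 * t) + 0.3 * rng.normal(size=n)
        v2 = np.sin(0.21 * t + 1.0) + 0.3 * rng.normal(size=n)
        return v1, v2

    def test_full_quantile_is_ensemble_maximum(self, rng):
        v1, v2 = self._noisy_pair(rng)
        with np.errstate(all="ignore"):
            hq, hs = surrogate_confidence_limit(
                v1, v2, 1.0, n_surrogates=120, quantile=1.0, rng=7
            )
        assert hq == pytest.approx(np.max(hs))

    def test_fixed_seed_gives_identical_ensemble(self, rng):
        v1, v2 = self._noisy_pair(rng)
        _, a = surrogate_confidence_limit(v1, v2, 1.0, n_surrogates=120, rng=11)
        _, b = surrogate_confidence_limit(v1, v2, 1.0, n_surrogates=120, rng=11)
        assert np.array_equal(a, b)

    def test_null_calibration_on_independent_noise(self):
        """Unrelated signals should not look significant: their H should sit
        inside the surrogate null distribution most of the time."""
        from neurorqa.recurrence import EmbeddingSpec, delay_embed, threshold_for_density, tau_recurrence_rate_streaming
        from neurorqa.sync import RecurrencePipelineConfig

        master = np.random.default_rng(5)
        pipe = RecurrencePipelineConfig(embedding=EmbeddingSpec(2, (5,)), theiler_ms=10.0)
        hits = 0
        trials = 20
        for _ in range(trials):
            v1, v2 = self._noisy_pair(master)
            hq, _ = surrogate_confidence_limit(
                v1, v2, 1.0, pipe, n_surrogates=100, quantile=0.05,
                rng=int(master.integers(2**31)),
            )

            def rr(x):
                X = delay_embed(x, pipe.embedding)
                return tau_recurrence_rate_streaming(X, threshold_for_density(X, pipe.density))

            h_obs = hellinger(rr(v1), rr(v2), pipe.theiler_ms)
            hits += h_obs < hq  # below the 5% null quantile = false positive
        assert hits <= 5  # expected ~1 of 20


class TestSyncOnset:
    g = np.linspace(0, 0.15, 16)

    def test_sustained_threshold_crossing(self):
        cpr = np.where(self.g >= 0.04, 0.99, 0.2)
        assert sync_onset(self.g, cpr, 0.95) == pytest.approx(0.04)

    def test_never_sustained_returns_none(self):
        assert sync_onset(self.g, np.full_like(self.g, 0.5), 0.95) is None

    def test_direction_below(self):
        h = np.where(self.g >= 0.06, 0.05, 0.8)
        got = sync_onset(self.g, h, 0.17, direction="below")
        assert got == pytest.approx(self.g[self.g >= 0.06][0])
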