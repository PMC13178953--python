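"""Feature-derivation tests against independent elementwise oracles."""

import numpy as np
import pytest

from maskgnn.features import (
    DegenerateRangeError,
    DegenerateSignalError,
    FunctionalConnectome,
    StructuralConnectome,
    TimeSeriesMatrix,
    aggregate_int,
    assemble_as,
    compute_coupling,
    compute_fc,
    compute_int,
    minmax_scale,
    normalize_as,
    normalize_sc,
)


def pearson_oracle(x):
    """Elementwise Pearson correlation from first principles."""
    t, u = x.shape
    out = np.empty((u, u))
    for i in range(u):
        for j in range(u):
            a, b = x[:, i] - x[:, i].mean(), x[:, j] - x[:, j].mean()
            out[i, j] = (a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum())
    return out


class TestComputeFC:
    def test_identical_and_negated_columns(self):
        base = np.array([1.0, 3.0, 2.0, 5.0])
        ts = TimeSeriesMatrix(np.column_stack([base, base, -base]), tr=1.0)
        fc = compute_fc(ts).values
        assert fc[0, 1] == pytest.approx(1.0)
        assert fc[0, 2] == pytest.approx(-1.0)

    def test_small_integer_matrix_matches_oracle(self):
        x = np.array([[1, 2, 0], [3, 1, 2], [2, 4, 1], [5, 3, 3]], dtype=float)
        fc = compute_fc(TimeSeriesMatrix(x, tr=0.8)).values
        np.testing.assert_allclose(fc, pearson_oracle(x), atol=1e-12)

    def test_random_matrices_match_oracle(self, rng):
        for _ in range(5):
            x = rng.normal(size=(30, 6))
            fc = compute_fc(TimeSeriesMatrix(x, tr=1.0)).values
            np.testing.assert_allclose(fc, pearson_oracle(x), atol=1e-10)
            assert np.allclose(fc, fc.T)
            assert np.allclose(np.diag(fc), 1.0)

    def test_zero_variance_column_raises_naming_column(self):
        x = np.array([[1.0, 2.0], [2.0, 2.0], [3.0, 2.0]])
        with pytest.raises(DegenerateSignalError, match=r"\[1\]"):
            compute_fc(TimeSeriesMatrix(x, tr=1.0))


class TestMinMaxScale:
    def test_basic_and_idempotent(self):
        np.testing.assert_allclose(minmax_scale(np.array([2.0, 4.0, 6.0])), [0, 0.5, 1])
        once = minmax_scale(np.array([2.0, 4.0, 6.0]))
        np.testing.assert_allclose(minmax_scale(once), once)

    def test_exclude_diagonal_leaves_diagonal_untouched(self, rng):
        m = rng.normal(size=(5, 5))
        m = m + m.T
        out = minmax_scale(m, exclude_diagonal=True)
        off = out[~np.eye(5, dtype=bool)]
        assert off.min() == pytest.approx(0.0) and off.max() == pytest.approx(1.0)
        np.testing.assert_array_equal(np.diag(out), np.diag(m))

    def test_constant_input_raises(self):
        with pytest.raises(DegenerateRangeError):
            minmax_scale(np.full(4, 3.0))


class TestNormalizeSC:
    def test_unit_volumes_leave_matrix_unchanged(self):
        m = np.array([[0.0, 2.0], [2.0, 0.0]])
        sc = StructuralConnectome(values=m, gm_volumes=np.ones(2))
        out = normalize_sc(sc, scale=False)
        np.testing.assert_array_equal(out.values, m)

    def test_sqrt_volume_product(self):
        m = np.array([[0.0, 6.0], [6.0, 0.0]])
        sc = StructuralConnectome(values=m, gm_volumes=np.array([4.0, 9.0]))
        out = normalize_sc(sc, scale=False)
        assert out.values[0, 1] == pytest.approx(1.0)

    def test_random_case_matches_elementwise_oracle(self, rng):
        m = np.abs(rng.normal(size=(6, 6)))
        m = m + m.T
        np.fill_diagonal(m, 0.0)
        vols = rng.uniform(1.0, 5.0, size=6)
        out = normalize_sc(StructuralConnectome(values=m, gm_volumes=vols), scale=False)
        expected = np.array(
            [[m[i, j] / np.sqrt(vols[i] * vols[j]) for j in range(6)] for i in range(6)]
        )
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    def test_commutes_with_permutation(self, rng):
        m = np.abs(rng.normal(size=(5, 5)))
        m = m + m.T
        np.fill_diagonal(m, 0.0)
        vols = rng.uniform(1.0, 5.0, size=5)
        perm = rng.permutation(5)
        direct = normalize_sc(
            StructuralConnectome(values=m[np.ix_(perm, perm)], gm_volumes=vols[perm])
        ).values
        permuted = normalize_sc(StructuralConnectome(values=m, gm_volumes=vols)).values[
            np.ix_(perm, perm)
        ]
        np.testing.assert_allclose(direct, permuted, atol=1e-12)

    def test_nonpositive_volume_raises(self):
        sc = StructuralConnectome(values=np.zeros((2, 2)), gm_volumes=np.array([1.0, 0.0]))
        with pytest.raises(ValueError, match="volume"):
            normalize_sc(sc)


def acf_oracle(y, k):
    """Lag-k autocorrelation with the full-series sum of squares as
    denominator, written directly from the defining sums."""
    yc = y - y.mean()
    num = sum(yc[t] * yc[t - k] for t in range(k, len(y)))
    return num / (yc**2).sum()


class TestComputeINT:
    def test_alternating_signal_gives_zero(self):
        y = np.array([1.0, -1.0] * 10)
        val, n = compute_int(y, tr=0.8)
        assert val == 0.0 and n == 0

    def test_constant_signal_raises(self):
        with pytest.raises(DegenerateSignalError):
            compute_int(np.full(10, 2.0), tr=1.0)

    def test_fft_acf_matches_direct_sums(self, rng):
        y = rng.normal(size=50)
        _, n = compute_int(y, tr=1.0)
        # reconstruct: sum of oracle acf over lags 1..n equals INT / tr
        val, _ = compute_int(y, tr=1.0)
        direct = sum(acf_oracle(y, k) for k in range(1, n + 1))
        assert val == pytest.approx(direct, rel=1e-9)
        assert acf_oracle(y, n + 1) < 0  # first excluded lag is negative

    def test_ar1_recovers_population_timescale(self):
        # population INT for AR(1): tr * rho / (1 - rho) = 0.8 * 1.5 = 1.2
        rng = np.random.default_rng(5)
        rho, tr = 0.6, 0.8
        y = np.empty(20000)
        y[0] = rng.normal()
        eps = rng.normal(size=20000)
        for t in range(1, 20000):
            y[t] = rho * y[t - 1] + eps[t]
        val, _ = compute_int(y, tr=tr)
        assert val == pytest.approx(tr * rho / (1 - rho), rel=0.15)

    def test_iid_noise_has_short_memory(self):
        rng = np.random.default_rng(99)
        tr = 1.0
        hits = sum(
            compute_int(rng.normal(size=10_000), tr=tr)[0] < 3 * tr for _ in range(100)
        )
        assert hits >= 95


class TestAggregateINT:
    def test_identity_and_mean(self):
        assert aggregate_int(np.array([1.0, 3.0]), ["a", "a"]) == {"a": 2.0}
        assert aggregate_int(np.array([1.0, 3.0]), ["a", "b"]) == {"a": 1.0, "b": 3.0}

    def test_matches_groupby_oracle(self, rng):
        import pandas as pd

        vals = rng.normal(size=50)
        labels = [f"roi{int(i)}" for i in rng.integers(0, 5, size=50)]
        got = aggregate_int(vals, labels)
        expected = pd.Series(vals).groupby(labels).mean()
        for roi, mean in expected.items():
            assert got[roi] == pytest.approx(mean)

    def test_missing_roi_raises(self):
        with pytest.raises(ValueError, match="roiX"):
            aggregate_int(np.array([1.0]), ["a"], roi_ids=["a", "roiX"])


def spearman_oracle(a, b):
    """Average-rank Spearman by explicit ranking + Pearson."""

    def avg_ranks(x):
        order = np.argsort(x, kind="stable")
        ranks = np.empty(len(x))
        i = 0
        sx = x[order]
        while i < len(x):
            j = i
            while j + 1 < len(x) and sx[j + 1] == sx[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    ra, rb = avg_ranks(np.asarray(a)), avg_ranks(np.asarray(b))
    ra, rb = ra - ra.mean(), rb - rb.mean()
    return (ra * rb).sum() / np.sqrt((ra * ra).sum() * (rb * rb).sum())


class TestCoupling:
    def _pair(self, fc_rows, sc_rows):
        q = fc_rows.shape[0]
        fc = FunctionalConnectome(values=fc_rows, roi_ids=[str(i) for i in range(q)])
        sc = StructuralConnectome(values=sc_rows, gm_volumes=np.ones(q))
        return sc, fc

    def test_monotone_transform_gives_one(self):
        sc_m = np.array([[0, 1, 2, 3], [1, 0, 4, 5], [2, 4, 0, 6], [3, 5, 6, 0.0]])
        fc_m = np.tanh(sc_m)  # strictly increasing transform
        np.fill_diagonal(fc_m, 1.0)
        fc_m = (fc_m + fc_m.T) / 2
        rho = compute_coupling(*self._pair(fc_m, sc_m))
        np.testing.assert_allclose(rho, 1.0)

    def test_rank_reversal_gives_minus_one(self):
        sc_m = np.array([[0, 1, 2, 3], [1, 0, 4, 5], [2, 4, 0, 6], [3, 5, 6, 0.0]])
        fc_m = -sc_m.copy()
        np.fill_diagonal(fc_m, 1.0)
        rho = compute_coupling(*self._pair(fc_m, sc_m))
        np.testing.assert_allclose(rho, -1.0)

    def test_ties_match_average_rank_oracle(self, rng):
        q = 7
        sc_m = np.round(np.abs(rng.normal(size=(q, q))), 1)  # rounding makes ties
        sc_m = sc_m + sc_m.T
        np.fill_diagonal(sc_m, 0.0)
        fc_m = np.round(rng.uniform(-1, 1, size=(q, q)), 1)
        fc_m = (fc_m + fc_m.T) / 2
        np.fill_diagonal(fc_m, 1.0)
        rho = compute_coupling(*self._pair(fc_m, sc_m))
        for i in range(q):
            keep = np.arange(q) != i
            assert rho[i] == pytest.approx(
                spearman_oracle(sc_m[i, keep], fc_m[i, keep]), abs=1e-12
            )

    def test_constant_profile_error_and_zero_modes(self):
        sc_m = np.zeros((3, 3))
        fc_m = np.eye(3)
        sc, fc = self._pair(fc_m, sc_m)
        with pytest.raises(DegenerateSignalError):
            compute_coupling(sc, fc, on_constant="error")
        with pytest.warns(RuntimeWarning):
            rho = compute_coupling(sc, fc, on_constant="zero")
        np.testing.assert_array_equal(rho, 0.0)


class TestNormalizeAS:
    def test_constant_column_raises(self, rng):
        table = np.column_stack([rng.normal(size=4), np.full(4, 2.0)])
        with pytest.raises(DegenerateRangeError, match="column 1"):
            normalize_as(table)

    def test_positive_column_preserves_rank_order(self, rng):
        col = rng.uniform(1, 100, size=8)[:, None]
        out = normalize_as(col)[:, 0]
        np.testing.assert_array_equal(np.argsort(out), np.argsort(col[:, 0]))

    def test_mixed_sign_matches_signed_log_oracle(self, rng):
        col = rng.normal(scale=5, size=9)
        out = normalize_as(col[:, None])[:, 0]
        t = np.sign(col) * np.log1p(np.abs(col))
        expected = (t - t.min()) / (t.max() - t.min())
        np.testing.assert_allclose(out, expected, atol=1e-12)


class TestAssembleAS:
    def test_two_roi_toy_layout(self):
        stats = np.array([[0.1] * 9, [0.9] * 9])
        out = assemble_as(stats, np.array([1.0, 2.0]), np.array([0.5, -0.5]))
        assert out.values.shape == (2, 11)
        assert out.feature_names[-2:] == ["int", "coupling"]
        assert out.values[:, 9].tolist() == [0.0, 1.0]  # scaled INT

    def test_column_count_is_input_plus_two(self, rng):
        stats = rng.uniform(size=(4, 6))
        out = assemble_as(stats, rng.normal(size=4), rng.uniform(-1, 1, 4))
        assert out.n_features == 8

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            assemble_as(rng.uniform(size=(4, 9)), rng.normal(size=3), rng.normal(size=4))


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    @given(
        arrays(
            float,
            st.integers(3, 12),
            elements=st.floats(-1e6, 1e6, allow_nan=False, width=64),
        )
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_minmax_scale_bounds_property(values):
        """Whenever scaling is defined, the output spans exactly [0, 1]
        and applying the operation twice changes nothing."""
        if np.ptp(values) == 0:
            with pytest.raises(DegenerateRangeError):
                minmax_scale(values)
            return
        out = minmax_scale(values)
        assert out.min() == pytest.approx(0.0) and out.max() == pytest.approx(1.0)
        np.testing.assert_allclose(minmax_scale(out), out, atol=1e-12)

except ImportError:  # pragma: no cover - hypothesis is an optional test extra
    pass
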