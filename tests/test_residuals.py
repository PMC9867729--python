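"""Residual transformations: hand-computed values and invariances."""

import numpy as np
import pytest
from conftest import chi2_oracle, random_table

from cellca import (
    CountMatrix,
    compute_weights,
    drop_empty,
    freeman_tukey_residuals,
    indexed_residuals,
    pearson_residuals,
    power_deflate,
    residuals_for,
    vst_transform,
)


class TestWeights:
    def test_uniform_table_symmetry(self, uniform2):
        w = compute_weights(uniform2)
        assert w.N == 4.0
        np.testing.assert_allclose(w.row_w, [0.5, 0.5])
        np.testing.assert_allclose(w.col_w, [0.5, 0.5])

    def test_diagonal_table_marginals(self, diag2):
        w = compute_weights(diag2)
        assert w.N == 4.0
        np.testing.assert_allclose(w.P, [[0.5, 0.0], [0.0, 0.5]])
        np.testing.assert_allclose(w.row_w, [0.5, 0.5])
        np.testing.assert_allclose(w.col_w, [0.5, 0.5])

    def test_weights_sum_to_one(self, rng):
        for _ in range(5):
            w = compute_weights(random_table(rng, 6, 9))
            assert abs(w.P.sum() - 1.0) < 1e-12
            assert abs(w.row_w.sum() - 1.0) < 1e-12
            assert abs(w.col_w.sum() - 1.0) < 1e-12

    def test_zero_margin_names_offender(self):
        X = CountMatrix(
            [[1, 2, 0], [3, 1, 0], [2, 2, 0]],
            ["g1", "g2", "g3"],
            ["c1", "c2", "cbad"],
        )
        with pytest.raises(ValueError, match="cbad"):
            compute_weights(X)


class TestDropEmpty:
    def test_zero_row_removed_rest_unchanged(self):
        X = CountMatrix(
            [[1, 2], [0, 0], [3, 4]], ["g1", "gz", "g3"], ["c1", "c2"]
        )
        out = drop_empty(X)
        assert out.feature_ids == ["g1", "g3"]
        np.testing.assert_array_equal(out.values, [[1, 2], [3, 4]])

    def test_clean_table_passes_through(self, diag2):
        assert drop_empty(diag2) is diag2

    def test_zero_row_and_column(self):
        X = CountMatrix(
            [[1, 0, 2], [0, 0, 0], [3, 0, 4]],
            ["g1", "g2", "g3"],
            ["c1", "c2", "c3"],
        )
        out = drop_empty(X)
        assert out.shape == (2, 2)

    def test_degenerate_result_errors(self):
        X = CountMatrix(
            [[1, 0], [0, 0], [2, 0]], ["a", "b", "c"], ["x", "y"]
        )
        with pytest.raises(ValueError, match="degenerate"):
            drop_empty(X)


class TestVst:
    @pytest.mark.parametrize(
        "mode,x,expected",
        [
            ("sqrt", 4.0, 2.0),
            ("freeman_tukey_counts", 0.0, 1.0),
            ("freeman_tukey_counts", 3.0, np.sqrt(3) + 2.0),
            ("anscombe", 0.0, 2 * np.sqrt(0.375)),
            ("anscombe", 1.0, 2 * np.sqrt(1.375)),
        ],
    )
    def test_closed_forms(self, mode, x, expected):
        X = CountMatrix([[x, 1], [1, 1]], ["a", "b"], ["x", "y"])
        out = vst_transform(X, mode)
        assert out.values[0, 0] == pytest.approx(expected, abs=1e-7)
        assert out.feature_ids == X.feature_ids

    def test_unknown_mode_errors(self, diag2):
        with pytest.raises(ValueError, match="unknown vst"):
            vst_transform(diag2, "log")


class TestPearson:
    def test_independence_gives_zero(self, uniform2):
        np.testing.assert_array_equal(
            pearson_residuals(uniform2).values, np.zeros((2, 2))
        )

    def test_diagonal_hand_values(self, diag2):
        r = pearson_residuals(diag2)
        np.testing.assert_allclose(r.values, [[0.5, -0.5], [-0.5, 0.5]])
        w = compute_weights(diag2)
        assert w.N * (r.values**2).sum() == pytest.approx(
            chi2_oracle(diag2.values)
        )

    def test_total_inertia_is_chi_squared(self, rng):
        for _ in range(10):
            X = random_table(rng, 8, 12)
            r = pearson_residuals(X).values
            chi2 = X.values.sum() * (r**2).sum()
            assert chi2 == pytest.approx(chi2_oracle(X.values), rel=1e-8)

    def test_scale_invariance(self, rng):
        X = random_table(rng, 5, 7)
        base = pearson_residuals(X).values
        for c in (0.1, 7.0, 1000.0):
            scaled = pearson_residuals(X.with_values(c * X.values)).values
            np.testing.assert_allclose(scaled, base, atol=1e-12)

    def test_rank_one_table_centered_to_zero(self, rng):
        a = rng.uniform(0.5, 2.0, size=6)
        b = rng.uniform(0.5, 2.0, size=4)
        X = CountMatrix(
            np.outer(a, b),
            [f"g{i}" for i in range(6)],
            [f"c{j}" for j in range(4)],
        )
        np.testing.assert_allclose(
            pearson_residuals(X).values, 0.0, atol=1e-12
        )

    def test_weighted_centering(self, rng):
        X = random_table(rng, 6, 9)
        w = compute_weights(X)
        r = pearson_residuals(X).values
        np.testing.assert_allclose(
            (np.sqrt(w.row_w)[:, None] * r).sum(axis=0), 0.0, atol=1e-10
        )
        np.testing.assert_allclose(
            (r * np.sqrt(w.col_w)[None, :]).sum(axis=1), 0.0, atol=1e-10
        )


class TestFreemanTukey:
    def test_uniform_table_value(self, uniform2):
        # sqrt(.25) + sqrt(.25 + .25) - sqrt(4*.0625 + .25)
        expected = np.sqrt(0.25) + np.sqrt(0.5) - np.sqrt(1.25)
        r = freeman_tukey_residuals(uniform2)
        np.testing.assert_allclose(r.values, expected)
        assert expected == pytest.approx(0.0890728, abs=1e-7)

    def test_shrinks_toward_hellinger_limit(self, uniform2):
        big = uniform2.with_values(100.0 * uniform2.values)
        r = freeman_tukey_residuals(big)
        np.testing.assert_allclose(r.values, 0.0012446, atol=1e-7)

    def test_diagonal_hand_values(self, diag2):
        r = freeman_tukey_residuals(diag2)
        # p = 0.5 (diag) or 0 (off); expected 0.25; N = 4
        diag = np.sqrt(0.5) + np.sqrt(0.75) - np.sqrt(1.25)
        off = np.sqrt(0.25) - np.sqrt(1.25)
        np.testing.assert_allclose(
            r.values, [[diag, off], [off, diag]], atol=1e-12
        )
        assert diag == pytest.approx(0.4550982, abs=1e-7)
        assert off == pytest.approx(-0.6180340, abs=1e-7)

    def test_monotone_convergence_in_scale(self, rng):
        X = random_table(rng, 5, 6, low=1, high=9)
        w = compute_weights(X)
        limit = 2 * (np.sqrt(w.P) - np.sqrt(w.expected()))
        prev = None
        for c in (1.0, 10.0, 100.0, 1000.0):
            r = freeman_tukey_residuals(X.with_values(c * X.values)).values
            gap = np.abs(r - limit).max()
            if prev is not None:
                assert gap < prev
            prev = gap
        assert prev < 1e-3


class TestIndexed:
    def test_interpretation_fifty_percent_excess(self):
        # build a table whose (0,0) cell sits 50% above expectation
        X = CountMatrix(
            [[3.0, 1.0], [1.0, 3.0]], ["g1", "g2"], ["c1", "c2"]
        )
        w = compute_weights(X)
        r = indexed_residuals(X).values
        np.testing.assert_allclose(
            w.P, (1.0 + r) * w.expected(), atol=1e-12
        )
        assert r[0, 0] == pytest.approx(0.5)

    def test_independence_gives_zero(self, uniform2):
        np.testing.assert_array_equal(
            indexed_residuals(uniform2).values, np.zeros((2, 2))
        )

    def test_diagonal_hand_values(self, diag2):
        np.testing.assert_allclose(
            indexed_residuals(diag2).values, [[1, -1], [-1, 1]]
        )

    def test_scale_invariance(self, rng):
        X = random_table(rng, 5, 7)
        base = indexed_residuals(X).values
        scaled = indexed_residuals(X.with_values(42.0 * X.values)).values
        np.testing.assert_allclose(scaled, base, atol=1e-12)


class TestPowerDeflate:
    def test_identity_at_alpha_one(self, diag2):
        r = pearson_residuals(diag2)
        out = power_deflate(r, 1.0)
        np.testing.assert_array_equal(out.values, r.values)

    def test_hand_value(self, diag2):
        r = pearson_residuals(diag2)
        out = power_deflate(r, 0.9)
        assert out.values[0, 0] == pytest.approx(0.535887, abs=1e-6)
        assert out.values[0, 1] == pytest.approx(-0.535887, abs=1e-6)
        assert out.alpha == 0.9

    def test_preserves_sign_zero_and_order(self, rng):
        vals = rng.normal(size=(6, 8))
        vals[0, 0] = 0.0
        from cellca import ResidualMatrix

        r = ResidualMatrix(
            vals, "pearson",
            [f"g{i}" for i in range(6)], [f"c{j}" for j in range(8)],
        )
        out = power_deflate(r, 0.7).values
        assert out[0, 0] == 0.0
        np.testing.assert_array_equal(np.sign(out), np.sign(vals))
        flat_in, flat_out = np.abs(vals).ravel(), np.abs(out).ravel()
        np.testing.assert_array_equal(
            np.argsort(flat_in), np.argsort(flat_out)
        )

    @pytest.mark.parametrize("alpha", [0.0, -0.5, 1.5])
    def test_alpha_out_of_range(self, diag2, alpha):
        with pytest.raises(ValueError, match="alpha"):
            power_deflate(pearson_residuals(diag2), alpha)


class TestPipelineComposition:
    def test_vst_then_pearson_inertia_of_transformed_table(self, rng):
        X = random_table(rng, 6, 8)
        res = residuals_for(X, kind="pearson", vst="anscombe")
        transformed = vst_transform(X, "anscombe")
        chi2 = transformed.values.sum() * (res.values**2).sum()
        assert chi2 == pytest.approx(
            chi2_oracle(transformed.values), rel=1e-8
        )
        assert res.vst == "anscombe"

    def test_relabeling_equivariance(self, rng):
        X = random_table(rng, 6, 6)
        perm = rng.permutation(6)
        permuted = CountMatrix(
            X.values[np.ix_(perm, perm)],
            [X.feature_ids[i] for i in perm],
            [X.cell_ids[j] for j in perm],
        )
        for kind in ("pearson", "freeman_tukey", "indexed"):
            base = residuals_for(X, kind=kind).values
            moved = residuals_for(permuted, kind=kind).values
            np.testing.assert_allclose(
                moved, base[np.ix_(perm, perm)], atol=1e-12
            )
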