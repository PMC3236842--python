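import shutil
import subprocess

import numpy as np
import pytest
from scipy import stats

import geonorm as gn
from geonorm.errors import StateError

from conftest import make_matrix


def brute_force_qn(values):
    """Explicit sort/average/substitute quantile normalization (complete data).

    Ties receive the mean of their tied ranks' reference values.
    """
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(m):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        mapped = np.empty(n)
        i = 0
        while i < n:
            k = i
            while k + 1 < n and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            mapped[i : k + 1] = reference[i : k + 1].mean()
            i = k + 1
        out[order, j] = mapped
    return out


class TestQuantileNormalize:
    def test_hand_computed_two_columns(self):
        m = make_matrix([[1, 2], [2, 4], [3, 6]], state="scaled")
        normalized, reference = gn.quantile_normalize(m)
        np.testing.assert_allclose(reference, [1.5, 3.0, 4.5])
        np.testing.assert_allclose(
            normalized.values, [[1.5, 1.5], [3.0, 3.0], [4.5, 4.5]]
        )
        assert normalized.state == "normalized"

    def test_identical_columns_fixed_point(self):
        col = np.array([[5.0], [1.0], [9.0], [3.0]])
        m = make_matrix(np.hstack([col, col, col]), state="scaled")
        normalized, _ = gn.quantile_normalize(m)
        np.testing.assert_allclose(normalized.values, m.values, atol=1e-12)

    def test_tie_rule_mean_of_tied_reference_values(self):
        m = make_matrix([[1, 1], [1, 2], [2, 3]], state="scaled")
        normalized, reference = gn.quantile_normalize(m)
        # column 0 ties at ranks 1-2: both get mean(reference[0:2])
        expected = reference[:2].mean()
        np.testing.assert_allclose(normalized.values[:2, 0], [expected, expected])

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            shape = (rng.integers(2, 11), rng.integers(2, 11))
            values = np.round(rng.uniform(0, 100, shape), 1)  # rounding makes ties
            m = make_matrix(values, state="scaled")
            normalized, _ = gn.quantile_normalize(m)
            np.testing.assert_allclose(
                normalized.values, brute_force_qn(values), rtol=1e-9
            )

    def test_columns_share_sorted_values_and_ranks_preserved(self):
        rng = np.random.default_rng(5)
        values = rng.lognormal(4, 1, (60, 8))
        m = make_matrix(values, state="scaled")
        normalized, _ = gn.quantile_normalize(m)
        sorted_first = np.sort(normalized.values[:, 0])
        for j in range(1, 8):
            np.testing.assert_allclose(
                np.sort(normalized.values[:, j]), sorted_first, rtol=1e-9
            )
            rho = stats.spearmanr(values[:, j], normalized.values[:, j]).statistic
            assert rho == pytest.approx(1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        m = make_matrix(rng.uniform(0, 1e4, (40, 6)), state="scaled")
        once, _ = gn.quantile_normalize(m)
        twice, _ = gn.quantile_normalize(once.with_values(once.values, "scaled"))
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-9)

    def test_missing_values_interpolated_consistently(self):
        rng = np.random.default_rng(7)
        values = rng.uniform(0, 100, (50, 6))
        values[rng.random(values.shape) < 0.2] = np.nan
        m = make_matrix(values, state="scaled")
        normalized, _ = gn.quantile_normalize(m)
        # missingness pattern untouched
        np.testing.assert_array_equal(np.isnan(values), normalized.mask)
        # columns with equal non-missing counts share sorted values
        counts = (~normalized.mask).sum(axis=0)
        for j in range(6):
            for k in range(j + 1, 6):
                if counts[j] == counts[k]:
                    a = np.sort(normalized.values[~normalized.mask[:, j], j])
                    b = np.sort(normalized.values[~normalized.mask[:, k], k])
                    np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_requires_scaled_state(self):
        m = make_matrix([[1.0, 2.0], [3.0, 4.0]], state="raw")
        with pytest.raises(StateError):
            gn.quantile_normalize(m)

    def test_frozen_reference_projection(self):
        rng = np.random.default_rng(8)
        m = make_matrix(rng.uniform(0, 1, (20, 3)), state="scaled")
        _, reference = gn.quantile_normalize(m)
        m2 = make_matrix(rng.uniform(0, 1, (20, 2)), state="scaled")
        projected, ref_back = gn.quantile_normalize(m2, reference)
        np.testing.assert_array_equal(ref_back, reference)
        np.testing.assert_allclose(
            np.sort(projected.values[:, 0]), np.sort(reference), rtol=1e-9
        )

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_limma_normalize_quantiles(self, tmp_path):
        """Independent oracle: limma::normalizeQuantiles on a tie-free matrix."""
        rng = np.random.default_rng(21)
        values = rng.uniform(0, 1000, (30, 5))
        infile, outfile = tmp_path / "in.csv", tmp_path / "out.csv"
        np.savetxt(infile, values, delimiter=",")
        script = (
            f"m <- as.matrix(read.csv('{infile}', header=FALSE));"
            "suppressMessages(library(limma));"
            f"write.table(normalizeQuantiles(m), '{outfile}',"
            "sep=',', row.names=FALSE, col.names=FALSE)"
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        expected = np.loadtxt(outfile, delimiter=",")
        normalized, _ = gn.quantile_normalize(make_matrix(values, state="scaled"))
        np.testing.assert_allclose(normalized.values, expected, rtol=1e-8)


class TestComparePrePost:
    def test_identical_matrices_r2_one(self):
        m = make_matrix(np.random.default_rng(0).uniform(0, 1, (10, 4)))
        assert gn.compare_pre_post(m, m) == pytest.approx(1.0)

    def test_affine_transform_r2_one(self):
        m = make_matrix(np.random.default_rng(1).uniform(0, 1, (10, 4)))
        m2 = m.with_values(2.0 * m.values + 7.0, m.state)
        assert gn.compare_pre_post(m, m2) == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self):
        a = make_matrix(np.ones((3, 2)))
        b = make_matrix(np.ones((2, 2)), gene_ids=[1, 2])
        with pytest.raises(ValueError, match="shape"):
            gn.compare_pre_post(a, b)


class TestReferenceIO:
    def test_roundtrip(self, tmp_path):
        reference = np.sort(np.random.default_rng(2).uniform(0, 1e4, 50))
        path = str(tmp_path / "ref.tsv")
        gn.normalize.save_reference(reference, path)
        np.testing.assert_array_equal(gn.normalize.load_reference(path), reference)
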