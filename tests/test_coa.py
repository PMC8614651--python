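import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from cubscan.coa import correspondence_analysis, project_groups


def random_table(rng, n_rows=8, n_cols=10):
    X = rng.integers(1, 30, size=(n_rows, n_cols)).astype(float)
    return pd.DataFrame(X,
                        index=[f"r{i}" for i in range(n_rows)],
                        columns=[f"c{j}" for j in range(n_cols)])


class TestCorrespondenceAnalysis:
    def test_identical_rows_zero_inertia(self):
        X = pd.DataFrame([[1.0, 2.0, 3.0]] * 4)
        res = correspondence_analysis(X)
        assert res.total_inertia == pytest.approx(0.0, abs=1e-12)
        assert res.row_coords.shape[1] == 0

    def test_diagonal_2x2(self):
        X = pd.DataFrame([[2.0, 0.0], [0.0, 2.0]], index=["a", "b"])
        res = correspondence_analysis(X)
        assert len(res.singular_values) == 1
        f1 = res.row_coords["f1"]
        assert f1["a"] == pytest.approx(-f1["b"])
        assert abs(f1["a"]) > 0

    def test_total_inertia_equals_chi2_over_total(self, rng):
        for _ in range(100):
            X = random_table(rng)
            res = correspondence_analysis(X)
            chi2 = chi2_contingency(X.values, correction=False)[0]
            assert res.total_inertia == pytest.approx(
                chi2 / X.values.sum(), abs=1e-9)

    def test_inertia_fractions_sum_to_one(self, rng):
        res = correspondence_analysis(random_table(rng))
        assert res.inertias.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(res.singular_values) <= 1e-12)
        assert np.sum(res.singular_values ** 2) == pytest.approx(
            res.total_inertia, abs=1e-12)

    def test_transition_formula(self, rng):
        # row coords = (1/sv) * profile-weighted average of column coords
        X = random_table(rng, 6, 7)
        res = correspondence_analysis(X)
        profiles = X.values / X.values.sum(axis=1, keepdims=True)
        for a, axis in enumerate(res.row_coords.columns):
            sv = res.singular_values[a]
            reconstructed = profiles @ res.col_coords[axis].values / sv
            assert np.allclose(reconstructed, res.row_coords[axis].values,
                               atol=1e-8)

    def test_row_permutation_equivariance(self, rng):
        X = random_table(rng, 6, 7)
        res = correspondence_analysis(X)
        perm = ["r3", "r0", "r5", "r1", "r4", "r2"]
        res_p = correspondence_analysis(X.loc[perm])
        # same axes up to sign
        for axis in res.row_coords.columns:
            a = res.row_coords[axis].loc[perm].values
            b = res_p.row_coords[axis].values
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)
        assert np.allclose(np.abs(res.col_coords.values),
                           np.abs(res_p.col_coords.values), atol=1e-8)

    def test_axis_sign_invariant_summaries(self, rng):
        # pairwise row distances don't depend on any axis's sign convention
        X = random_table(rng, 5, 6)
        res = correspondence_analysis(X, n_axes=4)
        coords = res.row_coords.values
        flipped = coords * np.array([1, -1, 1, -1][:coords.shape[1]])
        d0 = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        d1 = np.linalg.norm(flipped[:, None] - flipped[None, :], axis=-1)
        assert np.allclose(d0, d1)

    def test_all_zero_column_dropped(self, rng):
        X = random_table(rng, 5, 6)
        X["c2"] = 0.0
        with pytest.warns(UserWarning, match="all-zero"):
            res = correspondence_analysis(X)
        assert "c2" not in res.col_coords.index

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            correspondence_analysis(pd.DataFrame([[1.0, -1.0], [1.0, 1.0]]))

    def test_matches_independent_ca_implementation(self, rng):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        X = random_table(rng, 7, 9)
        res = correspondence_analysis(X, n_axes=3)
        ref = skbio_ord.ca(X, scaling=1)
        ref_coords = ref.samples.values[:, :3]
        for a in range(3):
            mine = res.row_coords.values[:, a]
            theirs = ref_coords[:, a]
            assert (np.allclose(mine, theirs, atol=1e-8)
                    or np.allclose(mine, -theirs, atol=1e-8))
        assert np.allclose(ref.proportion_explained.values[:3],
                           res.inertias[:3], atol=1e-10)


class TestProjectGroups:
    def test_single_group_is_weighted_mean(self, rng):
        X = random_table(rng, 5, 6)
        res = correspondence_analysis(X)
        groups = pd.Series(["g"] * 5, index=X.index)
        cent = project_groups(res, groups)
        w = res.row_masses.values
        expected = (res.row_coords.values * w[:, None]).sum(0) / w.sum()
        assert np.allclose(cent.loc["g"].values, expected)

    def test_singleton_group_equals_row(self, rng):
        X = random_table(rng, 4, 5)
        res = correspondence_analysis(X)
        groups = pd.Series(["a", "b", "b", "b"], index=X.index)
        cent = project_groups(res, groups)
        assert np.allclose(cent.loc["a"].values,
                           res.row_coords.loc["r0"].values)

    def test_unknown_rows_error(self, rng):
        X = random_table(rng, 4, 5)
        res = correspondence_analysis(X)
        groups = pd.Series(["a"], index=["r0"])
        with pytest.raises(KeyError):
            project_groups(res, groups)
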