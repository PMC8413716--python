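"""Eigengenes, trait correlations and cross-network label matching."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import devcoex as dx
from devcoex.modstats import pearson_with_p


def _module_matrix(genes, samples=None):
    idx = [f"g{i}" for i in range(len(genes))]
    cols = samples or [f"s{i}" for i in range(len(genes[0]))]
    return pd.DataFrame(genes, index=idx, columns=cols)


class TestModuleEigengenes:
    def test_rank_one_module_explains_everything(self):
        base = np.sin(np.linspace(0, 6, 12))
        # affine copies of one pattern
        matrix = _module_matrix([base, 2 * base + 1, 0.5 * base - 3, base + 10])
        ass = pd.Series([1] * 4, index=matrix.index)
        mes = dx.module_eigengenes(matrix, ass)
        assert mes.variance_explained[1] == pytest.approx(1.0)
        for g in matrix.index:
            r = np.corrcoef(mes.eigengenes["ME1"], matrix.loc[g])[0, 1]
            assert abs(r) == pytest.approx(1.0)

    def test_orientation_follows_mean_profile(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=20)
        matrix = _module_matrix([base + rng.normal(0, 0.1, 20) for _ in range(6)])
        ass = pd.Series([1] * 6, index=matrix.index)
        me = dx.module_eigengenes(matrix, ass).eigengenes["ME1"]
        assert np.corrcoef(me, base)[0, 1] > 0.9
        flipped = dx.module_eigengenes(-matrix, ass).eigengenes["ME1"]
        # jointly negated data has a negated mean profile: ME flips with it
        np.testing.assert_allclose(flipped, -me, atol=1e-8)

    def test_affine_gene_transforms_leave_me_unchanged(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=15)
        rows = [base + rng.normal(0, 0.2, 15) for _ in range(5)]
        matrix = _module_matrix(rows)
        ass = pd.Series([1] * 5, index=matrix.index)
        me1 = dx.module_eigengenes(matrix, ass).eigengenes["ME1"]
        scaled = matrix.mul([2.0, 5.0, 0.1, 3.0, 7.0], axis=0).add(
            [10, -4, 0, 2, 1], axis=0
        )
        me2 = dx.module_eigengenes(scaled, ass).eigengenes["ME1"]
        np.testing.assert_allclose(me1, me2, atol=1e-8)

    def test_two_orthogonal_patterns_split_variance_evenly(self):
        t = np.arange(16.0)
        a = np.cos(2 * np.pi * t / 16)
        b = np.sin(2 * np.pi * t / 16)  # orthogonal, equal variance
        matrix = _module_matrix([a, a, b, b])
        ass = pd.Series([1] * 4, index=matrix.index)
        mes = dx.module_eigengenes(matrix, ass)
        assert mes.variance_explained[1] == pytest.approx(0.5, abs=1e-9)

    def test_unit_variance_eigengenes(self, small_study):
        _, matrix, _, truth = small_study
        mes = dx.module_eigengenes(matrix, truth.assignment)
        for col in mes.eigengenes:
            assert mes.eigengenes[col].std(ddof=1) == pytest.approx(1.0)

    def test_first_pc_dominates_spectrum(self):
        rng = np.random.default_rng(7)
        matrix = _module_matrix(rng.normal(size=(10, 25)))
        ass = pd.Series([1] * 10, index=matrix.index)
        mes = dx.module_eigengenes(matrix, ass)
        X = (matrix - matrix.mean(axis=1).values[:, None]).div(
            matrix.std(axis=1, ddof=1), axis=0
        )
        eigvals = np.linalg.eigvalsh(np.cov(X))
        assert mes.variance_explained[1] == pytest.approx(
            eigvals.max() / eigvals.sum(), abs=1e-9
        )

    def test_single_gene_module_errors(self):
        matrix = _module_matrix(np.random.default_rng(0).normal(size=(3, 8)))
        ass = pd.Series([1, 2, 2], index=matrix.index)
        with pytest.raises(ValueError, match="module 1"):
            dx.module_eigengenes(matrix, ass)


class TestTraitCorrelation:
    def _mes(self, me):
        return dx.EigengeneSet(
            eigengenes=pd.DataFrame({"ME1": me}),
            variance_explained=pd.Series({1: 0.9}),
        )

    def test_trait_equal_to_me_has_unit_correlation(self):
        me = np.random.default_rng(0).normal(size=40)
        samples = pd.DataFrame({"t": me})
        table = dx.eigengene_trait_correlation(self._mes(me), samples, traits=["t"])
        assert table.r.iloc[0] == pytest.approx(1.0)
        assert table.p.iloc[0] == pytest.approx(0.0, abs=1e-30)

    def test_independent_trait_near_zero(self):
        rng = np.random.default_rng(1)
        me = rng.normal(size=2000)
        samples = pd.DataFrame({"t": rng.normal(size=2000)})
        table = dx.eigengene_trait_correlation(self._mes(me), samples, traits=["t"])
        assert abs(table.r.iloc[0]) < 0.08

    def test_p_matches_t_transform(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, 12))
        r, p = pearson_with_p(x, y)
        assert (r, p) == pytest.approx(stats.pearsonr(x, y), abs=1e-12)
        t = r * np.sqrt(10 / (1 - r**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 10), abs=1e-12)

    def test_p_matches_permutation_null(self):
        rng = np.random.default_rng(3)
        me, trait = rng.normal(size=(2, 25))
        r_obs, p_analytic = pearson_with_p(me, trait)
        B = 10_000
        perm = np.array(
            [abs(np.corrcoef(me, rng.permutation(trait))[0, 1]) for _ in range(B)]
        )
        p_perm = (perm >= abs(r_obs)).mean()
        se = np.sqrt(p_analytic * (1 - p_analytic) / B)
        assert abs(p_perm - p_analytic) < 3 * se + 1 / B

    def test_two_level_factor_encoded(self):
        me = np.r_[np.ones(10), -np.ones(10)]
        samples = pd.DataFrame({"sex": ["F"] * 10 + ["M"] * 10})
        table = dx.eigengene_trait_correlation(self._mes(me), samples, traits=["sex"])
        assert table.r.iloc[0] == pytest.approx(-1.0)

    def test_multilevel_factor_expands_to_indicators(self):
        rng = np.random.default_rng(4)
        me = rng.normal(size=30)
        samples = pd.DataFrame({"region": ["DFC", "HIP", "STR"] * 10})
        table = dx.eigengene_trait_correlation(self._mes(me), samples, traits=["region"])
        assert sorted(table.trait) == ["region=DFC", "region=HIP", "region=STR"]

    def test_constant_trait_flagged_and_excluded(self):
        me = np.random.default_rng(5).normal(size=10)
        samples = pd.DataFrame({"flat": [1.0] * 10, "ok": me})
        table = dx.eigengene_trait_correlation(self._mes(me), samples, traits=["flat", "ok"])
        assert table.attrs["excluded_traits"] == ["flat"]
        assert list(table.trait) == ["ok"]


class TestMatchLabels:
    def _series(self, labels, offset=0):
        return pd.Series(labels, index=[f"g{i + offset:03d}" for i in range(len(labels))])

    def test_identity_relabeling(self):
        ref = self._series([1] * 30 + [2] * 20 + [0] * 10)
        out = dx.match_labels(ref, ref)
        pd.testing.assert_series_equal(out, ref.rename("module"))

    def test_disjoint_modules_get_fresh_labels(self):
        ref = self._series([1] * 30 + [0] * 70)
        test = self._series([0] * 60 + [1] * 40)
        out = dx.match_labels(ref, test)
        assert set(out[test == 1]) == {2}  # fresh label after reference max

    def test_strong_overlap_inherits_reference_label(self):
        # 100-gene universe; reference module = genes 0..29,
        # test module = genes 0..24 plus 89..93 -> overlap 25, p tiny
        ref = self._series([1] * 30 + [0] * 70)
        labels = [2] * 25 + [0] * 64 + [2] * 5 + [0] * 6
        test = self._series(labels)
        p = dx.hypergeom_tail(25, 100, 30, 30)
        assert p < 1e-10
        out = dx.match_labels(ref, test)
        assert set(out[test == 2]) == {1}

    def test_idempotent(self):
        ref = self._series([1] * 40 + [2] * 30 + [0] * 30)
        test = self._series([0] * 5 + [3] * 38 + [1] * 27 + [0] * 30)
        once = dx.match_labels(ref, test)
        twice = dx.match_labels(ref, once)
        pd.testing.assert_series_equal(once, twice)

    def test_disjoint_universes_error(self):
        ref = self._series([1] * 10)
        test = self._series([1] * 10, offset=500)
        with pytest.raises(ValueError, match="share no genes"):
            dx.match_labels(ref, test)


def test_merge_similar_modules_collapses_split_module():
    rng = np.random.default_rng(9)
    base = rng.normal(size=40)
    rows = [0.9 * base + 0.2 * rng.normal(size=40) for _ in range(30)]
    matrix = pd.DataFrame(rows, index=[f"g{i:02d}" for i in range(30)])
    # one coherent module artificially split in two
    ass = pd.Series([1] * 15 + [2] * 15, index=matrix.index)
    merged = dx.merge_similar_modules(matrix, ass, cor_threshold=0.8)
    assert merged.nunique() == 1 and set(merged) == {1}
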