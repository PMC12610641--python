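"""PCA identities, loading-vector geometry and hierarchical clustering."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from aromarank.multivariate import (
    PCAResult,
    cluster_heatmap,
    colocalize,
    hcluster,
    joint_pca,
    loading_angle,
    run_pca,
    zscore_rows,
)


def frame(arr, prefix="v"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"s{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


def exactly_correlated_pair(n: int, rho: float, rng: np.random.Generator) -> pd.DataFrame:
    """Two variables whose *sample* correlation matrix is [[1, rho], [rho, 1]]."""
    x = rng.normal(size=(n, 2))
    x -= x.mean(axis=0)
    u, _, _ = np.linalg.svd(x, full_matrices=False)
    z = u * np.sqrt(n - 1)  # whitened: sample covariance = identity
    L = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
    return frame(z @ L.T)


class TestZscoreRows:
    def test_unit_step_row(self):
        z, flags = zscore_rows(pd.DataFrame([[1.0, 2.0, 3.0]], index=["r"]))
        assert z.loc["r"].tolist() == [-1.0, 0.0, 1.0]
        assert flags == []

    def test_constant_row_zeroed_and_flagged(self):
        z, flags = zscore_rows(pd.DataFrame([[5.0, 5.0, 5.0]], index=["r"]))
        assert z.loc["r"].tolist() == [0.0, 0.0, 0.0]
        assert flags == ["r"]

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        m = frame(rng.normal(size=(10, 3)))
        z, _ = zscore_rows(m)
        expected = (m.to_numpy() - m.to_numpy().mean(1, keepdims=True)) / m.to_numpy().std(
            1, ddof=1, keepdims=True
        )
        assert np.allclose(z.to_numpy(), expected, atol=1e-12)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-9)


class TestRunPCA:
    def test_two_variable_correlation_closed_form(self):
        """With correlation rho the ratios are (1+rho)/2 and (1-rho)/2."""
        x = exactly_correlated_pair(30, 0.6, np.random.default_rng(0))
        res = run_pca(x, preprocessing="zscore")
        assert res.explained_variance_ratio == pytest.approx([0.8, 0.2], abs=1e-12)

    def test_collinear_data_is_rank_one(self):
        t = np.arange(6.0)
        x = frame(np.outer(t, [2.0, -1.0, 0.5]))
        res = run_pca(x, preprocessing="center")
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(5)
        x = frame(rng.normal(size=(6, 4)))
        res = run_pca(x, preprocessing="center")
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, x.to_numpy() - x.to_numpy().mean(0), atol=1e-9)

    def test_loadings_orthonormal_and_ratios_valid(self):
        rng = np.random.default_rng(6)
        res = run_pca(frame(rng.normal(size=(8, 5))), preprocessing="zscore")
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)
        r = res.explained_variance_ratio
        assert (np.diff(r) <= 1e-12).all()
        assert ((r >= 0) & (r <= 1)).all()
        assert r.sum() == pytest.approx(1.0, abs=1e-9)

    def test_total_variance_conserved(self):
        rng = np.random.default_rng(7)
        x = frame(rng.normal(size=(7, 4)) * [1, 3, 0.5, 2])
        res = run_pca(x, preprocessing="center")
        centered = x.to_numpy() - x.to_numpy().mean(0)
        trace = np.trace(centered.T @ centered / (len(x) - 1))
        assert res.explained_variance.sum() == pytest.approx(trace, abs=1e-9)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(8)
        x = frame(rng.normal(size=(6, 3)))
        res = run_pca(x)
        for col in res.loadings.columns:
            v = res.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(9)
        x = frame(rng.normal(size=(6, 4)))
        res = run_pca(x, preprocessing="center")
        ref = sk.PCA().fit(x.to_numpy())
        assert np.allclose(
            res.explained_variance_ratio, ref.explained_variance_ratio_, atol=1e-9
        )

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            run_pca(frame(np.ones((1, 3))))


class TestJointPCA:
    def test_duplicated_variable_has_zero_angle(self):
        rng = np.random.default_rng(10)
        v = rng.normal(size=5)
        sens = pd.DataFrame({"fake-attr": v, "other": rng.normal(size=5)},
                            index=[f"s{i}" for i in range(5)])
        comp = pd.DataFrame({"cmp": v, "cmp2": rng.normal(size=5)}, index=sens.index)
        res = joint_pca(sens, comp)
        # in the informative leading plane the two identical variables align
        assert loading_angle(res, "fake-attr", "cmp", 2) == pytest.approx(0, abs=1e-6)

    def test_block_labels_preserved_under_reordering(self):
        rng = np.random.default_rng(11)
        idx = [f"s{i}" for i in range(4)]
        sens = pd.DataFrame(rng.normal(size=(4, 2)), index=idx, columns=["a1", "a2"])
        comp = pd.DataFrame(rng.normal(size=(4, 3)), index=idx, columns=["c1", "c2", "c3"])
        res = joint_pca(sens, comp[["c3", "c1", "c2"]])
        assert res.blocks["a1"] == "sensory"
        assert all(res.blocks[c] == "compound" for c in ("c1", "c2", "c3"))

    def test_sample_mismatch_rejected(self):
        sens = pd.DataFrame(np.ones((3, 2)), index=list("abc"), columns=["x", "y"])
        comp = pd.DataFrame(np.ones((3, 2)), index=list("abd"), columns=["u", "v"])
        with pytest.raises(ValueError, match="sample"):
            joint_pca(sens, comp)

    def test_planted_proportional_pair_recovered_and_monotone(self):
        """A compound built as slope x attribute + sigma*noise co-localizes,
        with theta -> 0 and r -> 1 monotonically as sigma decreases."""
        rng = np.random.default_rng(12)
        idx = ["cv1", "cv2", "cv3"]
        attr = np.array([2.0, 8.0, 4.5])
        other_attr = np.array([7.0, 3.0, 5.0])
        noise = rng.normal(size=3)
        thetas, rs = [], []
        for sigma in (1.5, 0.5, 0.02):
            sens = pd.DataFrame({"target": attr, "other": other_attr}, index=idx)
            comp = pd.DataFrame(
                {"linked": 0.5 * attr + sigma * noise, "free": rng.normal(5, 2, 3)},
                index=idx,
            )
            res = joint_pca(sens, comp)
            coloc = colocalize(res, [("linked", "target")])
            thetas.append(float(coloc.pairs["theta_degrees"][0]))
            rs.append(float(coloc.pairs["pearson_r"][0]))
        assert thetas[0] > thetas[1] > thetas[2]
        assert rs[0] < rs[1] < rs[2]
        assert thetas[2] < 10 and rs[2] > 0.9


class TestColocalize:
    @staticmethod
    def manual_result(loadings: dict[str, list[float]], data: pd.DataFrame) -> PCAResult:
        L = pd.DataFrame(loadings).T
        L.columns = [f"PC{i+1}" for i in range(L.shape[1])]
        n = L.shape[1]
        return PCAResult(
            scores=pd.DataFrame(np.zeros((len(data), n)), index=data.index, columns=L.columns),
            loadings=L,
            explained_variance=np.ones(n),
            explained_variance_ratio=np.ones(n) / n,
            preprocessing="zscore",
            data=data,
        )

    def test_identical_vectors_align_and_orthogonal_vectors_are_90_apart(self):
        data = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 3], "c": [3.0, 1, 2]})
        res = self.manual_result({"a": [0.6, 0.8], "b": [0.6, 0.8], "c": [1.0, 0.0]}, data)
        out = colocalize(res, [("a", "b"), ("c", "b")])
        assert out.pairs["theta_degrees"][0] == pytest.approx(0.0, abs=1e-12)
        res2 = self.manual_result({"a": [1.0, 0.0], "b": [0.0, 1.0]}, data[["a", "b"]])
        out2 = colocalize(res2, [("a", "b")])
        assert out2.pairs["theta_degrees"][0] == pytest.approx(90.0, abs=1e-12)

    def test_angle_matches_arccos_oracle(self):
        rng = np.random.default_rng(13)
        x = frame(rng.normal(size=(6, 5)))
        res = run_pca(x, preprocessing="zscore")
        scale = np.sqrt(res.explained_variance[:2])
        for a, b in itertools.combinations(x.columns, 2):
            va = res.loadings.loc[a].to_numpy()[:2] * scale
            vb = res.loadings.loc[b].to_numpy()[:2] * scale
            expect = np.degrees(
                np.arccos(np.clip(va @ vb / np.linalg.norm(va) / np.linalg.norm(vb), -1, 1))
            )
            assert loading_angle(res, a, b) == pytest.approx(expect, abs=1e-9)

    def test_perfectly_correlated_variables_are_collinear_with_three_samples(self):
        # |r| = 1 implies theta in {0, 180} degrees in the full loading space
        base = np.array([1.0, 4.0, 2.5])
        x = pd.DataFrame(
            {"u": base, "v": 3 * base + 1, "m": -2 * base, "w": [5.0, 1.0, 4.0]},
            index=list("abc"),
        )
        res = run_pca(x, preprocessing="zscore")
        # three samples give a rank-2 loading space: restrict to it
        t_uv = loading_angle(res, "u", "v", 2)
        t_uw = loading_angle(res, "u", "m", 2)
        assert t_uv == pytest.approx(0.0, abs=1e-5)
        assert t_uw == pytest.approx(180.0, abs=1e-5)

    def test_invariant_under_sample_reordering(self):
        rng = np.random.default_rng(14)
        x = frame(rng.normal(size=(5, 4)))
        pairs = [("v0", "v1"), ("v2", "v3")]
        a = colocalize(run_pca(x, "zscore"), pairs)
        x2 = x.iloc[[3, 0, 4, 1, 2]]
        b = colocalize(run_pca(x2, "zscore"), pairs)
        assert np.allclose(a.pairs["theta_degrees"], b.pairs["theta_degrees"], atol=1e-9)
        assert np.allclose(a.pairs["pearson_r"], b.pairs["pearson_r"], atol=1e-9)

    def test_small_sample_caveat_flag(self):
        rng = np.random.default_rng(15)
        x = frame(rng.normal(size=(3, 3)))
        out = colocalize(run_pca(x, "zscore"), [("v0", "v1")])
        assert bool(out.pairs["small_n"][0])


def brute_force_average_linkage(points: np.ndarray):
    """Exhaustive agglomeration: merge the pair of clusters with the smallest
    mean inter-point distance; record (member-set pair, height) per step."""
    D = squareform(pdist(points))
    members = {i: frozenset([i]) for i in range(len(points))}
    merges = []
    nxt = len(points)
    while len(members) > 1:
        best = None
        for a, b in itertools.combinations(sorted(members), 2):
            d = float(np.mean([D[i, j] for i in members[a] for j in members[b]]))
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merges.append(({members[a], members[b]}, d))
        members[nxt] = members[a] | members[b]
        del members[a], members[b]
        nxt += 1
    return merges


class TestHcluster:
    def test_close_pair_merges_first(self):
        m = pd.DataFrame({"x": [0.0, 1.0, 11.0]}, index=["a", "b", "c"])
        order, Z = hcluster(m, axis=0)
        assert set(Z[0, :2].astype(int)) == {0, 1}
        assert (np.diff(Z[:, 2]) >= 0).all()

    def test_duplicate_rows_merge_at_height_zero(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 9.0]])
        _, Z = hcluster(m, axis=0)
        assert Z[0, 2] == 0.0

    def test_nonfinite_distance_rejected(self):
        m = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="non-finite"):
            hcluster(m, axis=0)

    def test_matches_brute_force_agglomeration(self):
        rng = np.random.default_rng(16)
        pts = rng.normal(size=(8, 4))
        _, Z = hcluster(pd.DataFrame(pts), axis=0, linkage="average")
        oracle = brute_force_average_linkage(pts)
        # replay scipy's merge tree into member sets
        members = {i: frozenset([i]) for i in range(len(pts))}
        for step, row in enumerate(Z):
            a, b, height = int(row[0]), int(row[1]), row[2]
            expect_sets, expect_height = oracle[step]
            assert {members[a], members[b]} == expect_sets
            assert height == pytest.approx(expect_height, abs=1e-9)
            members[len(pts) + step] = members[a] | members[b]


class TestClusterHeatmap:
    def test_rows_standardized_and_orders_are_permutations(self, kadsura_voc):
        sub = kadsura_voc.means.iloc[:12]
        hm = cluster_heatmap(sub)
        z = hm.zmatrix.to_numpy()
        keep = [i for i, r in enumerate(sub.index) if r not in hm.constant_rows]
        assert np.allclose(z[keep].mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z[keep].std(axis=1, ddof=1), 1, atol=1e-9)
        assert sorted(hm.row_order) == list(range(sub.shape[0]))
        assert sorted(hm.col_order) == list(range(sub.shape[1]))
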