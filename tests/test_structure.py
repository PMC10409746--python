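"""Bray-Curtis, PCoA, confidence ellipses, PERMANOVA against oracles."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from dropoutkeys.structure import (
    _pseudo_f,
    bray_curtis,
    confidence_ellipse_outliers,
    ordination,
    pairwise_permanova,
    pcoa,
    permanova,
)
from dropoutkeys.types import ValidationError


def frame(X, prefix="s"):
    return pd.DataFrame(np.asarray(X, float), index=[f"{prefix}{i}" for i in range(len(X))])


class TestBrayCurtis:
    def test_identical_profiles_zero(self):
        bc = bray_curtis(frame([[1, 2, 3], [1, 2, 3]]))
        assert bc.iloc[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        bc = bray_curtis(frame([[1, 0, 2], [0, 3, 0]]))
        assert bc.iloc[0, 1] == 1.0

    def test_hand_example(self):
        bc = bray_curtis(frame([[6, 0, 2], [2, 4, 0]]))
        assert bc.iloc[0, 1] == pytest.approx(1 - 4 / 14)  # 0.714286

    def test_matches_scipy(self):
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(0)
        X = rng.lognormal(0, 1, (8, 12))
        bc = bray_curtis(frame(X))
        ref = squareform(pdist(X, metric="braycurtis"))
        np.testing.assert_allclose(bc.to_numpy(), ref, atol=1e-12)

    def test_all_zero_sample_named(self):
        with pytest.raises(ValidationError, match="s1"):
            bray_curtis(frame([[1, 2], [0, 0]]))

    def test_semimetric_properties(self):
        rng = np.random.default_rng(1)
        bc = bray_curtis(frame(rng.lognormal(0, 1, (10, 5)))).to_numpy()
        assert np.allclose(bc, bc.T)
        assert np.all(np.diag(bc) == 0)
        assert bc.min() >= 0 and bc.max() <= 1


class TestPCoA:
    def test_two_samples_closed_form(self):
        d = 0.42
        bc = pd.DataFrame([[0, d], [d, 0]], index=["a", "b"], columns=["a", "b"])
        coords, evals, prop = pcoa(bc)
        assert coords.shape[1] == 1
        np.testing.assert_allclose(np.abs(coords.iloc[:, 0]), d / 2, atol=1e-12)
        assert prop[0] == pytest.approx(1.0)

    def test_line_embedding_recovers_distances(self):
        x = np.array([0.0, 1.0, 2.5, 4.0, 7.0])
        D = np.abs(x[:, None] - x[None, :])
        bc = pd.DataFrame(D, index=list("abcde"), columns=list("abcde"))
        coords, _, _ = pcoa(bc)
        rec = np.sqrt(((coords.to_numpy()[:, None, :] - coords.to_numpy()[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(rec, D, atol=1e-9)

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        X = rng.lognormal(0, 1, (6, 4))
        bc = bray_curtis(frame(X))
        coords, _, _ = pcoa(bc)
        perm = ["s3", "s0", "s5", "s1", "s4", "s2"]
        coords_p, _, _ = pcoa(bc.loc[perm, perm])
        np.testing.assert_allclose(coords_p.to_numpy(), coords.loc[perm].to_numpy(), atol=1e-9)

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        X = rng.lognormal(0, 1, (9, 6))
        bc = bray_curtis(frame(X))
        coords, evals, _ = pcoa(bc)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(bc.to_numpy(), ids=list(bc.index)))
        k = coords.shape[1]
        np.testing.assert_allclose(
            np.abs(coords.to_numpy()), np.abs(ref.samples.to_numpy()[:, :k]), atol=1e-8
        )
        np.testing.assert_allclose(evals[:k], ref.eigvals.to_numpy()[:k], atol=1e-8)

    def test_asymmetric_rejected(self):
        bad = pd.DataFrame([[0, 1], [0.5, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValidationError):
            pcoa(bad)


class TestEllipses:
    def test_centroid_not_outlier_far_point_is(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 1, (30, 2))
        pts[0] = pts[1:].mean(axis=0)  # at the centroid
        pts[-1] = [30.0, 30.0]  # Mahalanobis^2 >> 5.991
        coords = pd.DataFrame(pts, columns=["PCo1", "PCo2"],
                              index=[f"s{i}" for i in range(30)])
        groups = pd.Series("g", index=coords.index)
        ellipses, flags = confidence_ellipse_outliers(coords, groups)
        assert not flags["s0"]
        assert flags["s29"]
        assert ellipses["g"].quantile == pytest.approx(5.991, abs=1e-3)

    def test_outlier_rate_calibration(self):
        """Isotropic Gaussian group: ~5% flagged at the 95% ellipse."""
        rng = np.random.default_rng(5)
        pts = rng.normal(0, 1, (10000, 2))
        coords = pd.DataFrame(pts, columns=["PCo1", "PCo2"],
                              index=[f"s{i}" for i in range(10000)])
        _, flags = confidence_ellipse_outliers(coords, pd.Series("g", index=coords.index))
        rate = flags.mean()
        assert 0.05 - 0.0056 <= rate <= 0.05 + 0.0056  # binomial 99% bounds

    def test_small_group_rejected(self):
        coords = pd.DataFrame([[0, 0], [1, 1]], columns=["PCo1", "PCo2"], index=["a", "b"])
        with pytest.raises(ValidationError):
            confidence_ellipse_outliers(coords, pd.Series("g", index=coords.index))


class TestPermanova:
    def _bc(self, X):
        return bray_curtis(frame(X))

    def test_extreme_separation_minimum_p(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.lognormal(0, 0.05, (5, 4)), rng.lognormal(4, 0.05, (5, 4))])
        bc = self._bc(X)
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=bc.index)
        res = permanova(bc, groups, n_perm=999, seed=0)
        # random label permutations occasionally recreate the same two-group
        # partition and tie F_obs, so p can sit slightly above its floor
        assert 1 / (1 + 999) <= res["p"] <= 0.02

    def test_matches_exhaustive_enumeration(self):
        """5-sample instance: permutation p agrees with the exact null."""
        rng = np.random.default_rng(7)
        X = rng.lognormal(0, 1, (5, 4))
        bc = self._bc(X)
        labels = np.array(["a", "a", "b", "b", "b"])
        groups = pd.Series(labels, index=bc.index)
        D2 = bc.to_numpy() ** 2
        f_obs = _pseudo_f(D2, labels)
        fs = [_pseudo_f(D2, np.array(p)) for p in set(permutations(labels))]
        p_exact = sum(f >= f_obs for f in fs) / len(fs)
        res = permanova(bc, groups, n_perm=9999, seed=1)
        assert res["pseudo_F"] == pytest.approx(f_obs)
        assert res["p"] == pytest.approx(p_exact, abs=0.02)

    def test_matches_skbio_pseudo_f(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(8)
        X = rng.lognormal(0, 1, (12, 6))
        bc = self._bc(X)
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=bc.index)
        dm = skbio.DistanceMatrix(bc.to_numpy(), ids=list(bc.index))
        ref = sk_permanova(dm, groups.to_numpy(), permutations=99)
        res = permanova(bc, groups, n_perm=99, seed=0)
        assert res["pseudo_F"] == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_invariant_to_sample_order_and_label_names(self):
        rng = np.random.default_rng(9)
        X = rng.lognormal(0, 1, (8, 5))
        bc = self._bc(X)
        groups = pd.Series(["a", "a", "a", "a", "b", "b", "b", "b"], index=bc.index)
        res1 = permanova(bc, groups, n_perm=499, seed=3)
        order = list(bc.index[::-1])
        res2 = permanova(bc.loc[order, order], groups, n_perm=499, seed=3)
        assert res1["p"] == res2["p"] and res1["pseudo_F"] == pytest.approx(res2["pseudo_F"])

    def test_single_sample_group_rejected(self):
        rng = np.random.default_rng(10)
        bc = self._bc(rng.lognormal(0, 1, (4, 3)))
        groups = pd.Series(["a", "a", "a", "b"], index=bc.index)
        with pytest.raises(ValidationError, match="b"):
            permanova(bc, groups)

    def test_pairwise_bh_adjusted(self):
        rng = np.random.default_rng(11)
        X = np.vstack([
            rng.lognormal(0, 0.1, (4, 4)),
            rng.lognormal(2, 0.1, (4, 4)),
            rng.lognormal(4, 0.1, (4, 4)),
        ])
        bc = self._bc(X)
        groups = pd.Series(["a"] * 4 + ["b"] * 4 + ["c"] * 4, index=bc.index)
        df = pairwise_permanova(bc, groups, n_perm=199, seed=0)
        assert len(df) == 3
        assert (df["p_adjusted"] >= df["p"]).all()


class TestOrdinationChain:
    def test_full_chain_flags_planted_outlier(self):
        rng = np.random.default_rng(12)
        base = rng.lognormal(0, 0.1, (12, 6))
        base[5] *= 30  # one divergent community profile
        profiles = frame(base)
        res = ordination(profiles, groups=pd.Series("g", index=profiles.index), n_perm=99, seed=0)
        # PERMANOVA skipped (single group) but ellipse flags the outlier
        assert res.outlier_flags is not None
        assert res.outlier_flags["s5"]
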