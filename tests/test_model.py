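"""PCA morphospace, Mahalanobis accuracy index, confidence ellipses, and the
Model/Results interface."""

import numpy as np
import pandas as pd
import pytest

from myrmomorph.efa import EFACoefficients, SpeciesShape
from myrmomorph.model import (
    MimicryAccuracy,
    MorphospaceError,
    accuracy_index,
    confidence_ellipse,
    fit_morphospace,
    mahalanobis_to_ants,
    project,
)


class TestMorphospace:
    def test_rank_two_data_retains_two_components(self, rng):
        # points in a 2-D affine subspace of a 7-D space plus constant dims
        basis = rng.normal(size=(2, 7))
        X = rng.normal(size=(40, 2)) @ basis + rng.normal(size=7)
        model = fit_morphospace(X, 0.95)
        assert model.k_retained == 2
        assert model.cumulative_fraction > 1 - 1e-9

    def test_isotropic_cloud_needs_all_components(self):
        rng = np.random.default_rng(123)
        X = rng.normal(size=(500, 5))
        model = fit_morphospace(X, 0.95)
        # every component carries ~20%, so four of them stay below 95%
        assert model.k_retained == 5

    def test_minimal_prefix(self, rng):
        X = rng.normal(size=(100, 4)) * np.array([10.0, 3.0, 1.0, 0.3])
        model = fit_morphospace(X, 0.95)
        cum = np.cumsum(model.explained_variance_fractions)
        assert cum[-1] >= 0.95 - 1e-9
        if model.k_retained > 1:
            assert cum[-2] < 0.95

    def test_components_orthonormal(self, rng):
        X = rng.normal(size=(30, 6))
        model = fit_morphospace(X, 0.95)
        gram = model.components @ model.components.T
        np.testing.assert_allclose(gram, np.eye(model.k_retained), atol=1e-8)

    def test_fewer_than_two_species_rejected(self):
        with pytest.raises(MorphospaceError):
            fit_morphospace(np.ones((1, 4)))


class TestProject:
    def test_mean_maps_to_origin(self, rng):
        X = rng.normal(size=(25, 6))
        model = fit_morphospace(X)
        np.testing.assert_allclose(project(model, X.mean(axis=0)), 0.0, atol=1e-10)

    def test_identical_shapes_identical_coordinates(self, rng):
        X = rng.normal(size=(25, 6))
        model = fit_morphospace(X)
        a = project(model, X[3])
        b = project(model, X[3].copy())
        np.testing.assert_allclose(a, b, atol=0)

    def test_residual_bounded_by_discarded_variance(self, rng):
        X = rng.normal(size=(60, 8)) * np.linspace(5, 0.1, 8)
        model = fit_morphospace(X, 0.95)
        coords = project(model, X)
        recon = coords @ model.components + model.mean_vector
        resid_var = ((X - recon) ** 2).sum()
        total_var = ((X - X.mean(axis=0)) ** 2).sum()
        assert resid_var / total_var <= (1 - model.cumulative_fraction) + 1e-9

    def test_dimension_mismatch_rejected(self, rng):
        model = fit_morphospace(rng.normal(size=(10, 6)))
        with pytest.raises(MorphospaceError):
            project(model, np.ones(5))


class TestMahalanobis:
    def test_ant_mean_distance_zero(self, rng):
        coords = rng.normal(size=(30, 3))
        groups = np.array(["ant"] * 20 + ["mimic_spider"] * 10)
        mu = coords[:20].mean(axis=0)
        d, _ = mahalanobis_to_ants(np.vstack([coords, mu]), np.append(groups, "x"))
        assert d[-1] < 1e-10

    def test_identity_covariance_gives_euclidean(self, rng):
        # construct ants whose sample covariance is exactly the identity
        raw = rng.normal(size=(50, 3))
        raw -= raw.mean(axis=0)
        cov = raw.T @ raw / (len(raw) - 1)
        ants = raw @ np.linalg.inv(np.linalg.cholesky(cov)).T  # cov = I
        probe = np.array([[1.0, 2.0, -1.0]])
        coords = np.vstack([ants, probe])
        groups = np.array(["ant"] * 50 + ["mimic_insect"])
        d, info = mahalanobis_to_ants(coords, groups)
        assert info["policy"] == "sample"
        np.testing.assert_allclose(
            d[-1], np.linalg.norm(probe[0] - ants.mean(axis=0)), atol=1e-8
        )

    def test_brute_force_oracle(self, rng):
        """Distances must match an explicit-inverse computation to 1e-8."""
        ants = rng.normal(size=(50, 3)) @ rng.normal(size=(3, 3))
        others = rng.normal(size=(12, 3)) * 3
        coords = np.vstack([ants, others])
        groups = np.array(["ant"] * 50 + ["non_mimic"] * 12)
        d, _ = mahalanobis_to_ants(coords, groups)
        mu = ants.mean(axis=0)
        centered = ants - mu
        inv = np.linalg.inv(centered.T @ centered / 49)
        expected = np.array(
            [np.sqrt((v - mu) @ inv @ (v - mu)) for v in coords]
        )
        np.testing.assert_allclose(d, expected, atol=1e-8)

    def test_shrinkage_applied_when_ants_fewer_than_dims(self, rng):
        coords = rng.normal(size=(10, 6))
        groups = np.array(["ant"] * 4 + ["non_mimic"] * 6)
        d, info = mahalanobis_to_ants(coords, groups)
        assert info["policy"] == "ledoit_wolf_shrinkage"
        assert 0 < info["shrinkage"] <= 1
        assert np.all(np.isfinite(d))

    def test_too_few_ants_rejected(self, rng):
        with pytest.raises(MorphospaceError):
            mahalanobis_to_ants(rng.normal(size=(5, 2)), np.array(["ant"] + ["x"] * 4))


class TestAccuracyIndex:
    def test_endpoints_and_linearity(self):
        df = accuracy_index(
            ["a", "b", "c"], ["ant", "mimic_spider", "non_mimic"],
            [0.0, 2.0, 4.0], "dorsal",
        )
        np.testing.assert_allclose(df["accuracy"], [1.0, 0.5, 0.0])
        assert (df["accuracy"] >= 0).all() and (df["accuracy"] <= 1).all()

    def test_exactly_one_species_scores_zero(self, rng):
        d = rng.uniform(0.1, 5.0, size=20)
        df = accuracy_index(range(20), ["g"] * 20, d)
        assert (df["accuracy"] == 0).sum() == 1

    def test_all_zero_distances_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            accuracy_index(["a"], ["ant"], [0.0])

    def test_affine_invariance(self, rng):
        """Mahalanobis accuracy is unchanged by any invertible affine map of
        the morphospace (when no regularization is triggered)."""
        coords = rng.normal(size=(40, 3))
        groups = np.array(["ant"] * 25 + ["mimic_spider"] * 15)
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        b = rng.normal(size=3)
        d1, i1 = mahalanobis_to_ants(coords, groups)
        d2, i2 = mahalanobis_to_ants(coords @ A.T + b, groups)
        assert i1["policy"] == i2["policy"] == "sample"
        a1 = accuracy_index(range(40), groups, d1)["accuracy"]
        a2 = accuracy_index(range(40), groups, d2)["accuracy"]
        np.testing.assert_allclose(a1, a2, atol=1e-8)

    def test_accuracy_depends_on_dataset_extremes(self, rng):
        """The index is relative to the least ant-like species: adding a
        species farther than the current maximum stretches the scale and
        weakly raises every other accuracy; removing the least ant-like
        species shrinks it and weakly lowers them."""
        d = rng.uniform(0.5, 3.0, size=15)
        base = accuracy_index(range(15), ["g"] * 15, d)["accuracy"].to_numpy()
        extended = accuracy_index(
            range(16), ["g"] * 16, np.append(d, 10.0)
        )["accuracy"].to_numpy()[:15]
        assert np.all(extended >= base - 1e-12)
        assert extended.max() > base[d < d.max()].max()  # strictly for some
        keep = d < d.max()
        reduced = accuracy_index(
            range(int(keep.sum())), ["g"] * int(keep.sum()), d[keep]
        )["accuracy"].to_numpy()
        assert np.all(reduced <= base[keep] + 1e-12)


class TestConfidenceEllipse:
    def test_standard_normal_semi_axes(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(100_000, 2))
        ell = confidence_ellipse(pts, 0.95)
        target = np.sqrt(5.991)  # chi-square(2) 95% quantile
        assert abs(ell.semi_axes[0] - target) < 0.02 * target
        assert abs(ell.semi_axes[1] - target) < 0.02 * target

    def test_scaling_equivariance(self, rng):
        pts = rng.normal(size=(500, 2)) @ np.array([[2.0, 0.5], [0.0, 1.0]])
        e1 = confidence_ellipse(pts)
        e2 = confidence_ellipse(pts * 3.0)
        np.testing.assert_allclose(
            np.array(e2.semi_axes), 3.0 * np.array(e1.semi_axes), rtol=1e-9
        )
        assert abs(e2.orientation - e1.orientation) < 1e-9

    def test_monte_carlo_coverage(self):
        rng = np.random.default_rng(99)
        cov = np.array([[2.0, 0.7], [0.7, 1.0]])
        L = np.linalg.cholesky(cov)
        pts = rng.normal(size=(100_000, 2)) @ L.T
        ell = confidence_ellipse(pts, 0.95)
        fresh = rng.normal(size=(100_000, 2)) @ L.T
        coverage = ell.contains(fresh).mean()
        assert abs(coverage - 0.95) < 0.01

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            confidence_ellipse(pts)


def _toy_shapes(rng, n_per_group=8, spread=0.08):
    """Species shapes in a 3-harmonic coefficient space with an ant cluster
    and mimics at graded distances along two independent directions."""
    shapes = []
    base = np.array([[1.0, 0, 0, 0.5], [0.2, 0, 0, 0.1], [0.05, 0, 0, 0.02]])
    offsets = {
        "ant": (0.0, 0.0),
        "mimic_insect": (0.3, 0.1),
        "mimic_spider": (0.6, -0.3),
        "non_mimic": (1.5, 1.2),
    }
    for group, (off1, off2) in offsets.items():
        for i in range(n_per_group):
            coeffs = base.copy()
            coeffs[1, 0] += off1 + spread * rng.standard_normal()
            coeffs[1, 3] += off2 + spread * rng.standard_normal()
            coeffs[2, 3] += spread * rng.standard_normal()
            shapes.append(
                SpeciesShape(
                    f"{group}_{i}", group, "dorsal",
                    EFACoefficients(coeffs, normalized=True),
                )
            )
    return shapes


class TestModelResults:
    def test_fit_produces_full_results(self, rng):
        res = MimicryAccuracy.from_species_shapes(_toy_shapes(rng)).fit(
            n_boot=2000, seed=1
        )
        assert len(res.accuracy) == 32
        assert set(res.accuracy.columns) >= {
            "species_id", "group", "aspect", "mahalanobis", "accuracy",
        }
        assert res.effect_size is not None and res.variance_test is not None
        assert res.morphospace.cumulative_fraction >= 0.95 - 1e-9
        # ant cluster scores best on average
        means = res.accuracy.groupby("group")["accuracy"].mean()
        assert means["ant"] == means.max()

    def test_mixed_aspects_rejected(self, rng):
        shapes = _toy_shapes(rng)
        shapes[0].aspect = "lateral"
        with pytest.raises(ValueError, match="aspect"):
            MimicryAccuracy.from_species_shapes(shapes)

    def test_summary_mentions_key_results(self, rng):
        res = MimicryAccuracy.from_species_shapes(_toy_shapes(rng)).fit(
            n_boot=2000, seed=1
        )
        text = res.summary()
        assert "cohens_d" in text and "BCa" in text
        assert "variance ratio" in text and "dorsal" in text

    def test_fit_deterministic_given_seed(self, rng):
        shapes = _toy_shapes(rng)
        r1 = MimicryAccuracy.from_species_shapes(shapes).fit(n_boot=2000, seed=9)
        r2 = MimicryAccuracy.from_species_shapes(shapes).fit(n_boot=2000, seed=9)
        assert r1.effect_size.ci_low == r2.effect_size.ci_low
        assert r1.effect_size.ci_high == r2.effect_size.ci_high
        pd.testing.assert_frame_equal(r1.accuracy, r2.accuracy)

    def test_confidence_ellipses_per_group(self, rng):
        res = MimicryAccuracy.from_species_shapes(_toy_shapes(rng)).fit(
            n_boot=2000, seed=1
        )
        ells = res.confidence_ellipses()
        assert set(ells) == {"ant", "mimic_insect", "mimic_spider", "non_mimic"}
        for ell in ells.values():
            assert ell.semi_axes[0] >= ell.semi_axes[1] > 0

    def test_plot_morphospace_smoke(self, rng):
        import matplotlib

        matplotlib.use("Agg")
        res = MimicryAccuracy.from_species_shapes(_toy_shapes(rng)).fit(
            n_boot=2000, seed=1
        )
        ax = res.plot_morphospace()
        assert ax.get_title() == "dorsal morphospace"
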