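"""Morphospace construction and the mimetic-accuracy model.

Species average shapes (flattened, normalized elliptic Fourier coefficients)
are embedded in a PCA morphospace retaining the smallest prefix of components
whose cumulative explained variance reaches the threshold (default 95%); this
also eliminates constant coefficient dimensions.  The Mahalanobis distance of
every species to the ant-group distribution in that space, rescaled by the
distance of the least ant-like species, gives the accuracy index

    accuracy = 1 - D / D_max,

which is 1 for a perfect average ant shape and 0 for the least ant-like
species in the same aspect's data set.

:class:`MimicryAccuracy` packages the whole analysis in the fit/results
idiom: build the model from species-level data, call :meth:`~MimicryAccuracy.fit`,
and read estimates, uncertainty and diagnostics off the returned
:class:`MimicryAccuracyResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats as sstats
from sklearn.covariance import ledoit_wolf
from sklearn.decomposition import PCA

from . import stats as gstats

#: regularize the ant covariance when its condition number exceeds this
COND_REGULARIZE = 1e8
#: hard error if still worse than this after shrinkage
COND_MAX = 1e12


class MorphospaceError(ValueError):
    pass


@dataclass
class MorphospaceModel:
    """Centered PCA basis of species coefficient vectors."""

    mean_vector: np.ndarray
    components: np.ndarray  # (k_retained, p), orthonormal rows
    explained_variance_fractions: np.ndarray  # retained fractions
    k_retained: int
    aspect: str | None = None

    @property
    def cumulative_fraction(self) -> float:
        return float(self.explained_variance_fractions.sum())


def fit_morphospace(
    X, variance_threshold: float = 0.95, aspect: str | None = None
) -> MorphospaceModel:
    """PCA of species coefficient vectors, retaining the smallest component
    prefix with cumulative explained variance >= ``variance_threshold``.

    Zero-variance (constant) dimensions carry no explained variance and never
    enter the retained set.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise MorphospaceError("need at least 2 species to fit a morphospace")
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError("variance_threshold must be in (0, 1]")
    pca = PCA(svd_solver="full")
    pca.fit(X)
    evr = pca.explained_variance_ratio_
    positive = evr > 1e-12
    cum = np.cumsum(evr)
    k = int(np.searchsorted(cum, variance_threshold - 1e-9) + 1)
    k = min(k, int(positive.sum()))
    k = max(k, 1)
    return MorphospaceModel(
        mean_vector=pca.mean_,
        components=pca.components_[:k],
        explained_variance_fractions=evr[:k],
        k_retained=k,
        aspect=aspect,
    )


def project(model: MorphospaceModel, X) -> np.ndarray:
    """Centered projection onto the retained components.

    Accepts a single coefficient vector or a stack of them.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.mean_vector.shape[0]:
        raise MorphospaceError(
            f"coefficient dimension {X.shape[1]} does not match model "
            f"dimension {model.mean_vector.shape[0]}"
        )
    coords = (X - model.mean_vector) @ model.components.T
    return coords[0] if coords.shape[0] == 1 else coords


def mahalanobis_to_ants(
    coords,
    groups,
    ant_group: str = "ant",
    cond_regularize: float = COND_REGULARIZE,
    cond_max: float = COND_MAX,
):
    """Mahalanobis distance of every shape vector to the ant distribution.

    Returns ``(distances, info)`` where ``info`` records the covariance
    regularization actually applied.  The ant mean and covariance (divisor
    n − 1) are estimated from the ant-group rows; when the estimate is
    unreliable — fewer than 3 ants per retained dimension, or condition
    number > ``cond_regularize`` — it is shrunk toward a scaled identity
    with a Ledoit–Wolf intensity, which keeps the metric stable when the
    retained morphospace has nearly as many dimensions as there are ant
    species.  A fully degenerate ant sample (zero covariance) falls back to
    the unit-identity metric, i.e. Euclidean distance.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    groups = np.asarray(groups)
    ants = coords[groups == ant_group]
    if len(ants) < 2:
        raise MorphospaceError("need at least 2 ant species for the ant distribution")
    mu = ants.mean(axis=0)
    centered = ants - mu
    cov = centered.T @ centered / (len(ants) - 1)
    shrinkage = 0.0
    policy = "sample"
    tr = float(np.trace(cov))
    if tr <= 0.0:
        cov = np.eye(coords.shape[1])
        shrinkage, policy = 1.0, "identity_fallback"
    elif len(ants) < 3 * coords.shape[1] or np.linalg.cond(cov) > cond_regularize:
        _, shrinkage = ledoit_wolf(ants, assume_centered=False)
        shrinkage = float(np.clip(max(shrinkage, 1e-4), 0.0, 1.0))
        cov = (1.0 - shrinkage) * cov + shrinkage * (tr / coords.shape[1]) * np.eye(
            coords.shape[1]
        )
        policy = "ledoit_wolf_shrinkage"
        if np.linalg.cond(cov) > cond_max:
            raise MorphospaceError(
                "ant covariance singular after Ledoit-Wolf shrinkage toward "
                "scaled identity (regularization policy exhausted)"
            )
    solve = linalg.cho_solve(linalg.cho_factor(cov), (coords - mu).T)
    d = np.sqrt(np.einsum("ij,ji->i", coords - mu, solve))
    info = {"shrinkage": shrinkage, "policy": policy, "n_ants": int(len(ants))}
    return d, info


def accuracy_index(species_ids, groups, distances, aspect: str | None = None) -> pd.DataFrame:
    """Accuracy = 1 − D/D_max over all species of one aspect's data set.

    The normalizing D_max is the distance of the least ant-like species among
    *all* species (ants, mimics and non-mimics alike), so exactly one species
    scores 0 and a perfect average ant shape scores 1.
    """
    d = np.asarray(distances, dtype=float)
    if len(d) < 1:
        raise ValueError("need at least one distance")
    dmax = d.max()
    if dmax <= 0.0:
        raise ValueError("degenerate dataset: all Mahalanobis distances are zero")
    return pd.DataFrame(
        {
            "species_id": list(species_ids),
            "group": list(groups),
            "aspect": aspect,
            "mahalanobis": d,
            "accuracy": 1.0 - d / dmax,
        }
    )


@dataclass
class ConfidenceEllipse:
    group: str | None
    center: np.ndarray
    semi_axes: tuple  # (major, minor)
    orientation: float  # radians, major axis vs +x

    def contains(self, points) -> np.ndarray:
        """Boolean mask of points inside the ellipse (used for coverage checks)."""
        pts = np.atleast_2d(points) - self.center
        ca, sa = np.cos(self.orientation), np.sin(self.orientation)
        u = pts @ np.array([ca, sa])
        v = pts @ np.array([-sa, ca])
        return (u / self.semi_axes[0]) ** 2 + (v / self.semi_axes[1]) ** 2 <= 1.0


def confidence_ellipse(points, level: float = 0.95, group: str | None = None) -> ConfidenceEllipse:
    """Normal-theory confidence region ellipse for a 2-D point cloud.

    Built from the sample mean and covariance scaled by the chi-square
    quantile with 2 degrees of freedom at the requested level.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need at least 3 two-dimensional points")
    cov = np.cov(pts.T, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() <= 1e-12 * max(evals.max(), 1e-300):
        raise ValueError("degenerate covariance: points are collinear")
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    q = sstats.chi2.ppf(level, df=2)
    return ConfidenceEllipse(
        group=group,
        center=pts.mean(axis=0),
        semi_axes=(float(np.sqrt(evals[0] * q)), float(np.sqrt(evals[1] * q))),
        orientation=float(np.arctan2(evecs[1, 0], evecs[0, 0])),
    )


class MimicryAccuracy:
    """Model of body-shape mimetic accuracy for one aspect's species shapes.

    Parameters
    ----------
    coefficients : (n_species, p) array
        Flattened normalized coefficient vectors, one row per species.
    species_ids, groups : sequences of str
        Species identifiers and mimicry-group labels (``ant``,
        ``mimic_spider``, ``mimic_insect``, ``non_mimic``).
    aspect : str
        ``dorsal`` or ``lateral``; purely descriptive here.
    variance_threshold : float
        Minimum cumulative explained variance of the retained PCA prefix.
    """

    def __init__(
        self,
        coefficients,
        species_ids,
        groups,
        aspect: str = "dorsal",
        variance_threshold: float = 0.95,
        ant_group: str = "ant",
    ):
        self.exog = np.atleast_2d(np.asarray(coefficients, dtype=float))
        self.species_ids = list(species_ids)
        self.groups = np.asarray(list(groups))
        if not (len(self.exog) == len(self.species_ids) == len(self.groups)):
            raise ValueError("coefficients, species_ids and groups must align")
        self.aspect = aspect
        self.variance_threshold = variance_threshold
        self.ant_group = ant_group

    @classmethod
    def from_species_shapes(cls, shapes, **kwargs) -> "MimicryAccuracy":
        """Build from a sequence of :class:`~myrmomorph.efa.SpeciesShape`."""
        shapes = list(shapes)
        aspects = {s.aspect for s in shapes}
        if len(aspects) > 1:
            raise ValueError(f"species shapes mix aspects: {sorted(aspects)}")
        return cls(
            np.stack([s.coefficients.flatten() for s in shapes]),
            [s.species_id for s in shapes],
            [s.group for s in shapes],
            aspect=aspects.pop() if aspects else "dorsal",
            **kwargs,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, coeff_columns=None, **kwargs) -> "MimicryAccuracy":
        """Build from a wide DataFrame with species_id/group columns plus
        coefficient columns (all remaining numeric columns by default)."""
        if coeff_columns is None:
            coeff_columns = [
                c for c in df.columns
                if c not in ("species_id", "group", "aspect")
            ]
        aspect = kwargs.pop("aspect", None)
        if aspect is None:
            aspect = df["aspect"].iloc[0] if "aspect" in df else "dorsal"
        return cls(
            df[coeff_columns].to_numpy(dtype=float),
            df["species_id"],
            df["group"],
            aspect=aspect,
            **kwargs,
        )

    def fit(
        self,
        n_boot: int = 10_000,
        seed: int | None = None,
        effect_statistic: str = "cohens_d",
        comparison: tuple = ("mimic_insect", "mimic_spider"),
        variance_comparison: tuple = ("mimic_spider", "mimic_insect"),
    ) -> "MimicryAccuracyResults":
        """Fit the morphospace, score accuracy, and compare mimic groups.

        The effect size is oriented first-minus-second of ``comparison``
        (default insect − spider) with a BCa bootstrap CI; the variance-ratio
        F-test uses ``variance_comparison`` (default spider/insect) with the
        one-tailed alternative that the first group varies *less*.
        """
        morpho = fit_morphospace(self.exog, self.variance_threshold, self.aspect)
        coords = project(morpho, self.exog)
        d, cov_info = mahalanobis_to_ants(coords, self.groups, self.ant_group)
        acc = accuracy_index(self.species_ids, self.groups, d, self.aspect)

        effect = None
        ftest = None
        g1, g2 = comparison
        x1 = acc.loc[acc.group == g1, "accuracy"].to_numpy()
        x2 = acc.loc[acc.group == g2, "accuracy"].to_numpy()
        if len(x1) >= 2 and len(x2) >= 2:
            effect = gstats.bca_bootstrap_ci(
                x1, x2, statistic=effect_statistic, n_boot=n_boot, seed=seed
            )
            v1 = acc.loc[acc.group == variance_comparison[0], "accuracy"].to_numpy()
            v2 = acc.loc[acc.group == variance_comparison[1], "accuracy"].to_numpy()
            ftest = gstats.variance_ratio_test(v1, v2, alternative="less")
        return MimicryAccuracyResults(
            model=self,
            morphospace=morpho,
            coordinates=coords,
            accuracy=acc,
            covariance_info=cov_info,
            effect_size=effect,
            variance_test=ftest,
            comparison=comparison,
            variance_comparison=variance_comparison,
        )


@dataclass
class MimicryAccuracyResults:
    """Fitted morphospace, accuracy table and group comparisons."""

    model: MimicryAccuracy
    morphospace: MorphospaceModel
    coordinates: np.ndarray
    accuracy: pd.DataFrame
    covariance_info: dict
    effect_size: gstats.EffectSizeResult | None
    variance_test: gstats.VarianceTestResult | None
    comparison: tuple = ("mimic_insect", "mimic_spider")
    variance_comparison: tuple = ("mimic_spider", "mimic_insect")

    @property
    def shape_vectors(self) -> pd.DataFrame:
        cols = {f"PC{i + 1}": self.coordinates[:, i]
                for i in range(self.morphospace.k_retained)}
        return pd.DataFrame(
            {"species_id": self.model.species_ids, "group": self.model.groups,
             "aspect": self.model.aspect, **cols}
        )

    def group_accuracy(self, group: str) -> np.ndarray:
        return self.accuracy.loc[self.accuracy.group == group, "accuracy"].to_numpy()

    def confidence_ellipses(self, level: float = 0.95, components=(0, 1)) -> dict:
        """Per-group 95% confidence ellipses in a 2-D morphospace plane."""
        if self.morphospace.k_retained < 2:
            return {}
        out = {}
        pts2 = self.coordinates[:, list(components)]
        for g in pd.unique(self.model.groups):
            sub = pts2[self.model.groups == g]
            if len(sub) >= 3:
                try:
                    out[g] = confidence_ellipse(sub, level=level, group=g)
                except ValueError:
                    continue
        return out

    def plot_morphospace(self, ax=None, level: float = 0.95):
        """Scatter the species in the first two PCs with group ellipses."""
        import matplotlib.pyplot as plt
        from matplotlib.patches import Ellipse as MplEllipse

        if ax is None:
            _, ax = plt.subplots()
        coords = self.coordinates
        if coords.shape[1] < 2:  # degenerate 1-D morphospace
            coords = np.column_stack([coords, np.zeros(len(coords))])
        for g in pd.unique(self.model.groups):
            sub = coords[self.model.groups == g][:, :2]
            ax.scatter(sub[:, 0], sub[:, 1], label=g, s=18)
        for g, ell in self.confidence_ellipses(level=level).items():
            ax.add_patch(
                MplEllipse(
                    ell.center, 2 * ell.semi_axes[0], 2 * ell.semi_axes[1],
                    angle=np.degrees(ell.orientation),
                    fill=False, linestyle="--",
                )
            )
        evr = self.morphospace.explained_variance_fractions
        ax.set_xlabel(f"PC1 ({evr[0]:.0%})")
        if len(evr) > 1:
            ax.set_ylabel(f"PC2 ({evr[1]:.0%})")
        ax.legend(fontsize="small")
        ax.set_title(f"{self.model.aspect} morphospace")
        return ax

    def summary(self) -> str:
        """Plain-text summary of the fitted analysis."""
        from statsmodels.iolib.table import SimpleTable

        m = self.morphospace
        lines = [
            f"Mimetic accuracy analysis ({self.model.aspect} aspect)",
            f"  species: {len(self.model.species_ids)}   "
            f"retained PCs: {m.k_retained} "
            f"({m.cumulative_fraction:.1%} of variance)   "
            f"ant covariance: {self.covariance_info['policy']} "
            f"(shrinkage {self.covariance_info['shrinkage']:.3f})",
            "",
        ]
        rows = []
        for g in pd.unique(self.model.groups):
            vals = self.group_accuracy(g)
            rows.append(
                [g, len(vals), f"{vals.mean():.3f}", f"{vals.std(ddof=1):.3f}"
                 if len(vals) > 1 else "-",
                 f"{vals.min():.2f}-{vals.max():.2f}"]
            )
        lines.append(
            SimpleTable(
                rows, headers=["group", "n", "mean acc", "sd", "range"],
                title="Accuracy by group",
            ).as_text()
        )
        if self.effect_size is not None:
            e = self.effect_size
            lines.append(
                f"\n{self.comparison[0]} - {self.comparison[1]} "
                f"{e.statistic}: {e.estimate:.2f}, "
                f"{e.level:.0%} BCa CI [{e.ci_low:.2f}, {e.ci_high:.2f}] "
                f"({e.n_boot} resamples)"
            )
        if self.variance_test is not None:
            f = self.variance_test
            lines.append(
                f"variance ratio {self.variance_comparison[0]}/"
                f"{self.variance_comparison[1]}: "
                f"F_{f.df1},{f.df2} = {f.f:.2f}, "
                f"{f.level:.0%} CI [{f.ci_low:.2g}, {f.ci_high:.2f}], "
                f"one-tailed p = {f.p:.2f}"
            )
        return "\n".join(lines)
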