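"""End-to-end orchestration: images -> outlines -> coefficients -> accuracy -> stats.

Per aspect the pipeline runs: read metadata and images, trace and standardize
outlines (subsample to 1600 points, five sliding-average smoothing passes),
Procrustes superimposition, elliptic Fourier transform, flip-preserving
normalization, asymmetry removal (dorsal only), hierarchical averaging
(outlines per specimen, specimens per species), PCA morphospace at the 95%
variance threshold, Mahalanobis distances to the ant distribution, the
accuracy index, and the group comparisons (insect − spider Cohen's d with a
BCa bootstrap CI; one-tailed spider/insect variance-ratio F-test).

Per-image failures are logged and skipped; structural problems (no ants,
fewer than 2 species) abort only the affected aspect.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .efa import (
    SpeciesShape,
    average_coefficients,
    efa_transform,
    normalize_coefficients,
    procrustes_align,
    remove_asymmetry,
    write_coefficients,
    EFACoefficients,
)
from .model import MimicryAccuracy
from .outlines import load_silhouette, read_metadata, standardize_outline

log = logging.getLogger("myrmomorph")

IMAGE_EXTENSIONS = (".png", ".tif", ".tiff")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All tunable parameters of one pipeline run."""

    input_dir: str
    metadata_path: str
    output_dir: str
    n_points: int = 1600
    smooth_iterations: int = 5
    n_harmonics: int = 40
    variance_threshold: float = 0.95
    remove_asymmetry_dorsal: bool = True
    n_boot: int = 10_000
    seed: int = 0
    aspects: tuple = ("dorsal", "lateral")

    def __post_init__(self):
        for name in ("n_points", "n_harmonics", "n_boot"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.smooth_iterations < 0:
            raise ValueError("smooth_iterations must be >= 0")
        if not 0.0 < self.variance_threshold <= 1.0:
            raise ValueError("variance_threshold must be in (0, 1]")

    @classmethod
    def from_toml(cls, path, **overrides) -> "PipelineConfig":
        """Load a flat TOML config file; keyword overrides win."""
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "aspects" in data:
            data["aspects"] = tuple(data["aspects"])
        return cls(**data)


def _find_image(input_dir: Path, image_id: str) -> Path:
    for ext in IMAGE_EXTENSIONS:
        p = input_dir / f"{image_id}{ext}"
        if p.exists():
            return p
    raise FileNotFoundError(f"no image file for id {image_id!r} in {input_dir}")


def standardize_images(
    input_dir, metadata: pd.DataFrame, n_points: int = 1600, smooth_iterations: int = 5
):
    """Trace and standardize every image in the metadata.

    Returns ``(outlines, failures)``: a dict image_id -> (n_points, 2) y-up
    outline, and a list of (image_id, message) for skipped images.
    """
    input_dir = Path(input_dir)
    outlines, failures = {}, []
    for image_id in metadata["image_id"]:
        try:
            mask = load_silhouette(_find_image(input_dir, image_id))
            outlines[image_id] = standardize_outline(mask, n_points, smooth_iterations)
        except Exception as exc:  # noqa: BLE001 - skip-and-log failure policy
            log.warning("skipping image %s: %s", image_id, exc)
            failures.append((image_id, str(exc)))
    return outlines, failures


def species_coefficient_table(
    outlines: dict,
    metadata: pd.DataFrame,
    aspect: str,
    n_harmonics: int = 40,
    remove_asymmetry_dorsal: bool = True,
) -> pd.DataFrame:
    """Procrustes + EFA + normalization + hierarchical averaging for one aspect.

    Returns a wide DataFrame (species_id, group, aspect, n_specimens,
    n_outlines, c0..c_{4H-1}) of species average coefficient vectors.
    """
    meta = metadata[metadata["aspect"] == aspect]
    ids = [i for i in meta["image_id"] if i in outlines]
    if len(ids) < 2:
        raise PipelineError(f"fewer than 2 usable outlines for aspect {aspect!r}")
    aligned = procrustes_align([outlines[i] for i in ids])

    symmetrize = remove_asymmetry_dorsal and aspect == "dorsal"
    per_image = {}
    for image_id, outline in zip(ids, aligned):
        cf = normalize_coefficients(efa_transform(outline, n_harmonics))
        per_image[image_id] = remove_asymmetry(cf) if symmetrize else cf

    rows = []
    meta_used = meta[meta["image_id"].isin(per_image)]
    for species_id, sp_meta in meta_used.groupby("species_id", sort=True):
        specimen_means = [
            average_coefficients([per_image[i] for i in spec_meta["image_id"]])
            for _, spec_meta in sp_meta.groupby("specimen_id", sort=True)
        ]
        species_mean = average_coefficients(specimen_means)
        row = {
            "species_id": species_id,
            "group": sp_meta["group"].iloc[0],
            "aspect": aspect,
            "n_specimens": sp_meta["specimen_id"].nunique(),
            "n_outlines": len(sp_meta),
        }
        row.update({f"c{i}": v for i, v in enumerate(species_mean.flatten())})
        rows.append(row)
    return pd.DataFrame(rows)


def species_shapes_from_table(table: pd.DataFrame):
    """Wide coefficient table -> list of :class:`SpeciesShape`."""
    ccols = [c for c in table.columns if c.startswith("c") and c[1:].isdigit()]
    ccols = sorted(ccols, key=lambda c: int(c[1:]))
    shapes = []
    for _, row in table.iterrows():
        coeffs = row[ccols].to_numpy(dtype=float).reshape(-1, 4)
        shapes.append(
            SpeciesShape(
                species_id=row["species_id"],
                group=row["group"],
                aspect=row["aspect"],
                coefficients=EFACoefficients(coeffs, normalized=True),
                n_specimens=int(row.get("n_specimens", 1)),
                n_outlines=int(row.get("n_outlines", 1)),
            )
        )
    return shapes


def fit_aspect(
    table: pd.DataFrame,
    variance_threshold: float = 0.95,
    n_boot: int = 10_000,
    seed: int | None = None,
):
    """Fit the accuracy model for one aspect's species coefficient table."""
    aspect = table["aspect"].iloc[0]
    if (table["group"] == "ant").sum() < 2:
        raise PipelineError(f"ant group required (aspect {aspect!r})")
    model = MimicryAccuracy.from_species_shapes(
        species_shapes_from_table(table), variance_threshold=variance_threshold
    )
    return model.fit(n_boot=n_boot, seed=seed)


def stats_report(results) -> dict:
    """JSON-ready stats block for one fitted aspect."""
    out = {
        "aspect": results.model.aspect,
        "n_species": len(results.model.species_ids),
        "k_retained": results.morphospace.k_retained,
        "explained_variance_fractions":
            results.morphospace.explained_variance_fractions.tolist(),
        "covariance": results.covariance_info,
        "group_accuracy": {
            g: {
                "n": int(n),
                "mean": float(vals.mean()),
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
            for g in pd.unique(results.model.groups)
            for vals, n in [(results.group_accuracy(g),
                             (results.model.groups == g).sum())]
        },
    }
    if results.effect_size is not None:
        e = results.effect_size
        out["effect_size"] = {
            "comparison": list(results.comparison),
            "statistic": e.statistic,
            "estimate": e.estimate,
            "ci": [e.ci_low, e.ci_high],
            "level": e.level,
            "n_boot": e.n_boot,
            "seed": e.seed,
            "n_redraws": e.n_redraws,
        }
    if results.variance_test is not None:
        f = results.variance_test
        out["f_test"] = {
            "comparison": list(results.variance_comparison),
            "f": f.f, "df": [f.df1, f.df2], "p": f.p,
            "ci": [f.ci_low, f.ci_high], "alternative": f.alternative,
        }
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a results bundle.

    The bundle maps each processed aspect to its
    :class:`~myrmomorph.model.MimicryAccuracyResults`, plus ``"errors"``
    (aspect -> message) and ``"output_dir"``.  Tables, reports and a
    provenance JSON are written under ``config.output_dir``.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    try:
        metadata = read_metadata(config.metadata_path)
        bundle: dict = {"errors": {}, "output_dir": str(out_dir)}
        provenance = {
            "config": dataclasses.asdict(config),
            "version": __version__,
            "counts": {},
        }
        for aspect in config.aspects:
            meta_a = metadata[metadata["aspect"] == aspect]
            if meta_a.empty:
                bundle["errors"][aspect] = "no images for aspect"
                continue
            if meta_a.loc[meta_a.group == "ant", "species_id"].nunique() < 2:
                bundle["errors"][aspect] = "ant group required"
                log.error("aspect %s: ant group required", aspect)
                continue
            try:
                outlines, failures = standardize_images(
                    config.input_dir, meta_a, config.n_points,
                    config.smooth_iterations,
                )
                table = species_coefficient_table(
                    outlines, meta_a, aspect, config.n_harmonics,
                    config.remove_asymmetry_dorsal,
                )
                results = fit_aspect(
                    table, config.variance_threshold, config.n_boot, config.seed
                )
            except Exception as exc:  # halt this aspect only
                bundle["errors"][aspect] = str(exc)
                log.error("aspect %s failed: %s", aspect, exc)
                continue

            bundle[aspect] = results
            provenance["counts"][aspect] = {
                "images": int(len(meta_a)),
                "outlines_traced": len(outlines),
                "failures": len(failures),
                "species": int(table.shape[0]),
                "k_retained": results.morphospace.k_retained,
            }
            provenance.setdefault("shrinkage", {})[aspect] = results.covariance_info

            table.to_csv(out_dir / f"coefficients_{aspect}.csv", index=False)
            results.accuracy.to_csv(out_dir / f"accuracy_{aspect}.csv", index=False)
            results.shape_vectors.to_csv(
                out_dir / f"morphospace_{aspect}.csv", index=False
            )
            morpho_meta = {
                "explained_variance_fractions":
                    results.morphospace.explained_variance_fractions.tolist(),
                "k_retained": results.morphospace.k_retained,
                "ellipses": {
                    g: {
                        "center": ell.center.tolist(),
                        "semi_axes": list(ell.semi_axes),
                        "orientation": ell.orientation,
                    }
                    for g, ell in results.confidence_ellipses().items()
                },
            }
            with open(out_dir / f"morphospace_{aspect}.json", "w") as fh:
                json.dump(morpho_meta, fh, indent=2)
            write_coefficients(
                {
                    row["species_id"]: ("species", shape.coefficients)
                    for (_, row), shape in zip(
                        table.iterrows(), species_shapes_from_table(table)
                    )
                },
                out_dir / f"species_coefficients_{aspect}.csv",
                out_dir / f"species_coefficients_{aspect}.meta.json",
                pipeline_version=__version__,
            )
            log.info(
                "aspect %s: %d species, %d PCs retained",
                aspect, table.shape[0], results.morphospace.k_retained,
            )

        if not any(a in bundle for a in config.aspects):
            raise PipelineError(f"all aspects failed: {bundle['errors']}")

        stats_blocks = {
            a: stats_report(bundle[a]) for a in config.aspects if a in bundle
        }
        with open(out_dir / "stats.json", "w") as fh:
            json.dump(stats_blocks, fh, indent=2)
        flat = []
        for a, block in stats_blocks.items():
            row = {"aspect": a, "n_species": block["n_species"]}
            if "effect_size" in block:
                row.update(
                    cohens_d=block["effect_size"]["estimate"],
                    d_ci_low=block["effect_size"]["ci"][0],
                    d_ci_high=block["effect_size"]["ci"][1],
                )
            if "f_test" in block:
                row.update(f=block["f_test"]["f"], f_p=block["f_test"]["p"])
            flat.append(row)
        pd.DataFrame(flat).to_csv(out_dir / "stats_summary.csv", index=False)
        with open(out_dir / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2)
        return bundle
    finally:
        log.removeHandler(handler)
        handler.close()


def reproduce_archived_analysis(data_dir, output_dir=None, n_boot: int = 10_000, seed: int = 0) -> dict:
    """Run the full analysis on the archived study data.

    ``data_dir`` must contain the silhouette images together with a
    ``metadata.csv`` in this package's format (the archived study data,
    with group/aspect labels mapped onto the metadata columns).  Returns the headline quantities: dorsal and
    lateral insect − spider Cohen's d, the dorsal spider accuracy maximum,
    and the dorsal first-two-PC variance fraction.
    """
    data_dir = Path(data_dir)
    metadata_path = data_dir / "metadata.csv"
    if not metadata_path.exists():
        raise FileNotFoundError(
            f"archived dataset not found: expected images and metadata.csv in {data_dir}"
        )
    config = PipelineConfig(
        input_dir=str(data_dir),
        metadata_path=str(metadata_path),
        output_dir=str(output_dir or data_dir / "results"),
        n_boot=n_boot,
        seed=seed,
    )
    bundle = run_pipeline(config)
    out = {}
    if "dorsal" in bundle:
        r = bundle["dorsal"]
        out["dorsal_cohens_d"] = r.effect_size.estimate
        out["dorsal_spider_accuracy_max"] = float(
            r.group_accuracy("mimic_spider").max()
        )
        out["dorsal_first_two_pc_variance"] = float(
            r.morphospace.explained_variance_fractions[:2].sum()
        )
    if "lateral" in bundle:
        out["lateral_cohens_d"] = bundle["lateral"].effect_size.estimate
    return out
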