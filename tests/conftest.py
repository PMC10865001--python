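"""Shared fixtures: random smooth outlines and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from myrmomorph.pipeline import PipelineConfig, run_pipeline
from myrmomorph.synthetic import SyntheticConfig, generate_dataset


def random_blob(rng, n=800, smoothness=6, irregularity=0.2, elongation=1.8):
    """Smooth closed test outline: band-limited radial blob, stretched along
    x so its first-ellipse major axis is near-horizontal (head-left-like)."""
    t = 2.0 * np.pi * np.arange(n) / n
    r = np.ones(n)
    for k in range(2, smoothness + 2):
        a, b = rng.normal(0, irregularity / k, 2)
        r += a * np.cos(k * t) + b * np.sin(k * t)
    r = np.clip(r, 0.2, None)
    return np.column_stack([elongation * r * np.cos(t), r * np.sin(t)])


def rotate(points, angle):
    c, s = np.cos(angle), np.sin(angle)
    return points @ np.array([[c, s], [-s, c]])


@pytest.fixture
def rng():
    return np.random.default_rng(20240214)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """Tiny rendered dataset (4 groups x 3 species x 2 x 2, dorsal only)."""
    out = tmp_path_factory.mktemp("smalldata")
    config = SyntheticConfig(
        n_species_per_group=3,
        n_specimens_per_species=2,
        n_outlines_per_specimen=2,
        seed=11,
        aspects=("dorsal",),
    )
    metadata, truth = generate_dataset(config, out)
    return {"dir": out, "config": config, "metadata": metadata, "truth": truth}


@pytest.fixture(scope="session")
def small_results(small_dataset, tmp_path_factory):
    """Fitted pipeline bundle for the tiny dataset."""
    out = tmp_path_factory.mktemp("smallresults")
    config = PipelineConfig(
        input_dir=str(small_dataset["dir"]),
        metadata_path=str(small_dataset["dir"] / "metadata.csv"),
        output_dir=str(out),
        n_boot=2000,
        seed=5,
        aspects=("dorsal",),
    )
    return run_pipeline(config)


@pytest.fixture(scope="session")
def recovery_study(tmp_path_factory):
    """Parameter-recovery study: mimic groups at true mimicry 0.9 vs 0.3
    (15 species each) plus the ant model group, default noise, fixed seed."""
    out = tmp_path_factory.mktemp("recovery")
    config = SyntheticConfig(
        n_species_per_group=15,
        mimicry_by_group={"ant": 1.0, "mimic_spider": 0.9, "mimic_insect": 0.3},
        groups=("ant", "mimic_spider", "mimic_insect"),
        mimicry_jitter_sd=0.0,  # the two levels are the study conditions
        seed=77,
        aspects=("dorsal",),
    )
    metadata, truth = generate_dataset(config, out)
    results_dir = tmp_path_factory.mktemp("recovery_results")
    bundle = run_pipeline(
        PipelineConfig(
            input_dir=str(out),
            metadata_path=str(out / "metadata.csv"),
            output_dir=str(results_dir),
            n_boot=10_000,
            seed=77,
            aspects=("dorsal",),
        )
    )
    return {"truth": truth, "results": bundle["dorsal"]}
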