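"""Synthetic silhouette datasets with known mimicry structure.

Body shapes are built from stylized arthropod body plans — sequences of
ellipse-like lobes on a horizontal axis (head left) with waist constrictions
such as the ant petiole.  Ants have three lobes with deep neck and petiole
constrictions; spiders two stocky lobes with a shallow waist; mimic insects
three slender lobes; non-mimics a single elongated lobe.  A species' "true
mimicry" m in [0, 1] linearly blends its plan's normalized elliptic Fourier
coefficients toward the canonical ant plan of the same aspect, so m = 1 is
exactly the average ant shape in the representation the pipeline measures.

Hierarchical band-limited radial noise (species > specimen > outline)
emulates biological variation and repeated silhouette tracing; rendered PNG
images plus metadata and ground-truth tables emulate the archived study
layout (multiple outlines per specimen, multiple specimens per species, four
groups, two aspects).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw
from shapely.geometry import Polygon

from .efa import (
    EFACoefficients,
    efa_transform,
    normalize_coefficients,
    reconstruct_outline,
)
from .outlines import GROUPS, smooth_outline, subsample_outline

PLAN_TYPES = ("ant", "spider", "insect", "non_mimic")

#: map of mimicry-group labels to plan families
GROUP_PLAN = {
    "ant": "ant",
    "mimic_spider": "spider",
    "mimic_insect": "insect",
    "non_mimic": "non_mimic",
}


@dataclass(frozen=True)
class BodyPlan:
    """Stylized body plan: lobes (center_x, length, width) along a horizontal
    axis in body-length units, plus waist constrictions (position, depth)."""

    plan_type: str
    lobes: tuple  # ((cx, length, width), ...) ordered head to rear
    constrictions: tuple = ()  # ((position, depth), ...)
    aspect: str = "dorsal"

    def __post_init__(self):
        if self.plan_type not in PLAN_TYPES:
            raise ValueError(f"unknown plan type {self.plan_type!r}")
        cxs = [c for c, _, _ in self.lobes]
        if list(cxs) != sorted(cxs):
            raise ValueError("lobes must be ordered head to rear")
        if any(ln <= 0 or w <= 0 for _, ln, w in self.lobes):
            raise ValueError("lobe lengths and widths must be positive")
        if any(not 0.0 <= depth < 1.0 for _, depth in self.constrictions):
            raise ValueError("constriction depth must be in [0, 1)")


CANONICAL_PLANS = {
    ("ant", "dorsal"): BodyPlan(
        "ant",
        lobes=((0.12, 0.26, 0.20), (0.37, 0.32, 0.17), (0.76, 0.46, 0.28)),
        constrictions=((0.25, 0.42), (0.55, 0.58)),
    ),
    ("ant", "lateral"): BodyPlan(
        "ant",
        lobes=((0.12, 0.26, 0.22), (0.38, 0.34, 0.20), (0.77, 0.44, 0.30)),
        constrictions=((0.26, 0.38), (0.57, 0.54)),
        aspect="lateral",
    ),
    ("spider", "dorsal"): BodyPlan(
        "spider",
        lobes=((0.24, 0.46, 0.34), (0.70, 0.54, 0.40)),
        constrictions=((0.48, 0.30),),
    ),
    ("spider", "lateral"): BodyPlan(
        "spider",
        lobes=((0.23, 0.44, 0.30), (0.69, 0.56, 0.46)),
        constrictions=((0.47, 0.28),),
        aspect="lateral",
    ),
    ("insect", "dorsal"): BodyPlan(
        "insect",
        lobes=((0.11, 0.22, 0.15), (0.38, 0.36, 0.14), (0.76, 0.44, 0.21)),
        constrictions=((0.23, 0.35), (0.57, 0.45)),
    ),
    ("insect", "lateral"): BodyPlan(
        "insect",
        lobes=((0.11, 0.22, 0.17), (0.38, 0.36, 0.17), (0.77, 0.42, 0.24)),
        constrictions=((0.24, 0.30), (0.58, 0.40)),
        aspect="lateral",
    ),
    ("non_mimic", "dorsal"): BodyPlan(
        "non_mimic", lobes=((0.50, 1.00, 0.36),)
    ),
    ("non_mimic", "lateral"): BodyPlan(
        "non_mimic", lobes=((0.50, 1.00, 0.30),), aspect="lateral"
    ),
}


@dataclass
class SyntheticConfig:
    """Study conditions for a generated dataset.

    Defaults emulate the magnitude of the archived study (four groups, two
    aspects, a few specimens per species and outlines per specimen) with an
    ant cluster at m = 1 and mimic groups at graded distances from it.
    Noise sds are radial displacements relative to centroid size.
    """

    n_species_per_group: int = 15
    n_specimens_per_species: int = 2
    n_outlines_per_specimen: int = 3
    mimicry_by_group: dict = field(
        default_factory=lambda: {
            "ant": 1.0,
            "mimic_spider": 0.65,
            "mimic_insect": 0.45,  # the insect plan is intrinsically more ant-like
            "non_mimic": 0.05,
        }
    )
    mimicry_jitter_sd: float = 0.12  # species-level spread in m (non-ant groups)
    species_noise_sd: float = 0.03
    specimen_noise_sd: float = 0.015
    outline_noise_sd: float = 0.008
    seed: int = 0
    image_size: tuple = (1200, 800)
    groups: tuple = GROUPS
    aspects: tuple = ("dorsal", "lateral")
    n_points: int = 900  # vertices per generated outline

    def __post_init__(self):
        for name in ("n_species_per_group", "n_specimens_per_species",
                     "n_outlines_per_specimen"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("species_noise_sd", "specimen_noise_sd", "outline_noise_sd",
                     "mimicry_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups: {sorted(unknown)}")


def _plan_outline(plan: BodyPlan, n_points: int = 900) -> np.ndarray:
    """Closed outline of a plan: lobe-envelope half-width profile with
    Gaussian waist notches, mirrored about the horizontal axis."""
    x0 = min(c - ln / 2 for c, ln, _ in plan.lobes)
    x1 = max(c + ln / 2 for c, ln, _ in plan.lobes)
    # cosine-spaced grid densifies the rounded head and tail caps
    u = np.linspace(0.0, np.pi, 500)
    xs = x0 + (x1 - x0) * (1.0 - np.cos(u)) / 2.0

    w = np.zeros_like(xs)
    for cx, ln, width in plan.lobes:
        inside = np.abs(xs - cx) < ln / 2
        half = np.zeros_like(xs)
        half[inside] = (width / 2) * np.sqrt(
            np.clip(1.0 - ((xs[inside] - cx) / (ln / 2)) ** 2, 0.0, 1.0)
        )
        w = np.maximum(w, half)
    for pos, depth in plan.constrictions:
        w *= 1.0 - depth * np.exp(-(((xs - pos) / 0.045) ** 2))

    interior = slice(1, -1)  # endpoints have w = 0 (the head and tail tips)
    upper = np.column_stack([xs[interior], w[interior]])
    lower = np.column_stack([xs[interior], -w[interior]])
    pts = np.vstack([[xs[0], 0.0], lower, [xs[-1], 0.0], upper[::-1]])
    return subsample_outline(pts, n_points)  # counter-clockwise, head tip first


@functools.lru_cache(maxsize=64)
def _plan_coefficients(plan: BodyPlan, n_harmonics: int) -> EFACoefficients:
    return normalize_coefficients(
        efa_transform(_plan_outline(plan), n_harmonics)
    )


def make_body_outline(
    plan: BodyPlan,
    mimicry: float,
    rng=None,
    n_points: int = 900,
    n_harmonics: int = 40,
) -> np.ndarray:
    """Outline of a plan blended toward the canonical ant plan by ``mimicry``.

    The blend is linear in normalized elliptic Fourier coefficients — the
    same representation the measurement pipeline uses — so m = 1 reproduces
    the canonical ant outline exactly and ground truth stays well defined.
    Deterministic given its inputs (``rng`` reserved for future stochastic
    plan variation).
    """
    if not 0.0 <= mimicry <= 1.0:
        raise ValueError(f"mimicry must be in [0, 1], got {mimicry}")
    c_plan = _plan_coefficients(plan, n_harmonics)
    c_ant = _plan_coefficients(CANONICAL_PLANS[("ant", plan.aspect)], n_harmonics)
    blended = (1.0 - mimicry) * c_plan.coeffs + mimicry * c_ant.coeffs
    coeffs = normalize_coefficients(EFACoefficients(blended, normalized=True))
    return reconstruct_outline(coeffs, n_points)


#: rejection rule: perturbed outlines must stay simple with at least this
#: clearance (fraction of centroid size) so narrow waists never pinch shut
MIN_CLEARANCE = 0.01

#: generated shapes are kept band-limited to this many harmonics, matching
#: the default harmonic count of the measurement pipeline
BAND_LIMIT = 40


def _is_simple(points: np.ndarray, clearance: float) -> bool:
    """Simple polygon, no waist thinner than ``clearance``, and no near-fold
    (turning angle >= 90 deg between consecutive segments, which would make
    further normal displacements self-intersect locally)."""
    seg = np.roll(points, -1, axis=0) - points
    lengths = np.hypot(seg[:, 0], seg[:, 1])
    if lengths.min() <= 0:
        return False
    cos_turn = np.einsum("ij,ij->i", seg, np.roll(seg, 1, axis=0)) / (
        lengths * np.roll(lengths, 1)
    )
    if cos_turn.min() < 0.0:
        return False
    poly = Polygon(points)
    if not poly.is_valid:
        return False
    eroded = poly.buffer(-clearance)
    return eroded.geom_type == "Polygon" and not eroded.is_empty


def perturb_outline(
    outline,
    noise_sd: float,
    smoothness: int = 8,
    rng=None,
    min_clearance: float = MIN_CLEARANCE,
) -> np.ndarray:
    """Displace an outline along its normals by a band-limited random field.

    The field is a random low-order Fourier series in the arc-length
    parameter (harmonics 1..``smoothness``), attenuated where the body is
    thin (variation at a narrow waist scales with the waist, not with body
    size) and rescaled so the pooled pointwise standard deviation equals
    ``noise_sd`` times the centroid size.  Candidates that self-intersect, or
    whose waists close to within ``min_clearance`` of centroid size, are
    rejected and redrawn (up to 100 attempts).  Hierarchical sampling passes
    a larger clearance at the upper levels so that a parent shape always
    leaves room for its children's smaller perturbations.
    """
    pts = np.asarray(outline, dtype=float)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return pts.copy()
    rng = np.random.default_rng(rng)
    n = len(pts)
    centered = pts - pts.mean(axis=0)
    size = np.sqrt((centered**2).sum(axis=1).mean())

    tangent = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    normal = np.column_stack([tangent[:, 1], -tangent[:, 0]])  # outward for CCW

    # thickness proxy: distance from the horizontal body axis; thin regions
    # (petiole, neck) receive proportionally smaller displacements
    dy = np.abs(pts[:, 1] - pts[:, 1].mean())
    atten = np.clip(dy / (0.2 * size), 0.15, 1.0)
    atten /= np.sqrt((atten**2).mean())  # pooled sd stays = noise_sd * size

    t = 2.0 * np.pi * np.arange(n) / n
    k = np.arange(1, smoothness + 1)[:, None]
    basis_c, basis_s = np.cos(k * t), np.sin(k * t)
    for _ in range(100):
        amp = rng.standard_normal((2, smoothness)) / np.sqrt(smoothness)
        f = (amp[0] @ basis_c + amp[1] @ basis_s) * noise_sd * size * atten
        candidate = pts + normal * f[:, None]
        # two sliding-average passes: negligible for the band-limited field
        # (attenuation < 0.1% at harmonic 8 of 900 points) but removes
        # incipient point-scale folds at high-curvature spots
        candidate = smooth_outline(candidate, 2)
        # keep generated shapes inside the 40-harmonic representation the
        # measurement pipeline uses (the normal directions and thickness
        # attenuation would otherwise leak content past harmonic 40)
        candidate = reconstruct_outline(
            efa_transform(candidate, BAND_LIMIT), len(candidate)
        )
        if _is_simple(candidate, min_clearance * size):
            return candidate
    raise ValueError("could not produce a simple outline in 100 attempts")


def render_outline(outline, image_size=(1200, 800), margin: float = 0.08) -> Image.Image:
    """Rasterize a y-up outline as a dark silhouette on a white background."""
    pts = np.asarray(outline, dtype=float)
    W, H = image_size
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    scale = min((1 - 2 * margin) * W / span[0], (1 - 2 * margin) * H / span[1])
    center = (lo + hi) / 2.0
    xy = (pts - center) * scale
    xy[:, 1] *= -1.0  # y-up -> image rows
    xy += np.array([W / 2.0, H / 2.0])
    img = Image.new("L", (W, H), 255)
    ImageDraw.Draw(img).polygon([tuple(p) for p in xy], fill=0)
    return img


def generate_dataset(config: SyntheticConfig, out_dir):
    """Generate silhouette images plus metadata and ground-truth tables.

    Hierarchical sampling: each species draws a mimicry level and a
    species-level outline perturbation; each specimen a smaller perturbation
    of its species shape; each recorded outline the smallest perturbation of
    its specimen.  Fully reproducible from ``config.seed``.

    Returns ``(metadata, ground_truth)`` DataFrames; files are written to
    ``out_dir`` as ``{species}_{specimen}_{outline}_{aspect}.png``,
    ``metadata.csv`` and ``ground_truth.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    meta_rows, truth_rows = [], []

    # each level's accepted shapes keep clearance for the levels below
    c_outline = MIN_CLEARANCE
    c_specimen = c_outline + 0.75 * config.outline_noise_sd
    c_species = c_specimen + 0.75 * config.specimen_noise_sd

    for group in config.groups:
        for s in range(config.n_species_per_group):
            species_id = f"{group}_s{s + 1:02d}"
            if group == "ant":
                m = 1.0
            else:
                m = float(
                    np.clip(
                        config.mimicry_by_group[group]
                        + config.mimicry_jitter_sd * rng.standard_normal(),
                        0.0, 1.0,
                    )
                )
            for aspect in config.aspects:
                plan = CANONICAL_PLANS[(GROUP_PLAN[group], aspect)]
                base = make_body_outline(plan, m, n_points=config.n_points)
                species_shape = perturb_outline(
                    base, config.species_noise_sd, rng=rng,
                    min_clearance=c_species,
                )
                truth_rows.append(
                    {"species_id": species_id, "group": group,
                     "aspect": aspect, "true_mimicry": m}
                )
                for j in range(config.n_specimens_per_species):
                    specimen_id = f"{species_id}_i{j + 1:02d}"
                    specimen_shape = perturb_outline(
                        species_shape, config.specimen_noise_sd, rng=rng,
                        min_clearance=c_specimen,
                    )
                    for k in range(config.n_outlines_per_specimen):
                        image_id = f"{species_id}_{j + 1:02d}_{k + 1:02d}_{aspect}"
                        o = perturb_outline(
                            specimen_shape, config.outline_noise_sd, rng=rng,
                            min_clearance=c_outline,
                        )
                        render_outline(o, config.image_size).save(
                            out_dir / f"{image_id}.png"
                        )
                        meta_rows.append(
                            {"image_id": image_id, "specimen_id": specimen_id,
                             "species_id": species_id, "group": group,
                             "aspect": aspect}
                        )

    metadata = pd.DataFrame(meta_rows)
    ground_truth = pd.DataFrame(truth_rows)
    metadata.to_csv(out_dir / "metadata.csv", index=False)
    ground_truth.to_csv(out_dir / "ground_truth.csv", index=False)
    return metadata, ground_truth
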