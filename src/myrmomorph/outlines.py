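"""Silhouette images, metadata, and outline standardization.

Input contract: monochrome silhouette images with a solid dark body shape on
a light background, body horizontal with the head to the left and appendages
excluded, plus a metadata table assigning each image to a specimen, species,
mimicry group and aspect (dorsal or lateral).

Outlines are plain ``(n, 2)`` float arrays of ``(x, y)`` vertices of a closed
polygon; the closing edge from the last vertex back to the first is implicit
(the first vertex is never repeated at the end).  ``extract_outline`` works in
image coordinates (x right, y down, origin top-left); :func:`to_math_coords`
converts to the y-up frame used by the Fourier analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from PIL import Image
from skimage import measure

GROUPS = ("ant", "mimic_spider", "mimic_insect", "non_mimic")
ASPECTS = ("dorsal", "lateral")
METADATA_COLUMNS = ("image_id", "specimen_id", "species_id", "group", "aspect")

#: binarization threshold for non-pure-binary inputs; foreground = darker side
BINARY_THRESHOLD = 128


class MetadataError(ValueError):
    """Malformed or invalid metadata table."""


class OutlineError(ValueError):
    """Outline extraction or standardization failure."""


def read_metadata(path) -> pd.DataFrame:
    """Read and validate the specimen metadata CSV.

    Required columns: image_id, specimen_id, species_id, group, aspect.
    ``group`` must be one of ``GROUPS`` and ``aspect`` one of ``ASPECTS``;
    image ids must be unique and each specimen must map to a single species,
    group, and (per image) aspect.
    """
    df = pd.read_csv(path, dtype=str)
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            raise MetadataError(f"metadata is missing required column {col!r}")
    df = df[list(METADATA_COLUMNS)].copy()
    for col in METADATA_COLUMNS:
        df[col] = df[col].astype(str).str.strip()

    for i, row in df.iterrows():
        if row["group"] not in GROUPS:
            raise MetadataError(
                f"row {i}: unknown group {row['group']!r} (expected one of {GROUPS})"
            )
        if row["aspect"] not in ASPECTS:
            raise MetadataError(
                f"row {i}: unknown aspect {row['aspect']!r} (expected one of {ASPECTS})"
            )
    dup = df["image_id"].duplicated()
    if dup.any():
        raise MetadataError(
            f"duplicate image_id values: {sorted(df.loc[dup, 'image_id'].unique())}"
        )
    # a specimen belongs to exactly one species and one group
    per_specimen = df.groupby("specimen_id")[["species_id", "group"]].nunique()
    bad = per_specimen[(per_specimen > 1).any(axis=1)]
    if len(bad):
        raise MetadataError(
            f"specimens mapped to multiple species/groups: {sorted(bad.index)}"
        )
    return df


def load_silhouette(path, threshold: int = BINARY_THRESHOLD) -> np.ndarray:
    """Load an image file as a boolean foreground mask (foreground = darker)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr < threshold


def signed_area(outline: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon (positive = counter-clockwise
    in a right-handed frame)."""
    x, y = outline[:, 0], outline[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def perimeter(outline: np.ndarray) -> float:
    """Total arc length of the closed polygon."""
    d = np.roll(outline, -1, axis=0) - outline
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _dedupe(points: np.ndarray) -> np.ndarray:
    keep = np.any(points != np.roll(points, 1, axis=0), axis=1)
    return points[keep]


def extract_outline(image) -> np.ndarray:
    """Trace the closed boundary of the largest foreground component.

    Parameters
    ----------
    image : array-like
        Boolean foreground mask, or a grey-level array which is binarized at
        ``BINARY_THRESHOLD`` (foreground = darker side).

    Returns
    -------
    ndarray of shape (n, 2)
        Sub-pixel boundary vertices (x, y) in image coordinates, traversed
        counter-clockwise when the y axis points down the screen.
    """
    arr = np.asarray(image)
    mask = arr if arr.dtype == bool else arr < BINARY_THRESHOLD
    if not mask.any():
        raise OutlineError("no silhouette found")

    labels = measure.label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background
    largest = counts.argmax()
    component = labels == largest

    # pad so the sub-pixel contour never touches the array border
    padded = np.pad(component, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise OutlineError("no silhouette found")
    # the outer boundary encloses the largest absolute area
    best = max(contours, key=lambda c: abs(signed_area(c[:, ::-1])))
    pts = best[:, ::-1] - 1.0  # (row, col) -> (x, y), undo padding
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    pts = _dedupe(np.ascontiguousarray(pts))
    if len(pts) < 3:
        raise OutlineError("degenerate silhouette boundary")
    # counter-clockwise as displayed (y down): positive shoelace on raw (x, y)
    if signed_area(pts) < 0:
        pts = np.roll(pts[::-1], 1, axis=0)
    return pts


def to_math_coords(outline: np.ndarray) -> np.ndarray:
    """Convert an image-coordinate outline to the y-up mathematical frame.

    Flips the y axis and reverses the traversal so the outline stays
    counter-clockwise in the new frame; the start point is preserved.
    """
    flipped = outline.copy()
    flipped[:, 1] *= -1.0
    return np.roll(flipped[::-1], 1, axis=0)


def subsample_outline(outline: np.ndarray, n: int = 1600) -> np.ndarray:
    """Resample a closed outline to ``n`` points equally spaced by arc length.

    The first output point coincides with the original first point and the
    traversal direction is preserved.
    """
    if n < 3:
        raise ValueError(f"n must be >= 3, got {n}")
    outline = np.asarray(outline, dtype=float)
    if len(outline) < 3:
        raise OutlineError("outline must have at least 3 points")
    closed = np.vstack([outline, outline[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    total = t[-1]
    if total <= 0:
        raise OutlineError("degenerate outline with zero perimeter")
    targets = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(targets, t, closed[:, 0])
    y = np.interp(targets, t, closed[:, 1])
    return np.column_stack([x, y])


def smooth_outline(outline: np.ndarray, iterations: int = 5) -> np.ndarray:
    """Cyclic sliding-average smoothing (window 3: a point and its two
    neighbours), applied ``iterations`` times.  Point count is unchanged."""
    if iterations < 0:
        raise ValueError(f"iterations must be >= 0, got {iterations}")
    pts = np.asarray(outline, dtype=float).copy()
    if len(pts) < 3:
        raise OutlineError("outline must have at least 3 points")
    for _ in range(iterations):
        pts = (np.roll(pts, 1, axis=0) + pts + np.roll(pts, -1, axis=0)) / 3.0
    return pts


def standardize_outline(
    image, n_points: int = 1600, smooth_iterations: int = 5
) -> np.ndarray:
    """extract -> y-up frame -> subsample -> smooth, the full standardization."""
    out = extract_outline(image)
    out = to_math_coords(out)
    out = subsample_outline(out, n_points)
    return smooth_outline(out, smooth_iterations)


def write_outlines(outlines: dict, path) -> None:
    """Write outlines to CSV with columns outline_id,point_index,x,y."""
    frames = []
    for outline_id, pts in outlines.items():
        pts = np.asarray(pts)
        frames.append(
            pd.DataFrame(
                {
                    "outline_id": outline_id,
                    "point_index": np.arange(len(pts)),
                    "x": pts[:, 0],
                    "y": pts[:, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_outlines(path) -> dict:
    """Inverse of :func:`write_outlines`; preserves first-appearance order."""
    df = pd.read_csv(path)
    out = {}
    for outline_id, sub in df.groupby("outline_id", sort=False):
        sub = sub.sort_values("point_index")
        out[outline_id] = sub[["x", "y"]].to_numpy(dtype=float)
    return out
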