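"""Elliptical Fourier analysis of closed outlines.

A closed outline is decomposed into per-harmonic coefficient quadruples
``(a_n, b_n, c_n, d_n)`` of the truncated series

    x(t) = A0 + sum_n a_n cos(n t) + b_n sin(n t)
    y(t) = C0 + sum_n c_n cos(n t) + d_n sin(n t),      t in [0, 2*pi)

computed with the piecewise-linear (Kuhl–Giardina) integrals over the
arc-length parametrized polygon.

Normalization makes the coefficients invariant to size, outline starting
position, and rotation — but, deliberately, only to rotations in
(−90°, +90°]: the rotation applied during normalization is reduced modulo
180°, so a shape and its 180°-rotated copy normalize to *different*
coefficient sets.  Ant-mimic silhouettes are prepared head-left, and a
normalization that silently identified head-left with head-right would
destroy exactly the anterior/posterior signal the analysis measures.  This
differs from the fully canonical first-ellipse normalization used by e.g. the
``efourier_norm`` convention, which is 180°-ambiguous.

For bilaterally symmetric animals photographed dorsally, any asymmetry in the
outline is an artefact of pose or camera position.  With the symmetry axis
horizontal and the series start point on it, mirror symmetry about that axis
is equivalent to ``b_n = c_n = 0`` for all harmonics (x even and y odd in t),
so :func:`remove_asymmetry` zeroes those coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .outlines import OutlineError

DEFAULT_HARMONICS = 40


class NormalizationError(ValueError):
    """First harmonic degenerate; coefficients cannot be normalized."""


@dataclass
class EFACoefficients:
    """Per-harmonic elliptic Fourier coefficients.

    ``coeffs`` has shape ``(H, 4)`` with columns ``a, b, c, d``; row ``n - 1``
    holds harmonic ``n``.  ``dc`` is the ``(A0, C0)`` centroid offset, zeroed
    by normalization.
    """

    coeffs: np.ndarray
    dc: tuple = (0.0, 0.0)
    normalized: bool = False
    symmetrized: bool = False

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 2 or self.coeffs.shape[1] != 4 or len(self.coeffs) < 1:
            raise ValueError("coeffs must have shape (H >= 1, 4)")

    @property
    def n_harmonics(self) -> int:
        return len(self.coeffs)

    def copy(self) -> "EFACoefficients":
        return replace(self, coeffs=self.coeffs.copy())

    def flatten(self) -> np.ndarray:
        """Row-major (a1, b1, c1, d1, a2, ...) vector for multivariate use."""
        return self.coeffs.ravel().copy()


@dataclass
class SpeciesShape:
    """A species' average shape: normalized coefficients plus bookkeeping."""

    species_id: str
    group: str
    aspect: str
    coefficients: EFACoefficients
    n_specimens: int = 1
    n_outlines: int = 1


def _closed_diffs(outline: np.ndarray):
    outline = np.asarray(outline, dtype=float)
    d = np.roll(outline, -1, axis=0) - outline
    dt = np.hypot(d[:, 0], d[:, 1])
    if np.any(dt == 0):
        keep = dt > 0
        outline, d, dt = outline[keep], d[keep], dt[keep]
    if len(outline) < 3:
        raise OutlineError("outline must have at least 3 distinct points")
    return outline, d, dt


def efa_transform(outline: np.ndarray, n_harmonics: int = DEFAULT_HARMONICS) -> EFACoefficients:
    """Elliptic Fourier transform of a closed polygon.

    Uses the exact integrals of the arc-length parametrized piecewise-linear
    contour; the reconstruction converges to the input as the harmonic count
    grows.
    """
    if n_harmonics < 1:
        raise ValueError(f"n_harmonics must be >= 1, got {n_harmonics}")
    pts, d, dt = _closed_diffs(outline)
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    phi = 2.0 * np.pi * t / T  # parameter angle at each vertex, phi[-1] = 2*pi

    n = np.arange(1, n_harmonics + 1)[:, None]  # (H, 1)
    cos_d = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])  # (H, K)
    sin_d = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    const = T / (2.0 * (n[:, 0] ** 2) * np.pi**2)

    vx = d[:, 0] / dt
    vy = d[:, 1] / dt
    a = const * (cos_d @ vx)
    b = const * (sin_d @ vx)
    c = const * (cos_d @ vy)
    dd = const * (sin_d @ vy)

    # dc terms = arc-length averaged position (trapezoid over segments)
    mid = (pts + np.roll(pts, -1, axis=0)) / 2.0
    dc = tuple((mid * dt[:, None]).sum(axis=0) / T)
    return EFACoefficients(np.column_stack([a, b, c, dd]), dc=dc)


def evaluate_series(coeffs: EFACoefficients, t) -> np.ndarray:
    """Evaluate the truncated series at arbitrary parameter angles ``t``.

    ``t`` is in radians over [0, 2*pi); for an outline transformed by
    :func:`efa_transform`, vertex ``i`` sits at ``t = 2*pi * s_i / S`` with
    ``s_i`` its cumulative arc length.
    """
    t = np.asarray(t, dtype=float)
    n = np.arange(1, coeffs.n_harmonics + 1)[:, None]
    cos_nt = np.cos(n * t)
    sin_nt = np.sin(n * t)
    a, b, c, d = coeffs.coeffs.T
    x = coeffs.dc[0] + a @ cos_nt + b @ sin_nt
    y = coeffs.dc[1] + c @ cos_nt + d @ sin_nt
    return np.column_stack([x, y])


def reconstruct_outline(coeffs: EFACoefficients, n_points: int) -> np.ndarray:
    """Evaluate the truncated series at ``n_points`` equally spaced parameters."""
    if n_points < 3:
        raise ValueError(f"n_points must be >= 3, got {n_points}")
    return evaluate_series(
        coeffs, np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    )


def _phase_shift(A: np.ndarray, theta: float) -> np.ndarray:
    """Advance the series start point by parameter ``theta``: C_n -> C_n R(n theta)."""
    n = np.arange(1, len(A) + 1)
    cn, sn = np.cos(n * theta), np.sin(n * theta)
    a, b, c, d = A.T
    return np.column_stack(
        [a * cn + b * sn, -a * sn + b * cn, c * cn + d * sn, -c * sn + d * cn]
    )


def _rotate(A: np.ndarray, angle: float) -> np.ndarray:
    """Rotate the shape by ``angle``: C_n -> R(angle) C_n."""
    cphi, sphi = np.cos(angle), np.sin(angle)
    a, b, c, d = A.T
    return np.column_stack(
        [a * cphi - c * sphi, b * cphi - d * sphi, a * sphi + c * cphi, b * sphi + d * cphi]
    )


def _wrap_half_pi(angle: float) -> float:
    """Reduce an angle modulo pi into (−pi/2, pi/2]."""
    a = (angle + np.pi / 2.0) % np.pi - np.pi / 2.0
    if a == -np.pi / 2.0:
        a = np.pi / 2.0
    return a


def _first_ellipse_phase(A: np.ndarray) -> float:
    """Start-point phase placing t = 0 on the first ellipse's major axis."""
    a1, b1, c1, d1 = A[0]
    theta = 0.5 * np.arctan2(
        2.0 * (a1 * b1 + c1 * d1), a1**2 + c1**2 - b1**2 - d1**2
    )
    shifted = _phase_shift(A[:1], theta)
    if np.hypot(shifted[0, 0], shifted[0, 2]) < np.hypot(shifted[0, 1], shifted[0, 3]):
        theta += np.pi / 2.0  # landed on the minor axis
    return theta


def normalize_coefficients(coeffs: EFACoefficients) -> EFACoefficients:
    """First-harmonic-ellipse normalization, preserving 180° flips.

    Steps: shift the start point to the first ellipse's major axis; rotate by
    the ellipse orientation *reduced modulo 180° into (−90°, +90°]*; scale by
    the semi-major magnitude; canonicalize the remaining start-point half-turn
    ambiguity so ``a1 > 0``.  The result is invariant to input scale, start
    point, and rotations that keep the major axis within (−90°, +90°] of
    horizontal, while an input and its 180°-rotated copy normalize to
    different coefficients.  DC terms are dropped.
    """
    A = coeffs.coeffs.copy()
    if np.hypot(*np.linalg.norm(A[0].reshape(2, 2), axis=1)) < 1e-12:
        raise NormalizationError("cannot normalize: degenerate first harmonic")

    theta = _first_ellipse_phase(A)
    A = _phase_shift(A, theta)

    psi = np.arctan2(A[0, 2], A[0, 0])  # major-axis orientation
    A = _rotate(A, -_wrap_half_pi(psi))

    scale = abs(A[0, 0])
    if scale < 1e-12:
        raise NormalizationError("cannot normalize: degenerate first harmonic")
    A /= scale

    if A[0, 0] < 0:  # resolve the half-period start ambiguity: negate odd harmonics
        odd = (np.arange(1, len(A) + 1) % 2) == 1
        A[odd] *= -1.0

    return EFACoefficients(A, dc=(0.0, 0.0), normalized=True, symmetrized=coeffs.symmetrized)


def remove_asymmetry(coeffs: EFACoefficients) -> EFACoefficients:
    """Zero the coefficients representing asymmetry about the horizontal axis.

    Assumes normalized coefficients (symmetry axis horizontal, start point on
    it).  ``b_n`` and ``c_n`` are set to 0 for every harmonic; the
    reconstruction is then exactly mirror-symmetric about the x axis.  A
    linear projection: idempotent and commuting with coefficient averaging.
    """
    A = coeffs.coeffs.copy()
    A[:, 1] = 0.0
    A[:, 2] = 0.0
    return EFACoefficients(
        A, dc=coeffs.dc, normalized=coeffs.normalized, symmetrized=True
    )


def average_coefficients(members) -> EFACoefficients:
    """Element-wise arithmetic mean of coefficient sets.

    Used hierarchically: outlines averaged per specimen, then specimen means
    averaged per species, so specimens are weighted equally regardless of how
    many outlines each contributed.
    """
    members = list(members)
    if not members:
        raise ValueError("cannot average an empty sequence of coefficients")
    H = members[0].n_harmonics
    if any(m.n_harmonics != H for m in members):
        raise ValueError("mismatched harmonic counts")
    stacked = np.stack([m.coeffs for m in members])
    dc = np.mean([m.dc for m in members], axis=0)
    return EFACoefficients(
        stacked.mean(axis=0),
        dc=tuple(dc),
        normalized=all(m.normalized for m in members),
        symmetrized=all(m.symmetrized for m in members),
    )


def _centered_unit(outline: np.ndarray):
    pts = np.asarray(outline, dtype=float)
    centered = pts - pts.mean(axis=0)
    size = np.sqrt((centered**2).sum())
    if size < 1e-12:
        raise OutlineError("degenerate (zero-size) outline")
    return centered / size


def _align_start(outline: np.ndarray) -> np.ndarray:
    """Roll the start index to the first-ellipse major-axis end with a1* > 0."""
    A = efa_transform(outline, 1).coeffs
    theta = _first_ellipse_phase(A)
    if _phase_shift(A, theta)[0, 0] < 0:
        theta += np.pi
    shift = int(round(theta / (2.0 * np.pi) * len(outline))) % len(outline)
    return np.roll(outline, -shift, axis=0)


def procrustes_align(outlines, max_iter: int = 100, tol: float = 1e-9):
    """Partial Procrustes superimposition with rotations restricted to
    (−90°, +90°].

    Each outline is translated to zero centroid and scaled to unit centroid
    size; start points are phase-aligned to the first-ellipse major axis so
    point indices correspond; outlines are then iteratively rotated onto the
    evolving mean shape.  The optimal rotation angle is reduced modulo 180°
    into (−90°, +90°] before being applied, so head-left shapes are never
    flipped head-right: an outline and its 180°-rotated copy are *not*
    superimposed onto each other.
    """
    outlines = [np.asarray(o, dtype=float) for o in outlines]
    if len(outlines) < 2:
        raise ValueError("need at least 2 outlines to superimpose")
    npts = {len(o) for o in outlines}
    if len(npts) != 1:
        raise ValueError(f"mismatched point counts: {sorted(npts)}")

    X = [_align_start(_centered_unit(o)) for o in outlines]
    mean = X[0].copy()
    mean /= np.sqrt((mean**2).sum())
    for _ in range(max_iter):
        for i, x in enumerate(X):
            num = float(np.sum(x[:, 0] * mean[:, 1] - x[:, 1] * mean[:, 0]))
            den = float(np.sum(x[:, 0] * mean[:, 0] + x[:, 1] * mean[:, 1]))
            ang = _wrap_half_pi(np.arctan2(num, den))
            ca, sa = np.cos(ang), np.sin(ang)
            X[i] = x @ np.array([[ca, sa], [-sa, ca]])
        new_mean = np.mean(X, axis=0)
        new_mean -= new_mean.mean(axis=0)
        new_mean /= np.sqrt((new_mean**2).sum())
        if np.abs(new_mean - mean).max() < tol:
            mean = new_mean
            break
        mean = new_mean
    return X


def write_coefficients(shapes, path, sidecar_path=None, pipeline_version: str = "") -> None:
    """Write coefficient sets to the interchange CSV
    (shape_id, level, harmonic, a, b, c, d) plus an optional JSON sidecar.

    ``shapes`` maps ``shape_id -> (level, EFACoefficients)`` with level in
    {outline, specimen, species}.
    """
    import json

    import pandas as pd

    rows = []
    H = None
    flags = {}
    for shape_id, (level, cf) in shapes.items():
        H = cf.n_harmonics
        flags = {"normalized": cf.normalized, "symmetrized": cf.symmetrized}
        for h in range(H):
            a, b, c, d = cf.coeffs[h]
            rows.append(
                {"shape_id": shape_id, "level": level, "harmonic": h + 1,
                 "a": a, "b": b, "c": c, "d": d}
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(
                {"n_harmonics": H, **flags, "pipeline_version": pipeline_version},
                fh, indent=2,
            )


def read_coefficients(path) -> dict:
    """Inverse of :func:`write_coefficients` (flags not recovered)."""
    import pandas as pd

    df = pd.read_csv(path)
    out = {}
    for shape_id, sub in df.groupby("shape_id", sort=False):
        sub = sub.sort_values("harmonic")
        level = sub["level"].iloc[0]
        out[shape_id] = (level, EFACoefficients(sub[["a", "b", "c", "d"]].to_numpy()))
    return out
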