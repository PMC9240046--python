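"""Planar geometric primitives for segmented OCT B-scan boundary curves.

Every optic-nerve-head index in this package is built from a handful of
exact polyline queries in a per-section 2D frame:

* ``x`` — lateral position in µm, strictly increasing along every curve;
* ``z`` — axial depth in µm, increasing posteriorly (deeper = larger z).

Curves (internal limiting membrane, Bruch's membrane, anterior lamina
cribrosa surface) are polylines with linear interpolation between samples.
All distance queries are closed-form per segment, so they are exact for
polyline inputs and serve as the trusted base for the morphometry layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryError",
    "CollinearOverlapError",
    "Point2D",
    "Curve2D",
    "ReferenceLine",
    "BScanSection",
    "LOCATIONS",
    "CURVE_ROLES",
    "signed_distance_to_line",
    "curve_line_intersections",
    "min_distance_point_to_curve",
    "perpendicular_foot_on_curve",
]

LOCATIONS = ("superior_mid", "central", "inferior_mid")
CURVE_ROLES = ("ILM", "BM", "ALCS")


class GeometryError(ValueError):
    """Invalid geometric input or unsatisfiable geometric query."""


class CollinearOverlapError(GeometryError):
    """A curve segment lies exactly on the query line (degenerate overlap)."""


@dataclass(frozen=True)
class Point2D:
    """A point in the section frame (x lateral µm, z axial µm, posterior-positive)."""

    x: float
    z: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.z)):
            raise GeometryError(f"non-finite point coordinates ({self.x}, {self.z})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.z], dtype=float)


@dataclass
class Curve2D:
    """An open polyline with strictly increasing x.

    Parameters
    ----------
    points
        ``(N, 2)`` array of (x, z) samples, N ≥ 2.
    role
        One of ``"ILM"``, ``"BM"``, ``"ALCS"``.
    """

    points: np.ndarray
    role: str = "ILM"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise GeometryError("curve requires an (N>=2, 2) array of points")
        if not np.all(np.isfinite(pts)):
            raise GeometryError("curve contains non-finite coordinates")
        if not np.all(np.diff(pts[:, 0]) > 0):
            raise GeometryError("curve x-coordinates must be strictly increasing")
        if self.role not in CURVE_ROLES:
            raise GeometryError(f"unknown curve role {self.role!r}")
        self.points = pts

    @property
    def xs(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def zs(self) -> np.ndarray:
        return self.points[:, 1]

    def x_span(self) -> tuple[float, float]:
        return float(self.points[0, 0]), float(self.points[-1, 0])


@dataclass(frozen=True)
class ReferenceLine:
    """The infinite line through two distinct points (e.g. the BMO reference line)."""

    p1: Point2D
    p2: Point2D

    def __post_init__(self) -> None:
        if self.p1.x == self.p2.x and self.p1.z == self.p2.z:
            raise GeometryError("degenerate reference line: p1 == p2")

    def direction(self) -> np.ndarray:
        d = self.p2.as_array() - self.p1.as_array()
        return d / np.linalg.norm(d)

    def posterior_normal(self) -> np.ndarray:
        """Unit normal pointing to the posterior (larger-z) side of the line.

        For a vertical-normal degenerate orientation (line parallel to the z
        axis) the normal with positive x is returned.
        """
        dx, dz = self.direction()
        n = np.array([-dz, dx])
        if n[1] < 0 or (n[1] == 0 and n[0] < 0):
            n = -n
        return n


def signed_distance_to_line(p: Point2D, line: ReferenceLine) -> float:
    """Perpendicular distance from ``p`` to ``line``, positive on the posterior side."""
    n = line.posterior_normal()
    return float(np.dot(p.as_array() - line.p1.as_array(), n))


def curve_line_intersections(
    curve: Curve2D, line: ReferenceLine, tol: float = 1e-9
) -> list[Point2D]:
    """All intersections of a polyline with an infinite line, ordered by x.

    Segment–line intersections are solved exactly for linear segments.
    A segment lying on the line (both endpoints within ``tol``) is a
    degenerate overlap and raises :class:`CollinearOverlapError` rather than
    returning a silent answer.
    """
    n = line.posterior_normal()
    s = (curve.points - line.p1.as_array()) @ n
    on = np.abs(s) <= tol
    if np.any(on[:-1] & on[1:]):
        raise CollinearOverlapError("curve segment collinear with the query line")

    hits: list[tuple[float, float]] = [
        (curve.points[i, 0], curve.points[i, 1]) for i in np.nonzero(on)[0]
    ]
    a, b = s[:-1], s[1:]
    crossing = (a * b < 0) & ~on[:-1] & ~on[1:]
    for i in np.nonzero(crossing)[0]:
        t = a[i] / (a[i] - b[i])
        pt = curve.points[i] + t * (curve.points[i + 1] - curve.points[i])
        hits.append((pt[0], pt[1]))

    hits.sort(key=lambda h: h[0])
    out: list[Point2D] = []
    for x, z in hits:
        if out and abs(x - out[-1].x) <= 1e-6 and abs(z - out[-1].z) <= 1e-6:
            continue
        out.append(Point2D(x, z))
    return out


def min_distance_point_to_curve(p: Point2D, curve: Curve2D) -> tuple[float, Point2D]:
    """Exact minimum Euclidean distance from ``p`` to the polyline.

    Uses the closed-form projection onto every segment (not vertex-only).
    Returns ``(distance, foot)``; ties are broken by the smaller foot x.
    """
    q = p.as_array()
    a = curve.points[:-1]
    d = curve.points[1:] - a
    seg_len2 = np.einsum("ij,ij->i", d, d)
    t = np.clip(np.einsum("ij,ij->i", q - a, d) / seg_len2, 0.0, 1.0)
    feet = a + t[:, None] * d
    dist = np.linalg.norm(q - feet, axis=1)
    dmin = dist.min()
    cand = np.nonzero(dist <= dmin + 1e-12)[0]
    best = cand[np.argmin(feet[cand, 0])]
    return float(dist[best]), Point2D(float(feet[best, 0]), float(feet[best, 1]))


def perpendicular_foot_on_curve(
    p: Point2D, line: ReferenceLine, curve: Curve2D, tol: float = 1e-9
) -> Point2D:
    """First intersection of the posterior perpendicular through ``p`` with ``curve``.

    The ray starts at ``p`` and runs perpendicular to ``line`` toward the
    posterior (larger-z) side. Raises :class:`GeometryError` when the ray
    never meets the curve (e.g. lamina surface not visible under a Bruch's
    membrane opening point), which marks the section unusable for curvature.
    """
    n = line.posterior_normal()
    q = p.as_array()
    a = curve.points[:-1]
    d = curve.points[1:] - a
    # Solve a + u*d = q + t*n per segment via 2D cross products.
    denom = d[:, 0] * n[1] - d[:, 1] * n[0]
    rel = q - a
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (rel[:, 0] * n[1] - rel[:, 1] * n[0]) / denom
    valid = (np.abs(denom) > 1e-15) & (u >= -tol) & (u <= 1 + tol)
    if not np.any(valid):
        raise GeometryError("perpendicular ray does not meet the curve")
    pts = a[valid] + np.clip(u[valid], 0.0, 1.0)[:, None] * d[valid]
    t = (pts - q) @ n
    ahead = t >= -1e-9
    if not np.any(ahead):
        raise GeometryError(
            "curve not visible on the posterior side of the perpendicular ray"
        )
    pts, t = pts[ahead], t[ahead]
    best = int(np.argmin(t))
    return Point2D(float(pts[best, 0]), float(pts[best, 1]))


@dataclass
class BScanSection:
    """One horizontal B-scan's boundary curves and BMO termination points.

    ``scan_offset`` is the scan index relative to the location's central
    scan; the nine target scans sit at offsets −2/0/+2 in each of the three
    locations, with adjacent-scan replacements (±1) used when a vessel
    shadow makes a target scan uninterpretable.
    """

    section_id: str
    location: str
    scan_offset: int
    ilm: Curve2D
    bm: Curve2D
    alcs: Curve2D
    bmo_temporal: Point2D
    bmo_nasal: Point2D
    quality_score: float
    flags: set[str] = field(default_factory=set)

    # Usable-quality threshold of the acquisition device: sections with a
    # quality score of 15 or less are not produced / not analysable.
    QUALITY_FLOOR = 15.0

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise GeometryError(f"unknown section location {self.location!r}")
        if self.bmo_temporal.x >= self.bmo_nasal.x:
            raise GeometryError("bmo_temporal.x must be < bmo_nasal.x")

    def validate(self, bm_tol: float = 1.0) -> None:
        """Check structural invariants (BMO points on BM, ALCS span, quality)."""
        for name, p in (("temporal", self.bmo_temporal), ("nasal", self.bmo_nasal)):
            d, _ = min_distance_point_to_curve(p, self.bm)
            if d > bm_tol:
                raise GeometryError(
                    f"BMO {name} point is {d:.2f} µm off the BM curve (tol {bm_tol})"
                )
        lo, hi = self.alcs.x_span()
        if lo > self.bmo_temporal.x or hi < self.bmo_nasal.x:
            raise GeometryError("ALCS does not span the BMO")
        if not self.is_usable:
            raise GeometryError(
                f"section quality score {self.quality_score} at or below "
                f"{self.QUALITY_FLOOR}"
            )

    @property
    def is_usable(self) -> bool:
        return self.quality_score > self.QUALITY_FLOOR
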