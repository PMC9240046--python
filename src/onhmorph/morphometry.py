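"""Optic-nerve-head indices measured on one B-scan section and per-eye aggregation.

Four indices are computed from the segmented boundary curves of a horizontal
B-scan through the optic nerve head:

* **HRW** (horizontal rim width, µm) — distance along the BMO reference line
  from a BMO termination point to the nearest ILM crossing of that line on
  the same rim side.
* **MRW** (minimum rim width, µm) — minimum Euclidean distance from a BMO
  termination point to the ILM; here the minimum within the selected
  horizontal section, not the radial-scan BMO-MRW of the Spectralis protocol.
* **HMR** — the per-measurement ratio HRW/MRW.
* **LCCI** (lamina cribrosa curvature index) — 100 · LCCD / W, where W is
  the BMO width and LCCD the maximum depth of the anterior lamina surface
  below the chord between the two perpendicular foot points dropped from
  the BMO termination points. Normalising by W makes LCCI independent of
  the physical size of the nerve head.

Per-eye aggregation follows the acquisition protocol: indices are measured
on three scans (separated by two scan intervals) at each of three vertical
locations — central, superior and inferior mid-periphery — and averaged
first within a location, then across the three locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    BScanSection,
    GeometryError,
    Point2D,
    ReferenceLine,
    LOCATIONS,
    curve_line_intersections,
    min_distance_point_to_curve,
    perpendicular_foot_on_curve,
)

__all__ = [
    "MorphometryError",
    "RimAbsentError",
    "SectionIndices",
    "MorphometryResult",
    "bmo_reference_line",
    "compute_hrw",
    "compute_mrw",
    "compute_lcci",
    "section_indices",
    "aggregate_eye",
    "disc_ovality",
    "torsion_angle",
]


class MorphometryError(ValueError):
    """A section cannot yield the requested index."""


class RimAbsentError(MorphometryError):
    """No ILM crossing of the BMO reference line on the requested rim side."""


@dataclass
class SectionIndices:
    """Per-section index values; flagged sides carry NaN."""

    section_id: str
    hrw_temporal: float
    hrw_nasal: float
    mrw_temporal: float
    mrw_nasal: float
    w: float
    lccd: float
    lcci: float
    flags: set[str] = field(default_factory=set)

    @property
    def hrw(self) -> float:
        return float(np.nanmean([self.hrw_temporal, self.hrw_nasal]))

    @property
    def mrw(self) -> float:
        return float(np.nanmean([self.mrw_temporal, self.mrw_nasal]))

    @property
    def hmr(self) -> float:
        """Mean over rim sides of the per-side HRW/MRW ratio."""
        ratios = [
            self.hrw_temporal / self.mrw_temporal,
            self.hrw_nasal / self.mrw_nasal,
        ]
        return float(np.nanmean(ratios))

    @property
    def hmr_temporal(self) -> float:
        return self.hrw_temporal / self.mrw_temporal


@dataclass
class MorphometryResult:
    """Per-eye aggregated indices (overall and temporal-rim-only)."""

    eye_id: str
    mean_hrw: float
    mean_mrw: float
    mean_hmr: float
    mean_lcci: float
    temporal_hrw: float
    temporal_mrw: float
    temporal_hmr: float
    per_location: dict[str, dict[str, float]]
    n_usable_scans: int
    flags: set[str] = field(default_factory=set)


def bmo_reference_line(section: BScanSection) -> tuple[ReferenceLine, float]:
    """The line through the two BMO termination points and the BMO width W (µm)."""
    line = ReferenceLine(section.bmo_temporal, section.bmo_nasal)
    w = float(
        np.linalg.norm(section.bmo_nasal.as_array() - section.bmo_temporal.as_array())
    )
    return line, w


def compute_hrw(section: BScanSection, side: str) -> float:
    """Horizontal rim width on one side, measured along the BMO reference line.

    The distance runs from the BMO termination point (which lies on the
    line) to the nearest ILM–line intersection on the rim side of that
    point (temporal: x < bmo_temporal.x; nasal: x > bmo_nasal.x). Raises
    :class:`RimAbsentError` when the ILM never crosses the line on that
    side, in which case the value is excluded from aggregation.
    """
    if side not in ("temporal", "nasal"):
        raise ValueError(f"side must be 'temporal' or 'nasal', got {side!r}")
    line, _ = bmo_reference_line(section)
    bmo = section.bmo_temporal if side == "temporal" else section.bmo_nasal
    crossings = curve_line_intersections(section.ilm, line)
    if side == "temporal":
        candidates = [c for c in crossings if c.x < bmo.x]
    else:
        candidates = [c for c in crossings if c.x > bmo.x]
    if not candidates:
        raise RimAbsentError(f"{side} rim absent/unmeasurable: no ILM-line crossing")
    dists = [np.linalg.norm(c.as_array() - bmo.as_array()) for c in candidates]
    return float(min(dists))


def compute_mrw(section: BScanSection, side: str) -> float:
    """Minimum rim width: minimum distance from the BMO point to the ILM."""
    if side not in ("temporal", "nasal"):
        raise ValueError(f"side must be 'temporal' or 'nasal', got {side!r}")
    bmo = section.bmo_temporal if side == "temporal" else section.bmo_nasal
    d, _ = min_distance_point_to_curve(bmo, section.ilm)
    return d


def compute_lcci(section: BScanSection) -> tuple[float, float, float]:
    """Lamina cribrosa curvature of one section: returns ``(w, lccd, lcci)``.

    Steps: (1) BMO reference line and width W; (2) perpendiculars dropped
    from each BMO point to the anterior lamina surface define two foot
    points; (3) the chord between the feet is the depth reference;
    (4) LCCD is the maximum perpendicular depth of the lamina surface below
    that chord, restricted laterally to the span between the feet (only the
    lamina within the BMO is considered); (5) LCCI = 100 · LCCD / W.
    """
    line, w = bmo_reference_line(section)
    try:
        foot_t = perpendicular_foot_on_curve(section.bmo_temporal, line, section.alcs)
        foot_n = perpendicular_foot_on_curve(section.bmo_nasal, line, section.alcs)
    except GeometryError as exc:
        raise MorphometryError(f"ALCS not visible under BMO point: {exc}") from exc
    if abs(foot_t.x - foot_n.x) < 1e-9 and abs(foot_t.z - foot_n.z) < 1e-9:
        raise MorphometryError("degenerate lamina chord: coincident foot points")
    chord = ReferenceLine(foot_t, foot_n)
    n = chord.posterior_normal()
    lo, hi = sorted((foot_t.x, foot_n.x))
    pts = section.alcs.points
    mask = (pts[:, 0] >= lo) & (pts[:, 0] <= hi)
    depth = (pts[mask] - foot_t.as_array()) @ n
    # The chord endpoints are on the curve at depth 0, so the maximum is >= 0;
    # clamp away numerically negative residue for flat laminas.
    lccd = float(max(depth.max(initial=0.0), 0.0))
    return w, lccd, 100.0 * lccd / w


def section_indices(section: BScanSection) -> SectionIndices:
    """Measure all indices of one section, flagging unmeasurable parts with NaN."""
    flags = set(section.flags)
    vals: dict[str, float] = {}
    for side in ("temporal", "nasal"):
        try:
            vals[f"hrw_{side}"] = compute_hrw(section, side)
        except RimAbsentError:
            vals[f"hrw_{side}"] = float("nan")
            flags.add(f"rim_absent_{side}")
        vals[f"mrw_{side}"] = compute_mrw(section, side)
    try:
        w, lccd, lcci = compute_lcci(section)
    except MorphometryError:
        _, w = bmo_reference_line(section)
        lccd, lcci = float("nan"), float("nan")
        flags.add("lcci_unmeasurable")
    return SectionIndices(
        section_id=section.section_id,
        hrw_temporal=vals["hrw_temporal"],
        hrw_nasal=vals["hrw_nasal"],
        mrw_temporal=vals["mrw_temporal"],
        mrw_nasal=vals["mrw_nasal"],
        w=w,
        lccd=lccd,
        lcci=lcci,
        flags=flags,
    )


def aggregate_eye(
    indices_by_location: dict[str, list[SectionIndices]], eye_id: str = ""
) -> MorphometryResult:
    """Aggregate per-scan indices to per-eye means.

    The location value is the unweighted mean over its usable scans (1–3);
    the eye value is the unweighted mean over the three locations. HMR is
    averaged as a per-section ratio, not recomputed from the aggregated
    HRW and MRW means. A location with no usable scan flags the eye
    ``incomplete`` and yields NaN eye means.
    """
    flags: set[str] = set()
    per_location: dict[str, dict[str, float]] = {}
    variables = (
        "hrw",
        "mrw",
        "hmr",
        "lcci",
        "hrw_temporal",
        "mrw_temporal",
        "hmr_temporal",
    )
    n_usable = 0
    for loc in LOCATIONS:
        scans = indices_by_location.get(loc, [])
        if not scans:
            flags.add("incomplete")
            per_location[loc] = {v: float("nan") for v in variables}
            continue
        n_usable += len(scans)
        loc_vals: dict[str, float] = {}
        for v in variables:
            vals = [getattr(s, v) for s in scans]
            loc_vals[v] = float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else float("nan")
        per_location[loc] = loc_vals

    def eye_mean(v: str) -> float:
        vals = [per_location[loc][v] for loc in LOCATIONS]
        return float(np.mean(vals))  # NaN propagates for incomplete eyes

    return MorphometryResult(
        eye_id=eye_id,
        mean_hrw=eye_mean("hrw"),
        mean_mrw=eye_mean("mrw"),
        mean_hmr=eye_mean("hmr"),
        mean_lcci=eye_mean("lcci"),
        temporal_hrw=eye_mean("hrw_temporal"),
        temporal_mrw=eye_mean("mrw_temporal"),
        temporal_hmr=eye_mean("hmr_temporal"),
        per_location=per_location,
        n_usable_scans=n_usable,
        flags=flags,
    )


def disc_ovality(longest_diameter: float, shortest_diameter: float) -> float:
    """Tilt ratio (ovality index): longest / shortest disc diameter.

    Values above 1.3 define a tilted disc for screening purposes.
    """
    if shortest_diameter <= 0:
        raise ValueError("shortest diameter must be positive")
    if longest_diameter < shortest_diameter:
        raise ValueError("longest diameter must be >= shortest diameter")
    return longest_diameter / shortest_diameter


def torsion_angle(long_axis_azimuth_deg: float) -> float:
    """Absolute deviation of the disc long axis from the vertical meridian (deg).

    Input azimuth must lie in (−90, 90]; values above 15° define torsion
    for screening purposes (strict inequality).
    """
    if not (-90 < long_axis_azimuth_deg <= 90):
        raise ValueError("azimuth must be in (-90, 90] degrees")
    return abs(long_axis_azimuth_deg)
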