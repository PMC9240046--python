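"""Synthetic three-group cohort generator (NTG, CRAO, healthy fellow eyes).

The generator plays the role of the study population: per-eye *latent* index
values (HRW*, MRW*, LCCI*) and clinical covariates are drawn from truncated
normal distributions whose moments are the packaged group parameters, and
each eye's nine B-scan sections are then *rendered* as explicit boundary
polylines constructed so that the morphometry module measures back the
latent values (construct-then-measure residual below 1 µm before jitter).
This makes every downstream stage — measurement, screening, matching and
statistics — testable end to end without any imaging data.

Distributional assumptions (documented, not data-derived):

* indices are independent within an eye apart from the hard constraint
  MRW* ≤ 0.98 · HRW*, imposed by truncating the MRW draw;
* within-eye scan-to-scan variability is multiplicative jitter with a small
  SD (default 2 % of the value);
* healthy eyes are fellow eyes of the CRAO subjects and share subject-level
  age and sex with their partner eye.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtr, ndtri

from .geometry import BScanSection, Curve2D, Point2D, LOCATIONS

__all__ = [
    "SyntheticError",
    "ConfigError",
    "GroupParams",
    "EyeRecord",
    "Cohort",
    "CohortConfig",
    "load_group_params",
    "load_screening_frequencies",
    "default_params_path",
    "sample_eye",
    "build_section",
    "render_sections",
    "generate_cohort",
    "generate_screening_pool",
    "simulate_observers",
]

GROUP_ORDER = ("NTG", "CRAO", "healthy")
RNFL_SECTORS = (
    "global",
    "temporal_superior",
    "temporal",
    "temporal_inferior",
    "nasal_inferior",
    "nasal",
    "nasal_superior",
)
#: vertical positions of the three measurement locations as fractions of the
#: vertical disc diameter ("equidistant" placement)
LOCATION_FRACTIONS = {"superior_mid": 0.25, "central": 0.5, "inferior_mid": 0.75}
SCAN_SPACING_UM = 32.0  # vertical distance between adjacent B-scans
#: replacement scan offsets used when a vessel shadow obscures a target scan
REPLACEMENT_OFFSET = {-2: -1, 0: 1, 2: 3}


class SyntheticError(ValueError):
    """Generator cannot realise the requested configuration."""


class ConfigError(ValueError):
    """Invalid cohort/pipeline configuration."""


@dataclass
class GroupParams:
    """Generative moments of one diagnostic group."""

    group: str
    n: int
    indices: dict[str, tuple[float, float]]  # hrw, mrw, lcci -> (mean, sd)
    covariates: dict[str, tuple[float, float]]
    rnfl: dict[str, tuple[float, float]]
    male_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigError(f"group {self.group}: n must be >= 0, got {self.n}")
        for name, (_, sd) in {**self.indices, **self.covariates, **self.rnfl}.items():
            if sd < 0:
                raise ConfigError(f"group {self.group}: negative SD for {name}")


def default_params_path() -> str:
    return str(
        importlib.resources.files("onhmorph").joinpath("data/group_parameters.yaml")
    )


def _load_yaml(path: str | None) -> dict[str, Any]:
    with open(path or default_params_path()) as fh:
        return yaml.safe_load(fh)


def load_group_params(path: str | None = None) -> dict[str, GroupParams]:
    """Load the packaged (or a user) group-parameter file."""
    raw = _load_yaml(path)
    out: dict[str, GroupParams] = {}
    for group, g in raw["groups"].items():
        def ms(key: str) -> tuple[float, float]:
            return float(g[key]["mean"]), float(g[key]["sd"])

        covar_keys = ("age", "spherical_equivalent", "iop_at_oct", "disc_area", "ovality")
        out[group] = GroupParams(
            group=group,
            n=int(g["n"]),
            indices={k: ms(k) for k in ("hrw", "mrw", "lcci")},
            covariates={k: ms(k) for k in covar_keys},
            rnfl={
                k: (float(v["mean"]), float(v["sd"])) for k, v in g["rnfl"].items()
            },
            male_fraction=float(g.get("male_fraction", 0.5)),
        )
    return out


def load_screening_frequencies(path: str | None = None) -> dict[str, dict[str, int]]:
    return _load_yaml(path)["screening_pool"]


@dataclass
class EyeRecord:
    """One eye's clinical covariates, exclusion attributes and latent indices."""

    eye_id: str
    subject_id: str
    group: str
    age: float
    sex: str
    spherical_equivalent: float
    iop_at_oct: float
    max_iop: float
    disc_area: float
    ovality: float
    torsion_deg: float
    rnfl: dict[str, float]
    latent: dict[str, float]  # hrw, mrw, lcci
    crao_subtype: str = ""  # incomplete | subtotal | total ("" if not CRAO)
    neovascular_glaucoma: bool = False
    quality_fail_sections: int = 0
    vf_glaucomatous: bool = False
    prior_surgery: bool = False
    retinal_or_neuro_disease: bool = False
    branch_rao: bool = False
    glaucoma_history: bool = False
    sections: list[BScanSection] = field(default_factory=list)

    def to_row(self) -> dict[str, Any]:
        row = {
            "eye_id": self.eye_id,
            "subject_id": self.subject_id,
            "group": self.group,
            "age": self.age,
            "sex": self.sex,
            "spherical_equivalent": self.spherical_equivalent,
            "iop_at_oct": self.iop_at_oct,
            "max_iop": self.max_iop,
            "disc_area": self.disc_area,
            "ovality": self.ovality,
            "torsion_deg": self.torsion_deg,
            "crao_subtype": self.crao_subtype,
            "neovascular_glaucoma": self.neovascular_glaucoma,
            "quality_fail_sections": self.quality_fail_sections,
            "vf_glaucomatous": self.vf_glaucomatous,
            "prior_surgery": self.prior_surgery,
            "retinal_or_neuro_disease": self.retinal_or_neuro_disease,
            "branch_rao": self.branch_rao,
            "glaucoma_history": self.glaucoma_history,
            "latent_hrw": self.latent["hrw"],
            "latent_mrw": self.latent["mrw"],
            "latent_lcci": self.latent["lcci"],
        }
        for sector in RNFL_SECTORS:
            row[f"rnfl_{sector}"] = self.rnfl[sector]
        return row


@dataclass
class Cohort:
    """Eyes-by-covariates table plus the full records (with rendered sections)."""

    table: pd.DataFrame
    eyes: dict[str, EyeRecord]


@dataclass
class CohortConfig:
    """Generator settings; defaults are the study conditions."""

    groups: dict[str, int] = field(
        default_factory=lambda: {"NTG": 31, "CRAO": 31, "healthy": 31}
    )
    params_path: str | None = None
    jitter_sd: float = 0.02
    vessel_shadow_rate: float = 0.02
    tilt_sd_deg: float = 0.4
    observer_noise_sd: float = 0.02
    render: bool = True

    def validate(self) -> None:
        for name, n in self.groups.items():
            if not isinstance(n, int) or n < 0:
                raise ConfigError(f"groups[{name!r}] must be a non-negative integer")
        n_h = self.groups.get("healthy", 0)
        n_c = self.groups.get("CRAO", 0)
        if n_h and n_h != n_c:
            raise ConfigError(
                "groups['healthy'] must equal groups['CRAO'] "
                "(healthy eyes are fellow eyes of the CRAO subjects)"
            )
        for name in ("jitter_sd", "vessel_shadow_rate", "tilt_sd_deg", "observer_noise_sd"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ConfigError(f"{name} must be in [0, 1), got {v}")


def _rng(seed: int | tuple) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed))


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    low: float = -np.inf,
    high: float = np.inf,
) -> float:
    """One draw from N(mean, sd) truncated to (low, high], via inverse CDF.

    Equivalent in distribution to rejection resampling but loop-free and
    deterministic given the generator state. An interval carrying
    (numerically) no probability mass is the case in which resampling would
    never terminate, and raises :class:`SyntheticError`.
    """
    if sd == 0:
        if low <= mean <= high:
            return mean
        raise SyntheticError(
            f"degenerate distribution mean {mean} outside truncation ({low}, {high}]"
        )
    a, b = (low - mean) / sd, (high - mean) / sd
    pa = float(ndtr(a)) if np.isfinite(a) else 0.0
    pb = float(ndtr(b)) if np.isfinite(b) else 1.0
    if not a < b or (pb - pa) < 1e-12:
        raise SyntheticError(
            f"infeasible truncation ({low}, {high}] for N({mean}, {sd})"
        )
    return float(mean + sd * ndtri(pa + rng.random() * (pb - pa)))


def sample_eye(
    params: GroupParams,
    seed: int | tuple,
    shared: dict[str, Any] | None = None,
) -> EyeRecord:
    """Draw one eye's latent indices and covariates (no geometry yet).

    ``shared`` may carry subject-level attributes (``age``, ``sex``,
    ``subject_id``) from a paired fellow eye. Deterministic given ``seed``.
    """
    rng = _rng(seed)
    cv = params.covariates
    age = shared["age"] if shared and "age" in shared else _truncated_normal(
        rng, *cv["age"], low=18.0, high=95.0
    )
    sex = shared["sex"] if shared and "sex" in shared else (
        "M" if rng.random() < params.male_fraction else "F"
    )
    se = _truncated_normal(rng, *cv["spherical_equivalent"], low=-8.0, high=3.0)
    iop = _truncated_normal(rng, *cv["iop_at_oct"], low=5.0, high=20.0)
    max_iop = _truncated_normal(rng, iop + 2.0, 1.2, low=iop, high=21.0)
    disc_area = _truncated_normal(rng, *cv["disc_area"], low=1.0, high=5.0)
    ovality = _truncated_normal(rng, *cv["ovality"], low=1.0, high=1.3)
    torsion = _truncated_normal(rng, 0.0, 5.0, low=0.0, high=14.5)
    rnfl = {
        sector: _truncated_normal(rng, *params.rnfl[sector], low=5.0)
        for sector in RNFL_SECTORS
    }
    # Joint draw of (HRW*, MRW*): the rim-width pair is resampled (bounded)
    # when the HRW draw leaves no room for MRW in (10, 0.98*HRW].
    for attempt in range(100):
        hrw = _truncated_normal(rng, *params.indices["hrw"], low=10.0)
        try:
            mrw = _truncated_normal(
                rng, *params.indices["mrw"], low=10.0, high=0.98 * hrw
            )
            break
        except SyntheticError:
            continue
    else:
        raise SyntheticError(
            f"group {params.group}: rim-width parameters leave no feasible "
            "(HRW, MRW) pairs after bounded resampling"
        )
    lcci = _truncated_normal(rng, *params.indices["lcci"], low=1e-6)

    group = params.group
    subtype = ""
    if group == "CRAO":
        subtype = "subtotal" if rng.random() < 0.5 else "total"
    return EyeRecord(
        eye_id="",
        subject_id=shared.get("subject_id", "") if shared else "",
        group=group,
        age=age,
        sex=sex,
        spherical_equivalent=se,
        iop_at_oct=iop,
        max_iop=max_iop,
        disc_area=disc_area,
        ovality=ovality,
        torsion_deg=torsion,
        rnfl=rnfl,
        latent={"hrw": hrw, "mrw": mrw, "lcci": lcci},
        crao_subtype=subtype,
        vf_glaucomatous=group == "NTG",
    )


# ---------------------------------------------------------------------------
# Section rendering
# ---------------------------------------------------------------------------

def _half_ilm(h: float, m: float, w: float, z_floor: float) -> np.ndarray:
    """ILM polyline of one rim side in the canonical frame (BMO at origin).

    The curve runs, with strictly increasing x, from a peripheral tail above
    the BMO plane, crosses the plane exactly at lateral distance ``h`` from
    the BMO point, spirals in to graze the circle of radius ``m`` about the
    BMO point (the minimum-rim-width contact), widens again and descends to
    the cup-floor corner. All radii stay >= m so the measured minimum
    distance is m, and the only plane crossing sits at along-line distance h.
    """
    beta0 = np.deg2rad(20.0)
    betas = np.linspace(beta0, 0.0, 25)
    r_ab = h * (1.0 + 0.8 * betas / beta0)
    above = np.column_stack([-r_ab * np.cos(betas), -r_ab * np.sin(betas)])
    tail = np.array([[above[0, 0] - 0.35 * w - 50.0, above[0, 1]]])

    a1, a2, a3 = np.deg2rad([45.0, 65.0, 75.0])
    al = np.linspace(0.0, a1, 48)[1:]
    r_bel = h + (m - h) * al / a1
    below = np.column_stack([-r_bel * np.cos(al), r_bel * np.sin(al)])

    step = min(10.0 / max(m, 20.0), 0.03)
    arc_al = np.append(np.arange(a1 + step, a2, step), a2)
    arc = np.column_stack([-m * np.cos(arc_al), m * np.sin(arc_al)])

    wid_al = np.linspace(a2, a3, 10)[1:]
    r_wid = m * (1.0 + 0.25 * (wid_al - a2) / (a3 - a2))
    widen = np.column_stack([-r_wid * np.cos(wid_al), r_wid * np.sin(wid_al)])

    corner = np.array([[0.08 * w, z_floor]])
    return np.vstack([tail, above, below, arc, widen, corner])


def _rotate_shift(pts: np.ndarray, theta_deg: float, shift: np.ndarray) -> np.ndarray:
    th = np.deg2rad(theta_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return pts @ rot.T + shift


def build_section(
    *,
    section_id: str,
    location: str,
    scan_offset: int,
    w: float,
    hrw_temporal: float,
    mrw_temporal: float,
    hrw_nasal: float,
    mrw_nasal: float,
    lcci: float,
    tilt_deg: float = 0.0,
    shift: tuple[float, float] = (0.0, 0.0),
    quality_score: float = 28.0,
    flags: set[str] | None = None,
) -> BScanSection:
    """Render one section whose measured indices equal the prescribed values.

    The section is built in a canonical frame (BMO reference line horizontal,
    temporal BMO point at the origin) and then rigidly rotated by
    ``tilt_deg`` and translated by ``shift`` — rigid motions leave every
    index unchanged. Raises :class:`SyntheticError` for geometrically
    unrealisable prescriptions (e.g. MRW > HRW).
    """
    for name, h, m in (
        ("temporal", hrw_temporal, mrw_temporal),
        ("nasal", hrw_nasal, mrw_nasal),
    ):
        if not (0 < m <= h):
            raise SyntheticError(
                f"unrealisable {name} rim: MRW {m:.1f} must be in (0, HRW {h:.1f}]"
            )
    if w <= 0 or lcci < 0:
        raise SyntheticError("w must be positive and lcci non-negative")

    z_floor = 1.3 * max(mrw_temporal, mrw_nasal)
    temporal = _half_ilm(hrw_temporal, mrw_temporal, w, z_floor)
    nasal_half = _half_ilm(hrw_nasal, mrw_nasal, w, z_floor)
    nasal = np.column_stack([w - nasal_half[:, 0], nasal_half[:, 1]])[::-1]
    ilm = np.vstack([temporal, nasal])

    z0 = z_floor + 60.0
    lccd = lcci * w / 100.0
    xi = np.linspace(-0.08, 1.08, 141)
    alcs = np.column_stack([xi * w, z0 + 4.0 * lccd * xi * (1.0 - xi)])

    bm = np.array([[-0.4 * w, 0.0], [0.0, 0.0], [w, 0.0], [1.4 * w, 0.0]])
    bmo = np.array([[0.0, 0.0], [w, 0.0]])

    off = np.asarray(shift, dtype=float)
    for theta in (tilt_deg, 0.0):  # fall back to no tilt if monotonicity breaks
        curves = {
            name: _rotate_shift(pts, theta, off)
            for name, pts in (("ilm", ilm), ("bm", bm), ("alcs", alcs))
        }
        if all(np.all(np.diff(c[:, 0]) > 0) for c in curves.values()):
            break
    bmo_rot = _rotate_shift(bmo, theta, off)

    return BScanSection(
        section_id=section_id,
        location=location,
        scan_offset=scan_offset,
        ilm=Curve2D(curves["ilm"], role="ILM"),
        bm=Curve2D(curves["bm"], role="BM"),
        alcs=Curve2D(curves["alcs"], role="ALCS"),
        bmo_temporal=Point2D(float(bmo_rot[0, 0]), float(bmo_rot[0, 1])),
        bmo_nasal=Point2D(float(bmo_rot[1, 0]), float(bmo_rot[1, 1])),
        quality_score=quality_score,
        flags=set(flags or ()),
    )


def render_sections(
    eye: EyeRecord,
    seed: int | tuple,
    jitter_sd: float = 0.02,
    vessel_shadow_rate: float = 0.0,
    tilt_sd_deg: float = 0.4,
) -> list[BScanSection]:
    """Render the eye's nine target scans (plus vessel-shadow replacements).

    The BMO width of each scan follows the elliptical disc geometry (disc
    area + ovality, long axis vertical): the horizontal chord length at the
    scan's vertical position. Per-scan multiplicative jitter (SD
    ``jitter_sd``) models within-eye scan variability; it is mean-preserving
    so per-eye aggregates remain centred on the latent values. With
    probability ``vessel_shadow_rate`` a target scan is flagged as obscured
    by an overlying vessel and an adjacent (±1 offset) replacement scan is
    rendered in its place.
    """
    rng = _rng(seed)
    area_um2 = eye.disc_area * 1e6
    d_h = float(np.sqrt(4.0 * area_um2 / (np.pi * eye.ovality)))
    d_v = eye.ovality * d_h

    def jitter() -> float:
        return max(1.0 + rng.normal(0.0, jitter_sd), 0.5) if jitter_sd > 0 else 1.0

    def one_scan(location: str, offset: int, flags: set[str]) -> BScanSection:
        frac = LOCATION_FRACTIONS[location]
        v = (frac - 0.5) * d_v + offset * SCAN_SPACING_UM
        chord = max(1.0 - (2.0 * v / d_v) ** 2, 0.09)
        w = d_h * np.sqrt(chord)
        h_t = max(eye.latent["hrw"] * jitter(), 5.0)
        h_n = max(eye.latent["hrw"] * jitter(), 5.0)
        m_t = min(max(eye.latent["mrw"] * jitter(), 5.0), 0.98 * h_t)
        m_n = min(max(eye.latent["mrw"] * jitter(), 5.0), 0.98 * h_n)
        lcci_s = max(eye.latent["lcci"] * jitter(), 0.01)
        tilt = float(np.clip(rng.normal(0.0, tilt_sd_deg), -1.2, 1.2)) if tilt_sd_deg else 0.0
        shift = tuple(rng.uniform(-200.0, 200.0, 2))
        return build_section(
            section_id=f"{eye.eye_id}:{location}:{offset:+d}",
            location=location,
            scan_offset=offset,
            w=w,
            hrw_temporal=h_t,
            mrw_temporal=m_t,
            hrw_nasal=h_n,
            mrw_nasal=m_n,
            lcci=lcci_s,
            tilt_deg=tilt,
            shift=shift,
            quality_score=float(rng.uniform(20.0, 35.0)),
            flags=flags,
        )

    sections: list[BScanSection] = []
    for location in LOCATIONS:
        for offset in (-2, 0, 2):
            shadowed = rng.random() < vessel_shadow_rate
            sections.append(one_scan(location, offset, {"vessel_shadow"} if shadowed else set()))
            if shadowed:
                sections.append(one_scan(location, REPLACEMENT_OFFSET[offset], set()))
    return sections


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _exact_sex_split(n: int, male_fraction: float, rng: np.random.Generator) -> list[str]:
    males = int(round(male_fraction * n))
    sexes = ["M"] * males + ["F"] * (n - males)
    rng.shuffle(sexes)
    return sexes


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> Cohort:
    """Generate the full synthetic study cohort.

    NTG eyes and CRAO eyes are independent subjects; each healthy eye is
    the fellow eye of one CRAO subject and shares that subject's age and
    sex. Per-eye child seeds are derived from ``(seed, group index, eye
    index)``, so cohorts are reproducible and order-independent.
    """
    config = config or CohortConfig()
    config.validate()
    params = load_group_params(config.params_path)
    for name in config.groups:
        if name not in params:
            raise ConfigError(f"groups[{name!r}]: no parameters for this group")

    eyes: dict[str, EyeRecord] = {}
    rows: list[dict[str, Any]] = []

    def add_eye(record: EyeRecord, eye_seed: tuple) -> None:
        if config.render:
            record.sections = render_sections(
                record,
                seed=eye_seed + (7,),
                jitter_sd=config.jitter_sd,
                vessel_shadow_rate=config.vessel_shadow_rate,
                tilt_sd_deg=config.tilt_sd_deg,
            )
        eyes[record.eye_id] = record
        rows.append(record.to_row())

    n_ntg = config.groups.get("NTG", 0)
    if n_ntg:
        sexes = _exact_sex_split(n_ntg, params["NTG"].male_fraction, _rng((seed, 0, 999999)))
        for i in range(n_ntg):
            rec = sample_eye(params["NTG"], seed=(seed, 0, i))
            rec.sex = sexes[i]
            rec.eye_id = f"NTG-{i:03d}"
            rec.subject_id = f"S-NTG-{i:03d}"
            add_eye(rec, (seed, 0, i))

    n_crao = config.groups.get("CRAO", 0)
    n_healthy = config.groups.get("healthy", 0)
    if n_crao:
        sexes = _exact_sex_split(n_crao, params["CRAO"].male_fraction, _rng((seed, 1, 999999)))
        for i in range(n_crao):
            crao = sample_eye(params["CRAO"], seed=(seed, 1, i))
            crao.sex = sexes[i]
            crao.eye_id = f"CRAO-{i:03d}"
            crao.subject_id = f"S-CRAO-{i:03d}"
            add_eye(crao, (seed, 1, i))
            if i < n_healthy:
                fellow = sample_eye(
                    params["healthy"],
                    seed=(seed, 2, i),
                    shared={"age": crao.age, "sex": crao.sex, "subject_id": crao.subject_id},
                )
                fellow.eye_id = f"healthy-{i:03d}"
                add_eye(fellow, (seed, 2, i))

    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values("eye_id", kind="stable").reset_index(drop=True)
    return Cohort(table=table, eyes=eyes)


def generate_screening_pool(
    seed: int = 0, params_path: str | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic pre-screening candidate pools (NTG and CRAO).

    Exclusion attributes are assigned to fixed row ranges (first k rows per
    reason) at the study's screening frequencies, so the exclusion counts
    are exact rather than expected values. The eligible NTG rows include,
    for each eligible CRAO eye, one candidate whose matching covariates sit
    within a fraction of the default calipers, so a 1:1 matched set of the
    full eligible CRAO size exists.
    """
    params = load_group_params(params_path)
    freqs = load_screening_frequencies(params_path)

    def base_rows(group: str, n: int, seed_tag: int) -> list[EyeRecord]:
        return [
            sample_eye(params[group], seed=(seed, seed_tag, i)) for i in range(n)
        ]

    # CRAO pool: reasons occupy fixed leading row blocks.
    f_c = freqs["CRAO"]
    n_c = f_c["n"]
    crao_recs = base_rows("CRAO", n_c, 10)
    blocks = [
        ("incomplete", f_c["incomplete_crao"]),
        ("nvg", f_c["neovascular_glaucoma"]),
        ("tilt", f_c["tilted_or_torted_disc"]),
        ("poor", f_c["poor_oct_quality"]),
    ]
    idx = 0
    for kind, count in blocks:
        for j in range(count):
            rec = crao_recs[idx]
            if kind == "incomplete":
                rec.crao_subtype = "incomplete"
            elif kind == "nvg":
                rec.neovascular_glaucoma = True
            elif kind == "tilt":
                if j % 2 == 0:
                    rec.ovality = 1.38
                else:
                    rec.torsion_deg = 20.0
            elif kind == "poor":
                rec.quality_fail_sections = 6
            idx += 1
    for i, rec in enumerate(crao_recs):
        rec.eye_id = f"CRAO-P{i:03d}"
        rec.subject_id = f"S-CRAO-P{i:03d}"
    crao_eligible = crao_recs[idx:]

    # NTG pool: tilted/torted then poor-quality blocks, remainder eligible.
    f_n = freqs["NTG"]
    n_n = f_n["n"]
    ntg_recs = base_rows("NTG", n_n, 11)
    n_tilt, n_poor = f_n["tilted_or_torted_disc"], f_n["poor_oct_quality"]
    for j in range(n_tilt):
        if j % 2 == 0:
            ntg_recs[j].ovality = 1.38
        else:
            ntg_recs[j].torsion_deg = 20.0
    for j in range(n_tilt, n_tilt + n_poor):
        ntg_recs[j].quality_fail_sections = 6
    for i, rec in enumerate(ntg_recs):
        rec.eye_id = f"NTG-P{i:03d}"
        rec.subject_id = f"S-NTG-P{i:03d}"

    # Engineer matchable partners among the eligible NTG rows.
    rng = _rng((seed, 12))
    eligible_ntg = ntg_recs[n_tilt + n_poor:]
    for partner, rec in zip(crao_eligible, eligible_ntg):
        rec.age = partner.age + rng.uniform(-1.5, 1.5)
        rec.iop_at_oct = partner.iop_at_oct + rng.uniform(-0.8, 0.8)
        rec.disc_area = partner.disc_area + rng.uniform(-0.08, 0.08)
        rec.rnfl["global"] = partner.rnfl["global"] + rng.uniform(-3.0, 3.0)

    ntg_df = pd.DataFrame([r.to_row() for r in ntg_recs])
    crao_df = pd.DataFrame([r.to_row() for r in crao_recs])
    return ntg_df, crao_df


def simulate_observers(
    measurements: pd.DataFrame,
    noise_sd_pct: float,
    seed: int = 0,
    columns: tuple[str, ...] = ("mean_hrw", "mean_mrw", "mean_lcci"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two independent noisy re-measurements of per-eye indices.

    Each observer's value is the true measurement scaled by
    ``1 + N(0, noise_sd_pct)`` independently per eye and variable; zero
    noise reproduces the input exactly for both observers.
    """
    if noise_sd_pct < 0:
        raise ValueError("noise_sd_pct must be >= 0")
    rng = _rng((seed, 20))
    out = []
    for _ in range(2):
        obs = measurements.copy()
        if noise_sd_pct > 0:
            for col in columns:
                obs[col] = obs[col] * (
                    1.0 + rng.normal(0.0, noise_sd_pct, size=len(obs))
                )
        out.append(obs)
    return out[0], out[1]
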