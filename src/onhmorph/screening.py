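"""Eligibility screening and 1:1 case matching.

Reproduces the study's filtering flow from candidate pools to the analysis
set: deterministic rule-based exclusions (CRAO completeness, neovascular
glaucoma, tilted/torted disc, OCT quality, refraction, surgery/disease
history, IOP) followed by greedy nearest-neighbour 1:1 matching of NTG to
CRAO eyes on age, IOP at OCT, disc area and global RNFL thickness, with
per-variable calipers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EXCLUSION_ORDER",
    "MATCH_VARIABLES",
    "DEFAULT_CALIPERS",
    "ExclusionReport",
    "MatchResult",
    "apply_exclusions",
    "exclusion_table",
    "match_one_to_one",
]

#: fixed evaluation/reporting order of exclusion reasons
EXCLUSION_ORDER = (
    "incomplete_crao",
    "neovascular_glaucoma",
    "tilted_or_torted_disc",
    "poor_oct_quality",
    "refraction_out_of_range",
    "prior_surgery",
    "retinal_or_neuro_disease",
    "high_iop",
    "branch_rao",
    "glaucoma_history",
)

MATCH_VARIABLES = ("age", "iop_at_oct", "disc_area", "rnfl_global")

#: matching tolerances: 5 y age, 3 mmHg IOP, 0.3 mm^2 disc area, 10 µm RNFL
DEFAULT_CALIPERS = {"age": 5.0, "iop_at_oct": 3.0, "disc_area": 0.3, "rnfl_global": 10.0}

#: ovality above this defines a tilted disc; torsion above 15 deg a torted one
OVALITY_LIMIT = 1.3
TORSION_LIMIT_DEG = 15.0
QUALITY_FAIL_LIMIT = 5  # excluded when MORE than this many sections fail
SE_RANGE_D = (-8.0, 3.0)
CYL_RANGE_D = (-3.0, 3.0)
MAX_IOP_LIMIT = 21.0


@dataclass
class ExclusionReport:
    eye_id: str
    excluded: bool
    reasons: list[str]

    def __post_init__(self) -> None:
        assert self.excluded == bool(self.reasons)


@dataclass
class MatchResult:
    pairs: list[tuple[str, str]]  # (ntg_eye_id, crao_eye_id)
    caliper_used: dict[str, float]
    unmatched: list[str] = field(default_factory=list)


_REQUIRED = (
    "eye_id",
    "group",
    "crao_subtype",
    "neovascular_glaucoma",
    "ovality",
    "torsion_deg",
    "quality_fail_sections",
    "spherical_equivalent",
    "prior_surgery",
    "retinal_or_neuro_disease",
    "max_iop",
    "branch_rao",
    "glaucoma_history",
)


def apply_exclusions(pool: pd.DataFrame) -> list[ExclusionReport]:
    """Evaluate every exclusion rule on every pool row.

    Rules are deterministic and order-independent; an eye is excluded when
    any rule fires, and its reasons are listed in :data:`EXCLUSION_ORDER`.
    Boundary values do not exclude (all thresholds are strict). Missing
    attributes raise ``KeyError``/``ValueError`` naming the eye and field.
    """
    for col in _REQUIRED:
        if col not in pool.columns:
            raise KeyError(f"pool is missing required column {col!r}")
    has_cyl = "cylinder" in pool.columns

    reports: list[ExclusionReport] = []
    for _, row in pool.iterrows():
        eye = row["eye_id"]
        for col in _REQUIRED:
            v = row[col]
            if col == "crao_subtype":
                continue  # empty outside the CRAO arm (CSV reads "" as NaN)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise ValueError(f"eye {eye}: missing attribute {col!r}")
        subtype = row["crao_subtype"]
        if row["group"] == "CRAO" and not isinstance(subtype, str):
            raise ValueError(f"eye {eye}: missing attribute 'crao_subtype'")
        reasons = []
        if row["group"] == "CRAO" and subtype == "incomplete":
            reasons.append("incomplete_crao")
        if row["neovascular_glaucoma"]:
            reasons.append("neovascular_glaucoma")
        if row["ovality"] > OVALITY_LIMIT or row["torsion_deg"] > TORSION_LIMIT_DEG:
            reasons.append("tilted_or_torted_disc")
        if row["quality_fail_sections"] > QUALITY_FAIL_LIMIT:
            reasons.append("poor_oct_quality")
        se_bad = not (SE_RANGE_D[0] <= row["spherical_equivalent"] <= SE_RANGE_D[1])
        cyl_bad = has_cyl and not (CYL_RANGE_D[0] <= row["cylinder"] <= CYL_RANGE_D[1])
        if se_bad or cyl_bad:
            reasons.append("refraction_out_of_range")
        if row["prior_surgery"]:
            reasons.append("prior_surgery")
        if row["retinal_or_neuro_disease"]:
            reasons.append("retinal_or_neuro_disease")
        if row["max_iop"] > MAX_IOP_LIMIT:
            reasons.append("high_iop")
        if row["branch_rao"]:
            reasons.append("branch_rao")
        if row["glaucoma_history"]:
            reasons.append("glaucoma_history")
        reports.append(ExclusionReport(eye, bool(reasons), reasons))
    return reports


def exclusion_table(reports: list[ExclusionReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "eye_id": [r.eye_id for r in reports],
            "excluded": [r.excluded for r in reports],
            "reasons": [";".join(r.reasons) for r in reports],
        }
    )


def match_one_to_one(
    ntg: pd.DataFrame,
    crao: pd.DataFrame,
    variables: tuple[str, ...] = MATCH_VARIABLES,
    calipers: dict[str, float] | None = None,
) -> MatchResult:
    """Greedy nearest-neighbour 1:1 matching within per-variable calipers.

    Candidate pairs are ranked by Euclidean distance on z-standardised
    matching variables (standardised over the pooled tables); pairs are
    accepted greedily, each eye at most once, only when every raw
    per-variable difference is within its caliper. Ties break on the
    smaller (ntg_eye_id, crao_eye_id). Deterministic for fixed inputs.
    """
    calipers = dict(DEFAULT_CALIPERS if calipers is None else calipers)
    if ntg.empty or crao.empty:
        return MatchResult(pairs=[], caliper_used=calipers,
                           unmatched=list(ntg.get("eye_id", [])) + list(crao.get("eye_id", [])))
    for df, name in ((ntg, "ntg"), (crao, "crao")):
        for v in variables:
            if v not in df.columns:
                raise KeyError(f"{name} table is missing matching variable {v!r}")

    pooled = pd.concat([ntg[list(variables)], crao[list(variables)]], ignore_index=True)
    mu = pooled.mean()
    sd = pooled.std(ddof=0).replace(0.0, 1.0)
    zn = ((ntg[list(variables)] - mu) / sd).to_numpy()
    zc = ((crao[list(variables)] - mu) / sd).to_numpy()

    ntg_ids = ntg["eye_id"].to_numpy()
    crao_ids = crao["eye_id"].to_numpy()
    raw_n = ntg[list(variables)].to_numpy()
    raw_c = crao[list(variables)].to_numpy()
    cal = np.array([calipers[v] for v in variables])

    candidates = []
    for i in range(len(ntg_ids)):
        diffs = np.abs(raw_n[i] - raw_c)
        ok = np.all(diffs <= cal, axis=1)
        dists = np.linalg.norm(zn[i] - zc, axis=1)
        for j in np.nonzero(ok)[0]:
            candidates.append((dists[j], str(ntg_ids[i]), str(crao_ids[j]), i, j))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))

    used_n: set[int] = set()
    used_c: set[int] = set()
    pairs: list[tuple[str, str]] = []
    for _, nid, cid, i, j in candidates:
        if i in used_n or j in used_c:
            continue
        used_n.add(i)
        used_c.add(j)
        pairs.append((nid, cid))
    unmatched = [str(ntg_ids[i]) for i in range(len(ntg_ids)) if i not in used_n]
    unmatched += [str(crao_ids[j]) for j in range(len(crao_ids)) if j not in used_c]
    return MatchResult(pairs=pairs, caliper_used=calipers, unmatched=unmatched)
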