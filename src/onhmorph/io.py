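"""File round-tripping: section geometry JSON and cohort/morphometry CSV.

Section geometry schema (coordinates in µm, written at 2-decimal precision)::

    {"section_id": ..., "location": ..., "scan_offset": ...,
     "quality_score": ...,
     "curves": {"ilm": [[x, z], ...], "bm": [...], "alcs": [...]},
     "bmo": {"temporal": [x, z], "nasal": [x, z]},
     "flags": [...]}

All writes are atomic (temp file + rename) so interrupted runs never leave
partial artifacts behind.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Any

import pandas as pd

from .geometry import BScanSection, Curve2D, Point2D

__all__ = [
    "SchemaError",
    "atomic_write_text",
    "section_to_dict",
    "section_from_dict",
    "write_sections_json",
    "read_sections_json",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_morphometry_csv",
    "read_morphometry_csv",
]

COHORT_REQUIRED = (
    "eye_id",
    "group",
    "age",
    "iop_at_oct",
    "disc_area",
    "rnfl_global",
)
MORPHOMETRY_REQUIRED = (
    "eye_id",
    "group",
    "mean_hrw",
    "mean_mrw",
    "mean_hmr",
    "mean_lcci",
    "temporal_hrw",
    "temporal_mrw",
    "temporal_hmr",
    "n_usable_scans",
    "flags",
)


class SchemaError(ValueError):
    """A file does not conform to its declared schema."""


def atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _round2(pairs) -> list[list[float]]:
    return [[round(float(x), 2), round(float(z), 2)] for x, z in pairs]


def section_to_dict(section: BScanSection) -> dict[str, Any]:
    return {
        "section_id": section.section_id,
        "location": section.location,
        "scan_offset": int(section.scan_offset),
        "quality_score": round(float(section.quality_score), 2),
        "curves": {
            "ilm": _round2(section.ilm.points),
            "bm": _round2(section.bm.points),
            "alcs": _round2(section.alcs.points),
        },
        "bmo": {
            "temporal": _round2([section.bmo_temporal.as_array()])[0],
            "nasal": _round2([section.bmo_nasal.as_array()])[0],
        },
        "flags": sorted(section.flags),
    }


def section_from_dict(d: dict[str, Any]) -> BScanSection:
    try:
        return BScanSection(
            section_id=d["section_id"],
            location=d["location"],
            scan_offset=int(d["scan_offset"]),
            ilm=Curve2D(d["curves"]["ilm"], role="ILM"),
            bm=Curve2D(d["curves"]["bm"], role="BM"),
            alcs=Curve2D(d["curves"]["alcs"], role="ALCS"),
            bmo_temporal=Point2D(*d["bmo"]["temporal"]),
            bmo_nasal=Point2D(*d["bmo"]["nasal"]),
            quality_score=float(d["quality_score"]),
            flags=set(d.get("flags", [])),
        )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed section record: {exc!r}") from exc


def write_sections_json(path: str | Path, sections: list[BScanSection]) -> None:
    payload = {"sections": [section_to_dict(s) for s in sections]}
    atomic_write_text(path, json.dumps(payload, indent=1, sort_keys=True))


def read_sections_json(path: str | Path) -> list[BScanSection]:
    with open(path) as fh:
        payload = json.load(fh)
    if "sections" not in payload:
        raise SchemaError(f"{path}: missing top-level 'sections' key")
    return [section_from_dict(d) for d in payload["sections"]]


def _write_csv(path: str | Path, df: pd.DataFrame) -> None:
    atomic_write_text(path, df.to_csv(index=False, float_format="%.6g"))


def _read_csv(path: str | Path, required: tuple[str, ...], kind: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: {kind} CSV is missing required columns {missing}")
    return df


def write_cohort_csv(path: str | Path, table: pd.DataFrame) -> None:
    _write_csv(path, table)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, COHORT_REQUIRED, "cohort")


def write_morphometry_csv(path: str | Path, table: pd.DataFrame) -> None:
    _write_csv(path, table)


def read_morphometry_csv(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, MORPHOMETRY_REQUIRED, "morphometry")
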