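"""End-to-end pipeline: simulate → measure → screen → stats → report.

Each stage is a plain function over in-memory objects; :func:`run_pipeline`
chains them, writes every artifact (CSV/JSON/TXT) under the configured
output directory and finishes with a manifest recording inputs, seed and
output hashes, so a fixed (config, seed) reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import LOCATIONS, BScanSection
from .morphometry import MorphometryResult, aggregate_eye, section_indices
from .screening import (
    DEFAULT_CALIPERS,
    apply_exclusions,
    exclusion_table,
    match_one_to_one,
)
from .stats import build_tables, format_table_text, icc_two_observers, regress_hrw_on_lcci
from .synthetic import (
    Cohort,
    CohortConfig,
    ConfigError,
    EyeRecord,
    generate_cohort,
    generate_screening_pool,
    simulate_observers,
)
from . import io as onhio

__all__ = [
    "PipelineConfig",
    "measure_eye",
    "measure_cohort",
    "run_pipeline",
]

log = logging.getLogger("onhmorph")


@dataclass
class PipelineConfig:
    """Everything one pipeline run depends on."""

    seed: int = 0
    out_dir: str = "results/run"
    sections_dir: str | None = None  # default: <out_dir>/sections
    cohort: CohortConfig = field(default_factory=CohortConfig)
    pool_mode: bool = False  # also run the screening fixture flow
    alpha: float = 0.05
    posthoc: str | None = None  # None = gate decides; "tukey" | "dunn"
    calipers: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CALIPERS))
    write_sections: bool = True

    def validate(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed must be an integer")
        if not (0 < self.alpha < 1):
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.posthoc not in (None, "tukey", "dunn"):
            raise ConfigError(f"posthoc must be 'tukey' or 'dunn', got {self.posthoc!r}")
        self.cohort.validate()


def usable_sections(record: EyeRecord) -> dict[str, list[BScanSection]]:
    """Group a record's sections by location, dropping vessel-shadowed scans."""
    by_loc: dict[str, list[BScanSection]] = {loc: [] for loc in LOCATIONS}
    for s in record.sections:
        if "vessel_shadow" in s.flags or not s.is_usable:
            continue
        by_loc[s.location].append(s)
    return by_loc


def measure_eye(record: EyeRecord) -> MorphometryResult:
    """Run the full morphometry on one eye's usable sections."""
    by_loc = {
        loc: [section_indices(s) for s in secs]
        for loc, secs in usable_sections(record).items()
    }
    return measure_from_indices(by_loc, record.eye_id)


def measure_from_indices(by_loc, eye_id: str) -> MorphometryResult:
    return aggregate_eye(by_loc, eye_id=eye_id)


def measure_cohort(cohort: Cohort) -> pd.DataFrame:
    """Per-eye morphometry table for a rendered cohort."""
    rows = []
    group_of = dict(zip(cohort.table["eye_id"], cohort.table["group"]))
    for eye_id, record in sorted(cohort.eyes.items()):
        res = measure_eye(record)
        rows.append(
            {
                "eye_id": eye_id,
                "group": group_of[eye_id],
                "mean_hrw": res.mean_hrw,
                "mean_mrw": res.mean_mrw,
                "mean_hmr": res.mean_hmr,
                "mean_lcci": res.mean_lcci,
                "temporal_hrw": res.temporal_hrw,
                "temporal_mrw": res.temporal_mrw,
                "temporal_hmr": res.temporal_hmr,
                "n_usable_scans": res.n_usable_scans,
                "flags": ";".join(sorted(res.flags)),
            }
        )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Execute all stages; returns the manifest (artifact name → sha256)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sections_dir = Path(config.sections_dir or out / "sections")

    log.info("stage simulate: generating cohort (seed=%d)", config.seed)
    cohort = generate_cohort(config.cohort, seed=config.seed)
    onhio.write_cohort_csv(out / "cohort.csv", cohort.table)
    if config.write_sections and config.cohort.render:
        for eye_id, record in sorted(cohort.eyes.items()):
            onhio.write_sections_json(sections_dir / f"{eye_id}.json", record.sections)

    log.info("stage measure: %d eyes", len(cohort.eyes))
    morpho = measure_cohort(cohort)
    onhio.write_morphometry_csv(out / "morphometry.csv", morpho)

    if config.pool_mode:
        log.info("stage screen: fixture pools")
        ntg_pool, crao_pool = generate_screening_pool(seed=config.seed)
        reports = apply_exclusions(pd.concat([ntg_pool, crao_pool], ignore_index=True))
        onhio.atomic_write_text(
            out / "exclusions.csv", exclusion_table(reports).to_csv(index=False)
        )
        excluded = {r.eye_id for r in reports if r.excluded}
        ntg_ok = ntg_pool[~ntg_pool["eye_id"].isin(excluded)]
        crao_ok = crao_pool[~crao_pool["eye_id"].isin(excluded)]
        match = match_one_to_one(ntg_ok, crao_ok, calipers=config.calipers)
        onhio.atomic_write_text(
            out / "matches.csv",
            pd.DataFrame(match.pairs, columns=["ntg_eye_id", "crao_eye_id"]).to_csv(
                index=False
            ),
        )

    log.info("stage stats")
    merged = cohort.table.merge(morpho.drop(columns=["group"]), on="eye_id")
    frames = build_tables(merged, alpha=config.alpha, posthoc=config.posthoc)
    for name, df in frames.items():
        onhio.atomic_write_text(out / f"table_{name}.csv", df.to_csv(index=False))
    onhio.atomic_write_text(out / "tables.txt", format_table_text(frames))

    obs1, obs2 = simulate_observers(
        morpho, config.cohort.observer_noise_sd, seed=config.seed
    )
    icc_rows = []
    for col in ("mean_hrw", "mean_mrw", "mean_lcci"):
        r = icc_two_observers(obs1[col].to_numpy(), obs2[col].to_numpy(), variable=col)
        icc_rows.append(
            {"variable": col, "icc": r.icc, "ci_low": r.ci_low, "ci_high": r.ci_high}
        )
    onhio.atomic_write_text(
        out / "icc.csv", pd.DataFrame(icc_rows).to_csv(index=False)
    )

    reg = regress_hrw_on_lcci(merged)
    onhio.atomic_write_text(out / "regression.json", json.dumps(reg, indent=1))

    log.info("stage report: manifest")
    manifest: dict[str, str] = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest[str(p.relative_to(out))] = _sha256(p)
    payload = {
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "artifacts": manifest,
    }
    onhio.atomic_write_text(out / "manifest.json", json.dumps(payload, indent=1, sort_keys=True))
    return manifest
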