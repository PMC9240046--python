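#!/usr/bin/env python
"""Three-group comparisons of clinical covariates and ONH indices.

Reads the cohort and per-eye morphometry written by 01_simulate_cohort.py
and runs the normality-gated omnibus tests (ANOVA + Tukey or
Kruskal–Wallis + Dunn) per variable, emitting mean ± SD tables with
omnibus and pairwise P-values and the post-hoc ordering pattern.

Writes results/table_{clinical,onh,temporal}.csv and results/tables.txt.
"""

from pathlib import Path

from onhmorph import io as onhio
from onhmorph.stats import build_tables, format_table_text

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort = onhio.read_cohort_csv(ROOT / "results" / "cohort.csv")
    morpho = onhio.read_morphometry_csv(ROOT / "results" / "morphometry.csv")
    merged = cohort.merge(morpho.drop(columns=["group"]), on="eye_id")

    frames = build_tables(merged)
    for name, df in frames.items():
        onhio.atomic_write_text(
            ROOT / "results" / f"table_{name}.csv", df.to_csv(index=False)
        )
    text = format_table_text(frames)
    onhio.atomic_write_text(ROOT / "results" / "tables.txt", text)
    print(text)


if __name__ == "__main__":
    main()
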