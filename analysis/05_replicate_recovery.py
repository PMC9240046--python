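#!/usr/bin/env python
"""Parameter recovery and headline significance over replicate cohorts.

Generates 200 independent synthetic cohorts (31 eyes per group), pushes
each through the full render → measure → aggregate pipeline, and
summarises how well the pipeline-measured group means recover the
configured values, plus how often the three-group MRW comparison reaches
P < 0.001 and which post-hoc ordering it produces.

Writes results/replicate_recovery.csv. Takes a few minutes.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from onhmorph.io import atomic_write_text
from onhmorph.replication import replicate_study
from onhmorph.synthetic import load_group_params

SEED = 1
N_REPLICATES = 200
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    reps = replicate_study(n_replicates=N_REPLICATES, seed=SEED)
    params = load_group_params()

    rows = []
    for group in ("NTG", "CRAO", "healthy"):
        for index in ("hrw", "mrw", "lcci"):
            mean, sd = params[group].indices[index]
            se = sd / np.sqrt(31)
            vals = reps[f"{group}_{index}"].to_numpy()
            rows.append(
                {
                    "group": group,
                    "index": index,
                    "configured_mean": mean,
                    "replicate_median": float(np.median(vals)),
                    "replicate_sd": float(np.std(vals, ddof=1)),
                    "coverage_3se": float(np.mean(np.abs(vals - mean) <= 3 * se)),
                }
            )
    summary = pd.DataFrame(rows)
    atomic_write_text(
        ROOT / "results" / "replicate_recovery.csv", summary.to_csv(index=False)
    )
    print(summary.round(3).to_string(index=False))

    rate = float((reps["mrw_omnibus_p"] < 0.001).mean())
    modal = reps["mrw_pattern"].mode().iloc[0]
    modal_freq = float((reps["mrw_pattern"] == modal).mean())
    print(f"\nMRW omnibus P < 0.001 in {rate:.1%} of {N_REPLICATES} replicates")
    print(f"modal post-hoc pattern: '{modal}' ({modal_freq:.1%} of replicates)")


if __name__ == "__main__":
    main()
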