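# onhmorph — optic nerve head morphometry on OCT B-scan boundary curves

`onhmorph` quantifies the topographic morphology of the optic nerve head
(ONH) from segmented horizontal EDI-OCT B-scans, for the comparison of
normal-tension glaucoma (NTG) against late-stage central retinal artery
occlusion (CRAO) and healthy fellow eyes. Both diseases end with a thin
retinal nerve fiber layer, but the shape of the remaining neuroretinal rim
and of the lamina cribrosa separates them. The package is aimed at
researchers who have per-section boundary curves (ILM, Bruch's membrane
with its opening points, anterior lamina surface) plus clinical records and
want reproducible index measurement, cohort screening and group statistics
— and at anyone who wants to stress-test that pipeline on fully synthetic
eyes.

## Indices

With the Bruch's membrane opening (BMO) termination points defining the
BMO reference line of a section:

* **HRW** — horizontal rim width: distance along the BMO reference line
  from a BMO point to the nearest ILM crossing of that line on the same
  rim side (µm);
* **MRW** — minimum rim width: min Euclidean distance from a BMO point to
  the ILM within the selected horizontal section (µm);
* **HMR** — HRW/MRW, computed per measurement and then averaged;
* **LCCI** — lamina cribrosa curvature index: `100 · LCCD / W`, where `W`
  is the BMO width and `LCCD` the maximum depth of the anterior lamina
  surface below the chord between the feet of the perpendiculars dropped
  from the BMO points. Dividing by `W` makes LCCI independent of ONH size.

Indices are measured on three scans (two scan intervals apart) at each of
three locations across the vertical disc diameter — superior mid-periphery,
centre, inferior mid-periphery — averaged per location and then per eye.

## Layout

```
src/onhmorph/     geometry.py     exact polyline queries (distances, crossings)
                  morphometry.py  HRW/MRW/HMR/LCCI + per-eye aggregation
                  synthetic.py    cohort generator & section renderer
                  screening.py    exclusion rules + 1:1 caliper matching
                  stats.py        gated omnibus tests, ICC(2,1), regression
                  pipeline.py     simulate -> measure -> screen -> stats -> report
                  cli.py          `onhmorph` command (simulate/measure/screen/stats/run)
analysis/         numbered drivers reproducing each stage, tables in results/
scripts/          acceptance.py (see "Reproducing the headline numbers")
docs/methods.md   models, assumptions, numerical choices
```

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/03_group_comparisons.py
```

generates the 93-eye synthetic cohort (31 per group), measures every eye
from its rendered section geometry and prints, among others:

```
== onh ==
Mean HRW, um    162.11 ± 53.80   356.14 ± 154.55   347.90 ± 77.05   P < 0.001  NTG < healthy = CRAO
Mean MRW, um     85.86 ± 36.83   119.03 ± 41.12    213.12 ± 37.15   P < 0.001  NTG < CRAO < healthy
Mean LCCI        10.99 ± 2.33      7.14 ± 2.27       6.97 ± 1.26    P < 0.001  healthy = CRAO < NTG
```

Columns are NTG, CRAO, healthy (mean ± SD), the normality-gated omnibus
P-value and the post-hoc ordering. The qualitative structure is the point:
glaucomatous eyes have a narrow rim *and* a posteriorly bowed lamina
(large LCCI), CRAO eyes lose MRW but keep HRW and lamina shape close to
their healthy fellow eyes. `analysis/02_screening_flow.py` reproduces the
screening flow (121 NTG and 90 CRAO assessed, 76 and 59 excluded, a 31/31
matched set); `04` computes interobserver ICCs and the HRW-on-LCCI
regression (negative slope, P < 0.001); `05` runs 200 replicate cohorts
and summarises parameter recovery.

## Data formats

Section geometry is JSON (µm, 2-decimal), cohorts and per-eye morphometry
are CSV; schemas are documented in `src/onhmorph/io.py` and validated on
read. The generative group parameters ship as
`src/onhmorph/data/group_parameters.yaml`.
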