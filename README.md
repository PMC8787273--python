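# spindlemorph

Quantification of intrafusal "bag" myotube formation in Neuregulin-1
(Nrg-1) treated C2C12 cultures: objective morphological classification of
myotubes from fluorescence micrographs, background-calibrated marker
(Egr3) intensity measurement, relative gene/protein expression, and the
accompanying statistical decision procedure — all exercisable end to end
on synthetic data, so every stage is testable without microscope access.

**Who it is for.** Muscle and neuromuscular tissue-engineering groups who
classify myotube phenotypes from phalloidin/DAPI micrographs and want the
whole measurement chain — segmentation, diameter profiling,
classification, intensity calibration, ΔΔCt, densitometry, statistics —
as reproducible, tested code instead of spreadsheet + Fiji sessions.

## The classification statistic

Nuclear-bag intrafusal fibres are fusiform: a bulging equatorial region
with clustered nuclei. The **diameter difference ratio** turns that into a
number. For a myotube with width profile *w(s)* measured along its medial
axis,

    DDR = max w(s) / min w(s),    DDR ≥ 1.

Training on linear and bag exemplars gives per-class mean ± sample SD
(linear 1.81 ± 0.37, bag 4.03 ± 1.32), and one standard deviation sets the
decision boundaries:

    linear  : DDR ≤ mean_lin + SD_lin  = 2.18
    bag     : DDR ≥ mean_bag − SD_bag  = 2.71
    unassigned : 2.18 < DDR < 2.71

A myotube is a single actin fibre containing ≥ 3 nuclei. Widths are
2 × (Euclidean distance transform) at each medial-axis point, with fibre
tips and points interfered with by a neighbouring myotube excluded.

Around the classifier the package implements: fusion efficiency (nuclei
inside myotubes ÷ all nuclei), myotube area per myonucleus, the 99%-rule
background calibration from a primary-negative image, coverage and
intensity-per-nucleus, Egr3-positive nucleus calls, ΔCt/2^−ΔΔCt relative
expression with primer QC (efficiency 90–115%, r² > 0.95, single melt
peak), proportional Myh isoform composition, western-blot adjusted
relative density, viability fold change, and the statistics: Shapiro-Wilk
gated t-test / Mann-Whitney, square-root-transformed two-way ANOVA with
Tukey HSD, and negative-binomial regression for nuclei counts.

## Worked example

```python
import numpy as np
from spindlemorph import (generate_field, CONTROL, NRG1,
                          analyze_field, derive_thresholds)

thr = derive_thresholds([1.44, 1.81, 2.18], [2.71, 4.03, 5.35])
print(f"linear cutoff: {thr.linear_cutoff:.2f}, bag cutoff: {thr.bag_cutoff:.2f}")

for params in (CONTROL, NRG1):
    bag, fus = [], []
    for seed in range(10):
        field = generate_field(params, seed=seed)           # one 1024² FOV
        _, summary, _ = analyze_field(field.micrograph, thr,
                                      denominator="assigned")
        bag.append(summary.bag_pct)
        fus.append(summary.fusion_efficiency_pct)
    print(f"{params.name:8s} bag {np.mean(bag):5.1f} +- {np.std(bag)/np.sqrt(10):4.1f} %   "
          f"fusion {np.mean(fus):5.1f} %")
```

prints

```
linear cutoff: 2.18, bag cutoff: 2.71
control  bag  11.3 +-  4.1 %   fusion  47.1 %
nrg1     bag  35.0 +-  5.0 %   fusion  49.6 %
```

The cutoffs are the training boundaries above. Each line is the mean
(± SEM) over ten simulated fields per arm: the control arm measures ~9–11%
bag myotubes and the treated arm ~35–42% (both consistent with the
generator's configured 8.5% and 41.6% mixing fractions at this sample
size), while fusion efficiency stays near 47% in both arms — the bag
phenotype shift is independent of overall fusion.

The same run is available from a shell:

```bash
spindlemorph simulate --condition nrg1 --n-fields 3 --seed 0 --out fields/
spindlemorph morpho --images fields/ --pixel-size 0.65 --out morpho/
spindlemorph run --seed 0 --out full_run/     # all stages + report.json
```

## Layout

- `src/spindlemorph/synthetic.py` — field/assay generators and the two
  study-arm parameter sets (`CONTROL`, `NRG1`)
- `src/spindlemorph/morphometry.py` — segmentation, nuclei, width
  profiles, DDR, thresholds, classification, field summaries
- `src/spindlemorph/intensity.py` — background calibration and marker
  intensity quantification
- `src/spindlemorph/expression.py` — primer QC, ΔΔCt, Myh proportions,
  blot densitometry, viability folds
- `src/spindlemorph/stats.py` — gated tests, two-way ANOVA + Tukey,
  negative-binomial counts model
- `src/spindlemorph/pipeline.py`, `cli.py` — orchestration and the
  `spindlemorph` command
- `docs/methods.md` — models, assumptions, parameter choices, limitations
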