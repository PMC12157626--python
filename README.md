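# strainquant

Quantification pipelines for **LIM-domain reporter recruitment to
mechanically strained actin** in live fluorescence microscopy.

Tandem LIM domains from proteins such as Zyxin, Testin and Prickle bind
F-actin selectively in its tension-induced ("strained") conformational
state.  In live imaging of *Xenopus* dorsal-mesoderm explants this shows up
as bright reporter segments along actin filaments; relaxing cytoskeletal
tension with the myosin II inhibitor Blebbistatin dissolves them within
minutes.  `strainquant` implements the two bespoke quantification
procedures used in that kind of experiment, plus a synthetic two-channel
scene generator so every stage can be exercised — and its failure modes
studied — without microscope data.

## What it computes

**1. Enrichment of a GFP construct at strain sites** (`strainquant.enrichment`).
A reference mask is built from the RFP channel of a Zyxin-LCR reporter
(the field's standard label for strained-actin sites) by the exact recipe:

    Subtract Background (radius 3 px, sliding paraboloid)
    → Gaussian blur (σ = 1 px)
    → Triangle auto-threshold (256-bin histogram)
    → Erode (1 iteration, 8-neighbourhood)
    → discard particles < 30 px

Mean intensities are then read from the **original** channels — RFP_i and
GFP_i inside the mask, GFP_o outside — and combined into the enrichment
score

$$\mathrm{score} = \frac{\mathrm{GFP}_i - \mathrm{GFP}_o}{\mathrm{RFP}_i}$$

which is invariant to uniform GFP offsets, linear in GFP gain, and 0 for a
spatially uniform construct.  Scores are normalized per trial to the mean
of the wild-type reference group (so the reference mean is exactly 1), and
construct groups are compared by one-way ANOVA.

**2. Loss of construct-positive structures after myosin inhibition**
(`strainquant.counting`).  Each frame of a time-lapse is processed by

    Subtract Background (radius 3 px, sliding paraboloid)
    → Rényi-entropy auto-threshold → discard particles < 10 px

and the surviving connected components are counted, giving a per-frame
object-count curve summarized as mean ± SD per condition.

All image operators (paraboloid/ball background subtraction, Gaussian
blur, Triangle and Rényi-entropy thresholds, binary erosion, run-based
connected-component labeling with area filtering) are implemented in
`strainquant.imageops` and validated against independent brute-force
oracles and scipy/scikit-image equivalents in the test suite.

The pipeline stages are scikit-learn-style estimators (`EnrichmentScorer`,
`ScoreNormalizer`, `ObjectCounter`) with `get_params`/`set_params`, so they
compose with sklearn tooling; plain functions (`build_reference_mask`,
`measure_enrichment`, `count_stack`, …) wrap them.

## Worked example

Score a synthetic cohort — wild-type construct (fully localized to strain
sites, `enrichment_rho=1.0`) against a localization-dead mutant
(`enrichment_rho=0.0`) — over two trials:

```python
import strainquant as sq
from strainquant.synthetic import SceneSpec

records, seed = [], 0
for trial in ("day1", "day2"):
    for rho, group in [(1.0, "WT")] * 3 + [(0.0, "FY>A")] * 3:
        seed += 1
        gfp, rfp, _ = sq.make_scene(
            SceneSpec(width=256, height=256, seed=seed, enrichment_rho=rho))
        records.append((gfp, rfp, trial, group, f"{group}_{trial}_{seed}"))

result = sq.run_enrichment_experiment(records, reference_group="WT")
print(result.scores[["trial", "group", "mask_area", "score", "normalized"]])
```

prints (abbreviated):

```
trial group     image_id  mask_area   score  normalized
 day1    WT    WT_day1_1       3632  9.5456      0.9950
 day1    WT    WT_day1_2       4231 10.0451      1.0470
 day1    WT    WT_day1_3       4261  9.1907      0.9580
 day1  FY>A  FY>A_day1_4       3292  0.0013      0.0001
 ...
one-way ANOVA: F(1,10) = 6137.34, p = 2.81e-15
group means: {'WT': 1.0, 'FY>A': -0.0}
```

Raw scores near 9.5 reflect strong GFP concentration in the ~4000-px
reference mask; after per-trial normalization the WT mean is exactly 1 and
the localization-dead group sits at 0, with the difference overwhelmingly
significant.

Counting objects in simulated myosin-inhibition time-lapses (16 frames,
one per minute; structure signal decays with τ = 3 min after drug
addition, ∞ for the vehicle control):

```python
import math
from strainquant.synthetic import TimeLapseSpec

base = SceneSpec(width=256, height=256, seed=5, conserve_total=False, enrichment_rho=1.0)
for tau in (3.0, math.inf):
    stack, _ = sq.make_timelapse(TimeLapseSpec(base=base, decay_tau=tau))
    print(tau, sq.count_stack(stack).counts.tolist())
```

```
blebbistatin (tau=3 min): [8, 8, 8, 8, 8, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0]
DMSO control:             [8, 8, 8, 8, 8, 8, 8, 8, 8, 8, 8, 8, 8, 8, 8, 8]
```

The eight filament-associated structures vanish from the count once their
intensity decays through the detection threshold — near-complete loss over
the 15-minute course — while the control stays flat.

The same workflows are available from the shell:

```bash
strainquant simulate timelapse --tau 3 --seed 5 --out tl/
strainquant count --in tl/timelapse.tif --interval-min 1 --out counts.csv
strainquant enrich --manifest manifest.csv --reference-group WT --out results/
```

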