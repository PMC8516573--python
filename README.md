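# sonoenhance

Local-statistics adaptive contrast enhancement for B-mode ultrasound,
exercised end to end on synthetic speckle phantoms, together with a
summary-statistics toolkit that recomputes the two-arm clinical comparisons
of an ultrasound-guided versus landmark-guided regional nerve block study.

## Who this is for

Researchers who want a tested, reproducible reference implementation of
Wallis-type adaptive contrast enhancement (windowed mean/variance gain with
a cap) and Gaussian unsharp masking for ultrasound-like imagery — plus a
principled way to evaluate such filters when no real scans are available:
seeded phantoms with a bright bone-surface band, acoustic shadow, Rayleigh
speckle, and an optional fracture gap with exact ground truth.

## The model

With `x(i,j)` the image and a `(2n+1) × (2n+1)` window centred on each
pixel, the local mean `m(i,j)` and population variance `σ²(i,j)` define the
enhancement

```
f(i,j) = m(i,j) + G(i,j) · (x(i,j) − m(i,j))
```

where the gain is either a constant `C ≥ 1` or adaptive,
`G = D / max(σ, √ε)`, inversely proportional to the local standard
deviation, and always capped at `G_max` so flat regions cannot blow up
noise. The same gain law applies in a frequency split: `low` = Gaussian
blur, `high = x − low`, `f = low + G · high` (unsharp masking). Enhancement
runs as an ordered plan of such stages; the default plan is an adaptive
contrast pass followed by an adaptive boundary pass on a fine detail band.

The clinical module recomputes, from printed group summaries (mean ± SD,
n = 20 per arm), pooled/Welch two-sample t-tests (pooled `F = t²` is the
two-group one-way ANOVA), 2×2 chi-square with Yates and Fisher-exact
fallback, and a tie-corrected Wilcoxon rank-sum for ordered anesthesia
grades (with an exact two-category option).

## Worked example

```
$ python analysis/03_accuracy_curve.py --seed 0
   stage  accuracy  mean_cnr
baseline       1.0    11.245
contrast       1.0    28.578
boundary       1.0    31.770

Mean CNR across stages is strictly increasing; accuracy 1.00 -> 1.00.
```

On 40 degraded phantoms (blur σ=2 plus additive noise, 20 with a fracture
gap and 20 without) the bone-band contrast-to-noise ratio rises from 11.2
to 28.6 after the adaptive contrast pass and to 31.8 after the boundary
pass, while a fixed columnwise gap detector stays at ceiling accuracy.

```
$ python analysis/04_clinical_stats.py
                  entry  ...             method  statistic   df      p  ...  concordant
operation_time_abstract  ...           t_pooled    -3.6162 38.0 0.0009  ...        True
         puncture_depth  ...           t_pooled    -6.7584 38.0 0.0000  ...        True
     needle_adjustments  ...           t_pooled    -2.6999 38.0 0.0103  ...        True
        pain_complaints  ...              chisq     7.0588  1.0 0.0079  ...        True

6/6 stated claims concordant at 0.05.
```

Every published significance claim is reproduced at the 0.05 level from the
printed summaries alone; the recomputed needle-adjustment p of 0.0103
brackets the published P = 0.009.

The numbered scripts under `analysis/` run the full story in order:
phantom suite and degradation (01), stagewise enhancement on one phantom
(02), the accuracy/CNR curve (03), the clinical comparisons (04), and the
pooled-t type-I calibration (05). The library they drive lives under
`src/sonoenhance/`; `sonoenhance.pipeline.run_pipeline` chains the stages
from a single YAML config and writes a hash manifest for reproducibility.

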