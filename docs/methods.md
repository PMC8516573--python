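# Methods

## Enhancement model

Every filter operates on 2-D float64 intensity grids in [0, 1] (8-bit
images map by /255, 16-bit by /65535). For a window half-width `n`, the
local mean and variance are the plain window average and *population*
variance (divide by `(2n+1)²`, no Bessel correction). All convolutions —
the box window and every Gaussian — use reflective borders (the edge pixel
repeated), which makes constant images exact fixed points and keeps the
small worked examples in the tests exact. Gaussian kernels are sampled at
integer offsets, truncated at 4σ, and renormalized to sum 1; the truncation
radius is fixed so results are bit-reproducible.

The enhancement law `f = m + G·(x − m)` is evaluated as
`x + (G − 1)·(x − m)`, which makes unit gain an exact floating-point
identity rather than an identity up to round-off. The adaptive gain
`G = D/σ` is floored through `σ ← max(σ, √ε)` with `ε = 1e−6` and capped at
`G_max = 5` by default: the inverse-σ law is undefined on flat regions, and
the cap bounds how much a nearly-flat region can be amplified. Variances
are clamped at zero against negative round-off. Each stage clips its output
to [0, 1]; the `clip=False` escape hatch exposes pre-clip values for
analysis.

## Default two-stage plan

Stage 1 ("contrast") is the adaptive window-statistics gain with a 9×9
window and target contrast `D = 0.004`. Because `D` sits below the local
standard deviation of degraded speckle (≈ 0.02–0.03), the gain is below 1
over smooth tissue: local contrast is driven toward a uniform low target,
which is exactly what the inverse-σ law does when asked to equalize
contrast — speckle and electronic noise are suppressed while strong
structure (the bone band, carried by the local mean) passes through.

Stage 2 ("boundary") applies the same adaptive gain law to the fine Gaussian
detail band (σ = 1.5, gain window 5×5, `D = 0.002`): residual fine-grain
noise left by stage 1 is pushed further down while edge contours, which
live mostly in the low band at this scale, are untouched. A constant-gain
unsharp pass was considered for this slot and rejected after a pilot grid
on the degraded phantom suite: any constant `C > 1` amplifies the residual
noise at least as much as the band contrast and therefore *lowers* the
bone-band CNR (the band, being a spatially extended structure, can never be
boosted more than white-ish noise by a purely spectral gain). The adaptive
form raises mean CNR from ≈ 28.6 to ≈ 31.8 on the suite and was robust
across suite seeds. Constant-gain unsharp remains available through
`StagePlan` for users who want the classic sharpening look rather than a
CNR-optimal chain.

All stage parameters were fixed once by that pilot grid and are recorded in
`sonoenhance.enhance.default_plan`.

## Phantom generator

The phantom emulates the first-order statistics and geometry that matter to
the enhancement task, not ultrasound physics. Background speckle is i.i.d.
Rayleigh with scale 0.1 (the classical first-order amplitude model for
fully developed speckle; mean ≈ 0.125), clipped to [0, 1] — at this scale
the clipped mass is e⁻⁵⁰, i.e. nil. The bone surface is a 4-pixel additive
band of brightness 0.6 at mid-depth (a thin, strongly hyperechoic line);
everything below it is multiplied by 0.35 (acoustic shadow); a fracture is
a 10-column interruption of the band with an exact ground-truth mask.
Degradation is a Gaussian blur (σ = 2) followed by additive Gaussian noise
(sd 0.03), matching a low-quality acquisition in which the gap is smeared
but still present. Geometry defaults: 192×192 pixels, band at row 96, gap
centre varied across the middle third of the image in suites. Randomness
uses NumPy's PCG64 generator throughout, so a `(spec, seed)` pair is
bit-reproducible across platforms.

What the phantom does *not* model: anisotropic point-spread, log
compression, attenuation with depth, reverberation, refraction, or
correlated speckle. Consequently, passing tests show that the enhancement
chain behaves as designed on Rayleigh-speckle imagery with the stated
geometry; they do not certify performance on clinical scans.

A property worth knowing when reading CNR numbers on speckle: blur *alone*
raises CNR, because smoothing shrinks the background standard deviation
(the denominator) faster than it smears the band contrast. The degraded
condition is only a genuinely harder starting point because of the additive
noise term, and the monotone CNR-decrease property of degradation is tested
in the noise-dominated regime (noise sd 0.06).

## Evaluation

CNR is `|mean(fg) − mean(bg)| / sd(bg)` with the band (gap columns
excluded) as foreground and the speckle field above the band as background;
the background sd is floored at 1e−12. The fracture detector averages each
column over the band rows and flags columns strictly below a fraction
(default 0.5) of the median column mean; an image is called "fracture" when
any column is flagged. A quantile-valued threshold was rejected for this
slot: an empirical quantile always leaves ≈ q·N columns below it, so the
non-empty-set decision rule would call every noisy image a fracture. The
median-fraction form keeps the noiseless cases exact (a zero threshold
flags nothing; a noiseless gap is recovered exactly) while making the call
discriminative. The accuracy curve holds the detector fixed across baseline
and stages so that accuracy changes isolate the enhancement's contribution.
Under the default degradation the detector is already at ceiling (the gap
drop is many column-noise standard deviations), so the curve's information
is carried by the CNR trend; stronger degradations move the accuracy arm
off ceiling at the cost of realism.

## Clinical statistics

All tests are two-sided. The pooled t uses `df = n_a + n_b − 2` and reports
`F = t²` on (1, df); Welch uses Satterthwaite df. The 2×2 chi-square is the
closed form `N(ad − bc)²/((a+b)(c+d)(a+c)(b+d))` with optional Yates
correction; when any expected cell is below 5 (the pain table has expected
cells of 3) the result flags and also reports Fisher's exact p. The grade
comparison is a Wilcoxon rank-sum on the category-expanded samples with
midranks and tie-corrected normal variance; for two categories an exact
permutation p is available by hypergeometric enumeration, used as the
cross-check in the tests. Degenerate inputs have conventions rather than
crashes: two identical constant groups give p = 1; a zero event-column
marginal gives χ² = 0, p = 1 with a warning; a single shared grade category
gives p = 1.

The registry of printed comparisons uses n = 20 per arm: although 100
patients were recruited, the published grade counts (11+9 and 13+7) and
complication rates (6/20 = 30 %) imply 20 per group, and no integer n
reproduces the published P = 0.009 / P = 0.002 exactly (n = 20 gives
0.0103 and 0.0009). Concordance is therefore judged at the 0.05 level
rather than by exact p matching, and `n_override` exposes the assumption.
The two slightly different operation-time summaries printed in the source
are both kept as separate registry entries; neither is "corrected".

Type-I calibration simulates 10,000 null two-group normal datasets (n = 20)
and checks the pooled-t rejection rate at α = 0.05 against the binomial
99 % band [0.041, 0.059].

## Problem sizes

The shipped suites use 40 phantoms of 192×192 pixels and 10,000 calibration
replicates; the full test suite and the acceptance script each run in a few
seconds on one CPU. These sizes give stable means (suite-to-suite CNR
variation ≲ 1 %) while staying cheap to re-run.

## Known limitations

* The phantom's realism gaps (above) bound what CNR/accuracy results say
  about clinical imagery.
* The exact rank-sum enumeration covers two ordered categories only; more
  categories fall back to the asymptotic form.
* The detector is deliberately simple (columnwise, single threshold); it is
  an instrument for comparing images, not a clinical fracture detector.
* Patient-level data are never reconstructed; all clinical inference is
  from printed summaries, inheriting their rounding.
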