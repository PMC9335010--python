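# Methods

This note documents the models, conventions and numerical choices behind
spinemetrics: what each quantity means, how the synthetic generator
realizes it, which defaults were chosen where the design was open, and what
the passing tests do and do not demonstrate about real data.

## Coordinate frame and sign conventions

All coordinates are in cm in a right-handed frame: x left(+)/right(−),
y anterior(+)/posterior(−), z cranial(+)/caudal(−). Sagittal plane (y, z),
coronal (x, z), transverse (x, y). The per-subject origin is arbitrary —
every parameter is translation invariant, including SVA, which is a
difference between two of the subject's own landmarks. Under uniform
scaling all angles are unchanged and SVA scales linearly (tested).

Angle conventions are fixed by anatomy and by the exact sagittal identity
PI = PT + SS:

* **Sagittal endplate tilt** — angle of the posterior→anterior endplate
  line vs the horizontal, positive when the posterior margin is cranial.
  This is the anatomical configuration of the S1 endplate (it slopes
  caudally toward the promontory; spondylolisthesis slides down that ramp),
  and it is the convention under which PI = PT + SS holds with PT positive
  when the sacral center is posterior to the hip axis (hips
  anterior-inferior to S1 in normal posture).
* **Lordosis positive / kyphosis positive** for the regional angles; a
  Table-style population then shows LL ≈ +40°, TK ≈ +39°.
* **Coronal tilts** are measured on the directed right→left endplate line,
  so Cobb angles beyond 90° (severe scoliosis, up to ~106° in large
  populations) are represented without folding back.

## Parameter definitions

* **SS** — tilt of the S1 superior endplate line (sacral anterior/posterior
  margin landmarks).
* **PT** — angle between the vertical and the hip-axis→sacral-center line;
  the hip axis is the midpoint of the femoral-head centers.
* **PI** — angle between the caudal perpendicular to the sacral endplate at
  its midpoint and the sacral-center→hip-axis line, computed geometrically;
  it equals PT + SS to machine precision (asserted at 1e−6° on 1,000 random
  pelves).
* **Regional angles** — the endplate orientation is the line through the
  two relevant margin landmarks (anterior/posterior sagittally, left/right
  coronally), not a 5-point plane fit. The two estimators agree within 1°
  for planar endplates at anatomical out-of-plane tilts (plane fit kept as
  a test oracle); the margin-line choice is simpler and exact for the
  synthetic data. LL = L1-superior to L5-inferior; TK = T1- or T4-superior
  to T12-inferior.
* **Cobb** — exhaustive search over all 17×16/2 ordered level pairs of the
  unsigned coronal angle between the upper superior and lower inferior
  endplate lines; ties break toward the most cranial, then shortest curve.
  The apex is the vertebra between the ends with maximal perpendicular
  coronal distance from the end-vertebra center line. A single maximal
  curve is reported; no multi-curve decomposition.
* **SVA** — anterior offset of the T1 body center (mean of its endplate
  centers) from the posterior margin of the S1 endplate. T1 is the default
  cranial reference because the reconstruction is thoracolumbar (no C7);
  the reference level is configurable.
* **TPA** — angle at the hip axis between the lines to the T1 body center
  and to the sacral endplate midpoint; equals PT plus the anterior
  inclination of the hip→T1 line (tested identity).
* **Axial rotation** — per vertebra, the left–right axis is the mean of the
  (left−right) vectors of its two endplates; rotation is the unsigned angle
  between its transverse projection and the global x-axis (a fixed-frame
  convention; no patient-specific re-referencing). Axes tilted more than
  85° out of the transverse plane are excluded from the maximum with a
  warning.
* **Roussouly lordosis** — a natural cubic spline through the sagittal
  projections of the sacral endplate midpoint and the 17 body centers
  (chord-length parametrization). Walking cranially from S1, the inflection
  is the most caudal persistent sign change of the tangent-rotation rate
  from lordotic to kyphotic; sign changes are read at vertebra resolution
  (tangent differences between consecutive body centers, 0.2° deadband)
  rather than from the dense second derivative, which is sensitive to
  spline flutter between data points. The angle is taken between the sacral
  endplate line and the endplate-parallel direction (perpendicular to the
  spline tangent) at the inflection — i.e. the tangent sweep of the
  lordotic arc, the quantity Roussouly's construction measures. If the
  curvature never changes sign the inflection is T1 and the angle spans the
  whole curve.

## Synthetic population model

The generator stands in for a large radiographic database; its defaults are
calibrated so that the *recomputed-from-landmarks* population statistics of
a large cohort approximate a mixed clinical population: mean PI 49°, SS
37°, LL 40°, TK 39°, SVA 0.3 cm, median Cobb 10° at 50.9% scoliosis
prevalence, mean maximal rotation ≈ 7°.

Sampling chain (defaults in `synthetic.py`; all configurable):

| quantity | model | default |
|---|---|---|
| age group | categorical | weights 0.521/0.127/0.167/0.161/0.024 (10–18 … 80+), age uniform within group |
| sex | Bernoulli | P(F) = 0.6 (deformity clinics skew female) |
| PI | truncated normal | mean 49°, sd 11°, bounds [3°, 89°] |
| SS | 0.55·PI + 10.05 + ε | ε sd 5.5°, bounds [2°, 75°]; PT = PI − SS exactly |
| LL | 17.20 + 0.55·PI − 0.12·age + sex ± ε | ε sd 8°, bounds [−15°, 74°]; sex effect +0.6 (F) / −0.9 (M), weighted to zero mean |
| TK | 19.54 + 0.40·LL + 0.10·age + sex ± ε | ε sd 7°, bounds [−17°, 79°] |
| SVA | −1.775 + 0.06·age + ε | ε sd 2.5 cm, bounds [−9.7, 27.6] cm |
| Cobb | mixture | prevalence 0.509: 10° + LogNormal(μ=1.933, σ=1.2) (mean excess ≈ 14°, mild curves most common — this places the population median just above the 10° threshold); else Uniform(1°, 10°); cap 106° |
| apex | categorical | T5…L2, peaked at T8/T9 (thoracic curves most common) |
| rotation | 1.0 + 0.4·Cobb + ε | ε sd 2°, clipped to [0°, 47°] |

The coupling signs reproduce the qualitative correlation structure of real
cohorts: PI–SS, PI–LL and Cobb–rotation strongly positive, age–LL negative,
age–TK and age–SVA positive (tested). The exact slopes are calibration
choices, not estimates of any real joint distribution — only the marginals
and the sign structure are constrained.

Truncated normals are drawn by rejection (bounds excluding mean ± 6 sd are
a configuration error). A single `numpy` Generator seeded from the config
drives the whole cohort; identical config + seed gives byte-identical
output files.

## Geometric realization (closed form)

1. **Pelvis** — sacral endplate line of depth 5 cm tilted by SS at the
   origin; hip axis 7 cm from the sacral center along the direction that
   realizes PT; femoral heads ±8.75 cm laterally. PI follows exactly.
2. **Sagittal centerline** — two tangent-continuous circular arcs joined at
   the T12–L1 disc midpoint. Vertebrae (level-wise body heights 1.6→2.6 cm,
   discs 0.5 cm thoracic / 1.0 cm lumbar) are placed at arc-length
   stations; each endplate is orthogonal to the local tangent. The arc
   curvatures are solved linearly so the L1-superior–L5-inferior and
   T4-superior–T12-inferior endplate angles equal the drawn LL and TK
   exactly (no vertebral wedging; deformity is rigid vertebra placement).
3. **Base tilt / balance** — the tangent tilt at the L5 inferior endplate
   is solved by bisection (closed-form objective) so the T1 body center
   lands at the drawn SVA; the prescribed global sagittal translation then
   only absorbs round-off. This keeps the spine anatomically coherent over
   the pelvis instead of translating a fixed-shape curve by several cm —
   and keeps the sacrum-to-L5 spline segment kink-free for the Roussouly
   computation. If no balanced tilt exists within the ±85° tangent
   envelope, the closest endpoint is used and the translation absorbs the
   rest.
4. **Coronal curve** — a 7-level span centred on the apex (truncated at
   T1/L5). Per-vertebra coronal tilts ramp monotonically from −Cobb/2 at
   the upper end to +Cobb/2 at the lower end (cosine/sine shaping, 0 at the
   apex), so the all-pairs search returns exactly the drawn Cobb at exactly
   the drawn end pair; lateral body-center offsets follow a half-sine bump
   (0.05 cm per degree of Cobb at the apex), making the apex the most
   deviated vertebra.
5. **Axial rotation** — the same bump shape scaled to peak at the drawn
   maximal rotation at the apex.
6. **Exactness trick** — each endplate's left–right axis L is solved so its
   transverse projection makes exactly the target rotation angle with x and
   its coronal projection exactly the target coronal tilt; the anterior
   axis A is solved orthogonal to L with exactly the target sagittal tilt.
   All three measured tilts are therefore exact simultaneously, and
   noiseless round-trips recover every truth parameter to ~1e−13.
7. **Noise** — optional i.i.d. Gaussian perturbation of every landmark
   coordinate, applied last. The default is 0: the shipped configuration
   produces exact geometric realizations, and noise is an explicit
   robustness parameter. (The all-pairs Cobb maximum is upward-biased under
   landmark noise, so a noisy default would conflate the population
   calibration with the noise process.)

### Noise propagation

A line through two landmarks a distance d apart, each with isotropic
coordinate noise σ, has tilt error sd ≈ √2·σ/d. At σ = 0.1 cm this predicts
≈1.6° (SS, 5 cm plate), ≈1.0° (PT, 7 cm lever), ≈1.9° (PI) and ≈3.5°
(LL, ~3 cm endplate depths); the regression tests assert the empirical
error sds match these closed forms and that errors stay inside their 3σ
envelopes. Consequences: the panel-average absolute angle error at σ = 0.1
is just under 2°, but individual regional angles cannot beat their span
limit — a fundamental property of the two-point estimator, not an
implementation artifact.

## Cohort rules

Age strata use integer-year inclusive bounds as printed (18 → 10–18,
19 → 19–44, …). Deformity thresholds are strict: scoliosis ⇔ Cobb > 10°,
deformity ⇔ Cobb > 10° or SVA > 5 cm; boundary subjects (exactly 10°/5 cm)
are non-deformed. The SVA criterion uses the signed value (anterior
imbalance), not |SVA|. Exclusion flags (implants, prior surgery,
neuromuscular/congenital deformity) are caller-supplied metadata — they
describe image-level findings with no landmark-level counterpart — plus an
age < 10 rule applied automatically.

## Statistics

* **Descriptives** — min/max/mean/median per parameter (median = mid-mean
  of central order statistics for even n).
* **Stratified fits** — per-stratum OLS (scipy `linregress`), with an
  optional pre-filter (e.g. deformity-free subset); constant-x strata
  return flagged results rather than raising.
* **Spearman matrix** — average-rank rank correlation; symmetric, unit
  diagonal, invariant under strictly monotone transforms; constant
  variables yield NaN entries.
* **ANCOVA** — explicit nested linear models: full = intercept + covariates
  + treatment-coded factor dummies vs reduced = intercept + covariates;
  F = [(SSE_r − SSE_f)/Δdf]/[SSE_f/df_f], p from the F distribution. This
  is a Type-III-style factor test given the covariates; the factor/response
  /covariate pairings are configuration, not hard-coded. Rank-deficient
  designs raise with the aliased columns named. Under a Gaussian null the
  test is exact: the type-I error at α = 0.05 sits inside (0.03, 0.07) over
  1,000 simulations (asserted). No multiple-testing correction is applied;
  p-values are reported raw.
* **Predictor importance** — per target (LL, TK, SVA, PI−LL, TPA, Cobb,
  rotation) an XGBoost regressor on the remaining predictors (age, sex, PI,
  SS, LL, TK, SVA, Cobb, rotation), fit separately for adolescents
  (age < 19) and adults. The target itself is withheld, and PI−LL
  additionally withholds PI and LL (it is their difference; leaving them in
  makes the row a tautology). Gain importances normalized to row sum 1;
  a permutation-importance backend (sklearn) offers the same contract.
  Fixed hyperparameters (200 trees, depth 3, learning rate 0.1, no
  subsampling, seed 0) keep runs deterministic; groups under 50 subjects
  are reported missing with a warning.

## Observer-agreement harness

Manual validation is emulated by four observers measuring truth + i.i.d.
Gaussian noise and a tool measuring truth + independent noise. Agreement
rates: fraction of cases with the tool inside the observers' range
(inclusive bounds) and fraction with |tool − observer mean| > 5 (strict;
the observer mean is the reference because no other reference is
canonical). For exchangeable noise the within-range rate converges to
(n−1)/(n+1) — 3/5 for four observers — which the harness reproduces to
±0.02 at 10,000 cases; at clinically reported noise levels (~3° for both
observers and tool) the rate falls in the 30–80% band seen in
human-vs-tool comparisons.

## Problem sizes and determinism

The shipped analyses use n = 2,000 subjects for the population round-trip
(population means are then determined to ≈0.2° by sampling error, an order
of magnitude inside the ±1.5° calibration tolerance), 200 subjects for
recovery tests, 1,000 replicates for the ANCOVA null, and 10,000 cases for
the order-statistics law. The pipeline derives per-stage child seeds from
one run seed via `SeedSequence.spawn`, so stages are individually
reproducible and full reruns are byte-identical.

## Known limitations

* The generator's joint distribution is calibrated, not estimated: only
  marginal means/medians/ranges and correlation signs are constrained.
  Passing round-trip tests demonstrates the measurement pipeline's
  correctness on idealized geometry, not detector performance on real
  radiographs.
* Single-curve scoliosis only; no double-major curves, no vertebral
  wedging, no soft tissue or growth modelling, no image synthesis.
* The thoracolumbar reconstruction has no C7, so SVA and TPA use T1 as the
  cranial reference; values are therefore not numerically identical to
  C7-based conventions.
* Axial rotation is measured against the global coronal plane; tools that
  re-reference to a patient-specific plane will differ for globally rotated
  acquisitions.
* Exclusion criteria based on visual image inspection cannot be derived
  from landmarks and must be supplied as metadata.
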