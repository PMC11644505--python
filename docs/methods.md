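# Methods

`tuberspec` implements a per-plant analysis chain linking handheld
spectroradiometer canopy reflectance (350–2500 nm) to potato tuber yield,
together with a synthetic field-trial generator that plants a known
spectra–yield coupling so every stage of the chain can be checked against
ground truth.

## Data model and preprocessing

A measurement campaign produces, per plant and measurement day, a canopy
reflectance curve (replicates averaged to one representative spectrum) and,
at harvest, a per-plant record: total tuber weight (g), tuber count, counts
by caliber (>75, 40–75, <40 mm — contextual only) and a rodent-damage flag.
Plants flagged for rodent damage are excluded outright: rodents destroy
tubers below ground with no reliable expression in canopy reflectance, so
they would only contaminate the response.

Spectra are resampled by linear interpolation from the instrument's dual
native sampling (1.4 nm below ~1000 nm, 2 nm above) onto a unified integer
1 nm grid, 350–2500 nm (2151 bands). Band masking then removes the two
atmospheric/leaf water-absorption windows 1350–1460 and 1790–2000 nm and the
noisy 2350–2500 nm tail, all intervals inclusive at both ends, leaving
exactly 1678 usable bands. Inclusive boundaries and the 1 nm grid are the
only convention consistent with that retained-band count. Band features are
named `x.<nm>` (e.g. `x.728` = reflectance at 728 nm).

## Vegetation-index bank

116 indices: 115 literature indices spanning the classic hyperspectral
families (simple ratios, normalized differences, Carter/Datt/Gitelson/
Vogelmann chlorophyll indices, carotenoid and anthocyanin reflectance
indices, red-edge position estimators, first-derivative indices, SWIR
water/soil indices) plus the crop-specific Potato Productivity Index (PPI).
Each registry entry carries its required wavelengths, a citation, and a
scale-invariance flag (true for pure ratios/normalized differences) used by
the property tests.

Numerical choices:

- Indices evaluate on the **pre-mask** resampled spectrum. Masking is a
  feature-selection step for individual bands, not destruction of the
  measurement; CAI, for example, needs 2000 nm, which the mask removes from
  the band features.
- Derivative indices (Boochs, D1/D2, DPI, Vogelmann3, Sum_Dr, EGFR/EGFN,
  red-edge positions) use a Savitzky–Golay first derivative (window 15 nm,
  order 2) on the 1 nm grid; an unsmoothed 1 nm finite difference would be
  noise-dominated at realistic instrument noise.
- `REP_LE` implements the linear-extrapolation red-edge position
  (intersection of derivative flank lines through 680/700 nm and
  725/760 nm); `mREIP` is the wavelength of the derivative maximum in
  680–750 nm.
- Where the literature offers variant formulas the registry documents the
  variant adopted. For the SWIR indices the linear Lobell–Asner soil/
  vegetation forms are used; PPI is implemented as a red-edge normalized
  difference on the 842/705 nm band centres (the Sentinel-2 B8/B5 pair),
  the package's adopted variant.
- Division by zero propagates NaN with a warning; batch evaluation is
  bit-identical to per-sample evaluation.

## Temporal aggregation search

Measurement days are aligned across years by rank of days-after-planting
(d1…dn); ordinals absent from any year (d7, measured only in the second
year) are excluded. Candidate aggregations are all contiguous ordinal
windows — m usable days give m(m+1)/2 windows, 21 for m = 6 — crossed with
three statistics applied elementwise across days: sum (cumulative signal),
mean (average), max (peak greenness). Single-day windows pass values
through verbatim.

Each of the 63 candidates is scored by bootstrap random-forest regression of
yield on all 1794 features: each resample fits a forest on a bootstrap draw
of plants and evaluates RMSE on the out-of-bag plants; the point score is
the mean resample RMSE with a 2.5/97.5 percentile interval. The forest
sidesteps the multicollinearity of 1 nm bands. Library defaults follow the
caret bootstrap convention (25 resamples, 500 trees, mtry = p/3); the
recovery experiment, the analysis drivers and the acceptance script use
desk-scale parameters (12 resamples, 15 trees, mtry = √p) so a 63-candidate
search over ~260 plants runs in well under a minute on one CPU — the
ranking of windows, which is all the search needs, is stable at this size.
Ties in point RMSE break toward the shorter window, then the earlier start,
then max > mean > sum.

By default feature screening runs once, on the winning aggregation;
`select_per_window=True` (CLI `--select-per-window`) re-runs the screening
inside every candidate before scoring, at proportionally higher cost.

## Feature screening

Two steps on the aggregated plant × 1794 table:

1. **Significance filter** — Pearson r of each feature with yield, two-sided
   p from the t-transform on n−2 df; keep p < 0.05, rank by |r| descending
   (name-ordered ties for determinism).
2. **Greedy decorrelation** — walk the ranking top-down, keeping a feature
   iff its pairwise |r| with every already-kept feature is ≤ 0.7. Because
   the walk is in descending |r|-with-yield order, the member of a redundant
   pair less correlated with yield is always the one dropped. The threshold
   applies to |r|: strong negative correlation is equally redundant.

A caveat found while testing: the kept set is *not* monotone in the
threshold — a feature re-admitted at a higher threshold can itself block
features kept at a lower one. The suite therefore checks maximality (every
removed feature exceeds the threshold against some kept feature) and
equivalence with an independently coded brute-force replay, not set
monotonicity.

## Yield model

Ordinary least squares of yield on the centred/scaled kept features.
Coefficients are reported in standardized units (g per feature SD) with
95 % CIs = estimate ± 1.96 SE (normal-theory, as printed), a significance
flag (CI excludes 0), and back-transformed original-scale values.
Out-of-sample performance uses leave-one-out cross-validation with the
standardization refit inside each fold (no leakage; the conservative choice
where the protocol is silent): RMSE (g), %RMSE = 100·RMSE/mean yield, and
R² = squared Pearson correlation of held-out predictions with observations
(the resampling-framework convention). Residuals are standardized by the
raw-residual SD (n−1 convention). Permutation importance is the mean
increase in RMSE over 50 shuffles of one feature column (loss difference,
not ratio), with 2.5/97.5 permutation percentiles; the comparison report
centres/scales both the |r| and the importance vectors onto one axis.

## Synthetic field generator

The generator is first-class, tested code defining the study conditions:

- **Design**: 2 years × 3 plots × 6 varieties × 10 plants = 360 plants;
  measurement days at DAP 46, 56, 86, 93, 100, 107 (year 1) and 55, 62, 81,
  91, 98, 109, 118 (year 2); harvest records with tuber counts by caliber;
  rodent damage flagged independently per plant with probability 0.27
  (flag only — no reflectance effect, matching its below-ground nature).
- **Yield**: mean 2400 g (consistent with an RMSE of ~700 g being ~29 % of
  the mean) plus Gaussian variety (SD 500 g), plot (SD 250 g) and plant
  (SD 550 g) effects, truncated at zero.
- **Reflectance template**: a smooth parametric curve — soil baseline mixed
  by fractional cover with a vegetation curve having a green peak (550 nm),
  a chlorophyll-deepened red absorption well (670 nm), a red-edge inflection
  shifting to longer wavelengths with chlorophyll, a NIR plateau and
  water-deepened SWIR dips (1450/1940 nm). Deliberately not a
  radiative-transfer model (no PROSAIL): it only needs to make the named
  index families respond in the physically right direction.
- **Planted coupling (two channels)**: each plant's chlorophyll seasonal
  amplitude A = 2.0·(1 + 0.25·z) + ε, ε ~ N(0, 0.45), and water amplitude
  W = 1 + 0.25·z + η, η ~ N(0, 0.3), where z is the yield in nominal-SD
  units. Chlorophyll follows a logistic rise/senescence trajectory peaking
  inside the coupling window (default d2–d5) with per-plant timing jitter
  (SD 4 days), so mid-season windows — and max/mean aggregation over them —
  carry the most signal, while early and late days are attenuated. Two
  channels (red-edge vs SWIR) make the top-correlated and top-important
  features genuinely distinct, as in a real multi-trait canopy.
- **Noise**: per-replicate Gaussian reflectance noise (SD 0.01, five
  replicates averaged) that is *spectrally correlated* (20 nm correlation
  length). Correlated noise is essential realism: field-spectrometer curves
  are smooth, which is what lets a redundancy filter collapse thousands of
  adjacent bands to a couple of dozen independent features. With iid
  per-band noise, chance-significant noise-dominated bands are mutually
  uncorrelated and inflate the kept set several-fold. An optional
  multiplicative brightness jitter (`brightness_jitter_sd`, default 0)
  can add the spectrally flat illumination/geometry variation that ratio
  indices are designed to cancel.
- **Known noise floor**: yield reaches the spectra only through (A, W), so
  the residual RMSE of an OLS of yield on the true amplitudes is the
  irreducible error of any spectra-based model (~450 g at the defaults,
  putting the expected LOOCV R² near 0.5–0.6). The recovery experiment requires
  the pipeline's LOOCV RMSE to land within [1.0, 1.3]× this floor.

What the generator does **not** emulate: radiative-transfer physics, soil
and weather variation, disease or nutrient stress expressed spectrally,
variety-specific spectral signatures (varieties differ only in yield), or
irregular within-year measurement scheduling. Passing tests therefore show
the chain recovers planted couplings under a clean two-channel world — not
that the specific indices selected here would top the ranking in real
fields.

## Recovery experiment and sign checks

Per seed, a fresh trial is generated, the full pipeline runs, and four
things are measured: (1) whether the selected window overlaps the planted
coupling window; (2) whether the coefficient signs of the top-2 kept
features match the planted direction, computed by perturbing the noise-free
template along the yield direction (both channels together). Only the top-2
are checked because kept features may share pairwise |r| up to 0.7, and the
partial OLS coefficient of a secondary correlated regressor need not carry
the marginal sign even under a correct model (classic suppressor effects);
(3) the LOOCV-RMSE–to–noise-floor ratio; (4) whether the top-2 features by
permutation importance coincide with the top-2 by |r|.

## Problem sizes and tolerances

Default analyses run 360 plants (~263 after rodent exclusion), 1794
features per day, 63 aggregation candidates at desk-scale forest
parameters, 50 permutation repetitions, and a 10-seed recovery experiment.
All randomness flows from a single integer seed (generator, bootstrap,
forests, permutations); identical seeds give byte-identical outputs. Exact
structural counts (2151 → 1678 bands, 115 + 1 indices, 21 windows, 1794
columns) are asserted exactly; stochastic recovery checks use the
majority-vote bounds stated above.

## Known limitations

- The VI registry reconstructs a published index list; a handful of
  formulas exist in several published variants and the adopted variant is
  recorded per entry rather than resolved bibliographically.
- The bootstrap RF scorer ranks aggregation candidates; its absolute RMSE
  at desk-scale forest parameters is a slightly pessimistic estimate of a
  full-size forest's.
- LOOCV R² via squared correlation can flatter a model with calibration
  bias; the residual tables written by the report are the place to check.
- The generator's truncation of yield at zero and amplitude clipping
  introduce mild nonlinearity at the extremes of the planted affine
  couplings.
- Agreement between the permutation-importance ranking and the marginal
  |r| ranking is *not* a stable property of this chain: features survive
  decorrelation with pairwise |r| up to 0.7, and permutation importance of
  an OLS model follows partial coefficients, which routinely concentrate on
  suppressor combinations rather than on the two largest marginal
  correlates. The recovery experiment reports the top-2 agreement rate, and
  in repeated synthetic trials it holds only in a minority of seeds; a
  reported convergence of the two rankings on any single dataset should be
  read as a property of that dataset, not of the method.
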