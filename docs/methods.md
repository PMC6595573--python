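# Methods

This note documents the models, numerical choices and known limits of
`leafspec`. It complements the API docs; nothing here states a result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Data model

A raw study consists of replicate reflectance scans — nine per plant
(leaves 2–4, each at tip/middle/base) — on the 350–2500 nm grid at 1 nm
(2151 points), plus a lab trait table per plant. Replicates are averaged
arithmetically and symmetrically into one spectrum per plant before any
modelling; the pipeline never treats leaf or position as a factor. LWC and
SLA can be derived from lab fields as LWC = (FW − DW)/FW × 100 (%) and
SLA = LA/DW (m²/kg, DW converted g → kg inside the function).

## Preprocessing

1. **Trim** to 450–2500 nm. The 350–450 nm edge of contact-probe spectra is
   dominated by detector noise and is discarded (2151 → 2051 bands).
2. **Savitzky–Golay** smoothing, window 5, polynomial order 2, applied along
   the wavelength axis. Edge bands are filled by evaluating the same-order
   polynomial fitted to the edge window (scipy's `mode="interp"`), so the
   band count is preserved. A window-5/order-2 filter reproduces any local
   quadratic exactly; its interior impulse response is (−3, 12, 17, 12, −3)/35.
3. **Decimation** to every 5 nm anchored at 450 nm (2051 → 411 bands). This
   is point selection of the smoothed values, not block averaging: after
   smoothing, neighbouring 1-nm bands are almost perfectly correlated and
   selection is the simpler, exactly-invertible-in-shape choice.
4. **Standardization** of predictors and response to zero mean and unit
   sample variance (n − 1 denominator). Scaling statistics are always
   computed on the training split (or the fold-complement inside CV) and
   reused downstream — never on data the model will be scored on.

## Whole-spectrum calibration

Both calibrations operate in standardized space and pick their complexity
hyperparameter by 10-fold random-segment cross-validation. Folds are a
seeded permutation split into near-equal segments (sizes differ by ≤ 1);
RMSE_CV pools all held-out squared residuals (rather than averaging
per-fold RMSEs) and is reported in original trait units. Ties in RMSE_CV
resolve to the simpler model (fewer latent variables, smaller C).

### Partial least squares (PLS1, NIPALS)

Components are computed by NIPALS with deflation of X and y: weight
w ∝ Xᵀy (unit norm), score t = Xw, loadings p = Xᵀt/tᵀt, q = yᵀt/tᵀt,
then X ← X − tpᵀ, y ← y − qt. Training scores are mutually orthogonal and
weights unit-norm by construction; the regression vector for a components
is B_a = W_a (P_aᵀW_a)⁻¹ q_a. Up to 25 latent variables are considered
(clipped with a warning to min(n − ⌈n/k⌉ − 1, p) when the CV fold size
cannot support that many); the CV curve is computed for all counts in one
pass per fold and the minimiser is refitted on the full training set. With
as many components as the centered predictor rank, PLS1 reproduces the
ordinary least squares fit — the test suite uses this as an oracle.

### Linear ε-insensitive SVR

The primal is min ½‖w‖² + C Σ max(0, |yᵢ − w·xᵢ| − ε) in standardized
space, without a bias term: predictors and response are centered there, so
the optimal intercept is zero (it is stored explicitly as 0 and the
response mean re-enters through the inverse scaling). The dual
min ½βᵀQβ − yᵀβ + ε‖β‖₁ over [−C, C]ⁿ with Q = XXᵀ is solved by
coordinate descent with an exact one-variable soft-threshold update and a
freshly seeded random coordinate permutation each sweep. Convergence is
declared when the relative duality gap falls below 1e-6, with a hard cap
of 10,000 sweeps; hitting the cap is recorded on the results object and
warned about once. ε defaults to 0.1 in standardized response units. The
kernel is compiled with numba; the Gram matrix is shared across the C grid
within each CV fold. The test suite checks the solution against a generic
box-constrained QP solver and against the KKT conditions of the
ε-insensitive loss.

## Vegetation indices and the two-band search

All indices are normalized differences (B1 − B2)/(B1 + B2) of reflectance
at two exact grid bands (no interpolation; an off-grid request fails,
naming the nearest bands). Built-ins: GNDVI = (R800 − R550)/(R800 + R550),
RENDVI = (R750 − R705)/(R750 + R705), NDWI = (R860 − R1240)/(R860 + R1240).
Index-to-trait calibration is OLS on [1, v, v²]. The exhaustive search
scores every unordered pair of processed-grid bands (411·410/2 = 84,255
pairs on the default grid) by the absolute Pearson correlation of the
(longer − shorter)-oriented index with the trait, on training samples only;
the normalized difference is antisymmetric under band swap, so |r| is
orientation-invariant and the unordered search is complete. Exact |r| ties
resolve to the lexicographically smallest (short, long) pair. The search
runs on the 5-nm processed grid by default — the selected bands are then
multiples of 5 nm, which is also where the three built-in VI bands live.

## Evaluation

The sample set is split 60/40 by a seeded permutation (train size
round(0.6·n)); one split per run is shared by every method and trait.
Metrics on the test set:

* RMSE = √(Σ(Ŷᵢ − Yᵢ)²/N).
* MAPE (%) = 100 · (Σ|Ŷᵢ − Yᵢ|/N) / Ȳ. Note the single division by the
  mean measured value — this is *not* the textbook per-sample percentage
  error, and the two disagree whenever Y varies. The package implements
  only this variant, under the name `mape`, because it is the quantity the
  rest of the metric panel is designed around.
* RPD = SD(Y)/RMSE with the sample (n − 1) SD, so RPD·RMSE = SD(Y) is an
  exact identity. Perfect predictions give RPD = +∞ with an explicit flag.
* R²: primarily the squared Pearson correlation between measured and
  estimated values (affine-invariant, the convention for
  measured-vs-predicted scatter reporting); the 1 − SSres/SStot variant is
  co-reported as `r2_ss` since the two differ for biased predictions.

RPD grades: Excellent (> 3.5), Very Good (2.5–3.5), Good (1.5–2.5), Fair
(< 1.5). Exact boundary values resolve downward (3.5 → Very Good),
matching the strict inequalities of the tier definitions.

PCA of processed spectra is a column-centered SVD returning scores and
explained-variance fractions, for exploratory group-structure plots.

## Synthetic study generator

The generator exists so the whole pipeline is testable without access to a
real study. It emulates, per seeded run:

* **Traits**: per environment group (FieldMinusN, FieldPlusN, Greenhouse),
  a six-dimensional Gaussian with group means, shared per-trait SDs and a
  shared correlation matrix, clipped to physical ranges. Defaults encode
  the consistently reported relations — CHL–N r = +0.75, CHL–SLA −0.55,
  LWC–SLA +0.5, LWC–K +0.5, N–P +0.6 (matrix positive definite, smallest
  eigenvalue 0.159) — and CHL/N group ordering Greenhouse > Field+N >
  Field−N. Means/SDs (e.g. CHL 300/420/520 ± 80 µmol/m²; N 2.2/3.0/3.6
  ± 0.45 %) are plausible for a diverse maize panel at tasseling but are
  invented plumbing: no quantitative match to any real study is claimed.
* **Spectra**: a smooth continuum (VIS shoulder 0.15, logistic red edge at
  712 nm, NIR plateau ≈ 0.5, gentle SWIR decline) minus Gaussian absorption
  dips in reflectance space: pigment dips at 430/660 nm scaled by CHL,
  water dips at 970/1240/1450/1900 nm scaled by LWC, dry-matter dips at
  2100/2300 nm scaled by N, and deliberately weak P (2150 nm, strength
  0.003) and K (1350 nm, 0.008) features so that P and K are mostly
  recoverable only through their trait correlations — reproducing the
  usual finding that P is the least predictable of the six. SLA drives no
  spectral feature at all and is recoverable only via its correlations.
* **Noise structure**: i.i.d. Gaussian band noise (sd 0.004, elevated to
  0.012 below 450 nm) per scan; a per-scan continuum scale factor
  (sd 1 %) for within-leaf variation; and two per-plant components shared
  by all nine replicates so they do not average out — a structural
  brightness factor (sd 2 %) and a smooth additive nuisance curve (eight
  random Gaussian bumps, amplitude sd 0.006) standing in for unmodelled
  constituents. The nuisance component is what keeps whole-spectrum R²
  below 1 and separates trait tiers; without it every trait with any
  spectral expression is recovered essentially perfectly.
* Reflectance is clamped to [0.001, 1.0]; with all noise terms disabled the
  spectrum is a deterministic function of the trait vector.

What the generator does **not** emulate: radiative transfer (no
PROSPECT-style leaf optics), absolute reflectance magnitudes of any
particular instrument, wavelength-correlated instrument drift, specular/
geometry effects, or genotype structure within groups. Passing tests on
synthetic data therefore demonstrate the correctness and statistical
behaviour of the pipeline, not field performance on real maize spectra.

## Reproducibility

Every source of randomness flows from seeds. The pipeline derives one
child seed per stage (simulate / split / CV folds) from the master seed via
`numpy.random.SeedSequence(master, spawn_key=(stage,))`, truncated below
2³¹, so stages can be rerun in isolation; repeated runs with the same
configuration are byte-identical in all JSON outputs. The SVR solver's
coordinate permutations use a fixed internal seed, making fits
deterministic irrespective of the user's seeds.

## Default problem sizes

The default synthetic study is 150 plants per group × 3 groups × 9 scans
(4050 spectra), chosen as a realistic panel size for a single-season
phenotyping experiment; the full acceptance run (all six traits, all four
method families) completes in about two minutes on one CPU. Unit tests use
smaller fixtures (10–30 plants) except where a contract explicitly
concerns the default scale.

## Known limitations

* PLS1 only (univariate response); multi-trait joint calibration (PLS2) is
  out of scope.
* The SVR has no bias term outside standardized space by design; applying
  it to deliberately uncentered data would bias predictions.
* No derivative/SNV/MSC/continuum-removal preprocessing and no nonlinear
  SVR kernels — the pipeline mirrors a specific, deliberately simple
  analysis chain.
* The wide-CSV reader expects a regular integer-nm grid; irregular grids
  and vendor binary formats (.asd) are unsupported.
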