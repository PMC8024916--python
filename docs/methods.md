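# Methods

This note documents the models implemented in `eraptype`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions that matter for reproducing results.

## Allotype calling and population statistics

An ERAP1 allotype is a 9-residue haplotype over the coding polymorphic
positions (56, 127, 276, 346, 349, 528, 575, 725, 730), in that canonical
order. Position 12 also passes a 1% polymorphism cutoff but lies in the
signal peptide and is excised from the mature protein, so the site filter
(`filter_polymorphic_sites`) takes an explicit exclusion list rather than
hard-coding it.

Calling is exact catalog lookup: the shipped catalog maps the 16 known
haplotypes to labels 1–16 and everything else to `unassigned`, which
participates in all downstream tables as its own label. The catalog is
deliberately not frequency-driven at call time — the discovery cutoffs
(1% in all populations for allotypes 1–10; 0.5% in at least one population
for 11–16) describe how the catalog was assembled, and both are exposed as
parameters of the site filter rather than baked into classification.

Frequencies are chromosome counts divided by total chromosomes, kept at
full precision internally and rounded to one decimal percent only in
report writers. Diplotypes are unordered pairs with numerically sorted
keys. Two co-occurrence expectations are computed: the Hardy–Weinberg form
(2pq for distinct allotypes, p² for homozygotes), which is the default,
and the plain product p·q, kept because it is a common back-of-envelope
comparison. For the two commonest allotypes (p = 25.6%, q = 21.8%) these
give 11.2% and 5.6% respectively; the random-pairing simulation
(`random_pairing_simulation`) converges on the former, which is the
mechanistically correct null for unordered pairs.

ERAP2 is reduced to its two tag SNPs: haplotype [G,A] over
(rs2549782, rs2248374) is allotype A and [T,G] is allotype B; anything
else is `other`. The rs2248374 G allele abolishes expression, so a sample
is expression-null iff both haplotypes carry G there — with only A/B
haplotypes present this coincides with B/B homozygosity.

## Enzyme kinetics

Units are molar and seconds throughout the library.

- **Standard curves** are ordinary least-squares lines (signal on
  concentration) with an invertible `apply`/`invert` pair; a
  non-positive slope is rejected as a calibration failure.
- **Initial rates** are the slope of the early time-course region. The
  window is defined by accumulated product ≤ 10% of initial substrate
  (minimum four points). This keeps the constant-substrate assumption
  explicit: the 10% window still under-reads the instantaneous rate by
  up to ~3–4% when S ≈ K_M/2, because the rate falls as substrate
  depletes; a 5% window halves that. The window fraction is a parameter
  so analyses can make that trade-off explicitly.
- **Linear-regime efficiency**: when v/E is proportional to S the slope
  is k_cat/K_M directly. The through-origin slope weights points by S²,
  so the estimate carries a downward curvature bias of roughly the
  largest S/K_M in the design; grids should stay below ~K_M/20 for <5%
  bias. Curvature is detected as R² below 0.98 (flag by default,
  exception in strict mode).
- **MM and Hill fits** use `scipy.optimize.curve_fit` with non-negative
  bounds. Both are fitted in nondimensional form (substrate scaled by
  its median, rate by its maximum) because raw magnitudes (rates
  ~1e-10 M/s against K_M ~1e-5 M) stall the trust-region optimiser at
  its starting point. Starting values are therefore simply (1, 1[, 1]),
  i.e. V_max ≈ max rate, K ≈ median S, h = 1. Standard errors come from
  the scaled covariance mapped back to physical units; k_cat/K_M errors
  use the delta method including the k_cat–K_M covariance. Least
  squares is unweighted (assay noise is treated as homoscedastic on the
  measured-rate scale over the ranges used).
- **Model selection** between MM and Hill uses AIC
  (n·ln(RSS/n) + 2(k+1)); the extra Hill parameter must improve AIC by
  more than 2, otherwise MM wins by parsimony. `fit_hill(fix_h=1)` is
  exactly the MM model and agrees with `fit_mm` to optimiser precision,
  which the tests assert at four significant figures.
- **Non-results**: fits that do not converge return flagged results
  with NaN parameters; activity profiles treat absent entries as
  missing and fold-ratio/landscape code excludes them with a log note,
  never extrapolating. This is how the catalytically deficient allotype
  10 on the Leu-pNA substrate is represented: no ground truth, no data,
  an explicitly missing value downstream.

## Sequential trimming

Quantification divides each species' MS signal by the co-measured
internal-standard signal and inverts the species' calibration curve.
Descriptive summaries are computed exactly as the data are sampled:
fractions of the per-time-point total, and maxima over the sampled grid
without interpolation (the time courses are discrete; interpolated maxima
would claim unmeasured resolution). LOWESS (tricube-weighted local linear,
no robustness iterations, backed by statsmodels) is provided as a display
aid only and never feeds statistics.

The cascade model is an extension beyond the descriptive statistics: all
species that still have a scissile N-terminus compete for one enzyme,

    v_i = kcat_i · E · (S_i/KM_i) / (1 + Σ_j S_j/KM_j),

with d[S_i]/dt = v_{i−1} − v_i and the terminal product not consumed.
This is the simplest mechanism consistent with single-enzyme digestion of
co-present substrates; free amino acids are not tracked (each cleavage
converts one peptide into one shorter peptide), so total peptide is
conserved, which the integrator reproduces to better than 1e-6 relative.
Rate recovery (`recover_cascade_rates`) fits log-parameters jointly to all
species with `scipy.optimize.least_squares` (residuals normalised by the
initial precursor, Jacobian-scaled). Below saturation the individual
(k_cat, K_M) pairs are strongly correlated along a flat valley; the
per-step efficiency k_cat/K_M is the well-determined combination and is
the primary output, with delta-method standard errors from the
log-parameter covariance. Slow variants are digested at higher enzyme
(the generators use 10×, mirroring assay practice), and the series carry
E explicitly so summaries can normalise per enzyme.

## Titrations

Raw readouts are converted to percent turnover
100·[P]/([P]+[S]) after correcting substrate and product detection
sensitivities through their calibration curves; turnover above 35% is
flagged (initial-rate conditions doubtful) but not excluded — the bound is
a QC observation, not a filter. Responses are normalised to percent
activity between uninhibited (high) and fully inhibited (low) controls
and may exceed 100% for activators.

The 4PL model is fitted on log10 dose,
r = r_inf + (r0 − r_inf)/(1 + 10^(slope·(log x − log XC50))), for
conditioning. A negative fitted slope is the mirrored parameterisation
and is normalised away; direction (`inhibition`/`activation`) comes from
whether the response falls or rises with dose, and `top`/`bottom` are
reported as the larger/smaller asymptote so activation curves show
top > 100%. Midpoints are reported as pXC50 = −log10(XC50/M) (pIC50 for
inhibition). A midpoint outside the tested dose range is flagged. Dose
designs matter more than the fit: a threefold series centred on the
transition keeps the pXC50 sampling error near 0.03 log units at 3%
response noise, while a series that clips one asymptote inflates it —
the generators default to centred series. Correlations between
per-allotype quantities report both Pearson and Spearman with two-sided
p-values, since with ~10 allotypes the choice is consequential and not
obvious a priori.

## Genotype-activity landscape

Total activity of a genotype is the sum of its two allelic catalytic
efficiencies, under an explicit equal-expression assumption (expression
and turnover effects of the SNPs are known to exist but are small and
SNP- rather than allotype-resolved, so they are excluded and the
assumption is carried as metadata). The default substrate is the 9mer
epitope, the substrate with complete efficiency coverage. Entries are
ranked by activity; the pair-level spread equals
(2·max allele)/(2·min allele), i.e. the allelic spread, which the tests
verify by brute force over all pairs. Activity banding for display is
left to the caller (no canonical numeric boundaries exist).

## Synthetic data

Generators are pure functions of (spec, seed); noise is multiplicative
log-normal parameterised by its CV and mean-corrected (E[noise] = 1),
with plate-reader-like heteroscedasticity in mind.

Panels: exact-count mode apportions round(freq × 2n) chromosomes with
largest-remainder correction so totals are exactly 2n, then pairs
chromosomes at random (or per an explicit joint diplotype table, checked
against the marginals). The shipped frequency columns leave a small
remainder, carried by an alphabet-valid haplotype absent from the catalog
so those chromosomes classify as unassigned. Population structure beyond
the per-population frequency vectors (LD decay, admixture, relatedness)
is *not* emulated; passing tests therefore validate the counting and
calling machinery, not robustness to real-panel artefacts.

Kinetic ground truths encode reported fold relationships rather than
absolute supplementary values: the 9mer efficiency ratio between
allotypes 2 and 10 is exactly 60 (k_cat 10-fold below the 1–9 median,
K_M spread within 6-fold, allotypes 1–2 the tightest binders), and the
Leu-AMC efficiency ratio between allotypes 3 and 10 is exactly 18 with a
~2-fold band across 1–9. Absolute magnitudes are plausible for an ER
aminopeptidase (k_cat of order 1–10 s⁻¹, K_M tens of μM for the 9mer)
and are configuration, chosen once. Leu-AMC linearity up to 150 μM is
represented by a common 1.5 mM K_M, making the efficiency the only live
parameter. Titration truths span pIC50 7.2–7.6 (active-site inhibitor)
and pXC50 4.8–6.5 (regulatory-site binder), with maximal activation
growing with potency so the activity–potency correlations have a
positive ground truth.

## Problem sizes and determinism

The test suite and acceptance script run at the study's own scales where
that is cheap (2504-sample panels, 200-seed pairing simulations, 100-seed
recovery batches) and at reduced scale where it is not: cascade-rate
recovery is exercised on two- and three-species systems, where the
noiseless round trip is sharp, rather than the full seven-species digest,
whose 12-parameter fit adds runtime without adding information about
correctness. Every stochastic path takes an explicit seed; derived seeds
come from `numpy.random.SeedSequence` spawning and stay below 2³¹.

## Known limitations

- Exact catalog lookup cannot absorb genotyping error or novel
  haplotypes; they surface as `unassigned` rather than nearest-match.
- The cascade model assumes one competitive pool and no product
  inhibition or re-binding beyond competition.
- The landscape ignores expression variation by design (documented
  assumption), and inhibitor analyses stop at the 4PL description — no
  mechanistic allosteric-coupling model is attempted.
- Phased input is required; the package performs no phasing or
  imputation.
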