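# Methods

## The trial and its synthetic regeneration

The analysis targets a greenhouse trial of two contrasting soybean
genotypes — MUNASQA (drought-tolerant, slow-wilting background) and TJ2049
(susceptible) — under well-watered control and mild water deficit imposed at
the V3 (vegetative) and R5 (seed-fill) stages, with destructive sampling of
10 replicate plants per cell at 0, 4 and 8 days after stress (DAS). Twenty-two
markers spanning three biological processes (8 stress-response, 5 growth,
9 water-use) were scored, plus per-plant yield at maturity from 50 plants per
genotype in each of three arms (control, V3-stress, R5-stress).

No replicate-level data are available for this trial; its published record is
per-cell means and standard errors. The synthetic generator treats that record
as the data-generating truth:

* **Noise model.** Replicates are drawn i.i.d. normal around each cell mean
  with SD = SE·√n (n = 10 for the core markers; 50 for leaf morphology,
  where one independent experiment scored 5 plants × 10 microscope fields at
  R5/21 DAS; 40 for stomatal aperture, scored 72 h after stress at V3).
  Normality and independence are modelling choices matching the mean ± SE
  reporting convention; real replicates share pot/bench effects the generator
  does not emulate, so a green test establishes correctness of the analysis
  given the stated noise, not robustness to correlated error.
* **Positivity.** Markers that are physically nonnegative are floored at
  1e-6 after sampling (events logged). CTD and the interval rates may be
  negative and are never floored.
* **Rate markers.** NAR, RGR and CGR are undefined at 0 DAS (no interval
  yet); their cells exist only at 4 and 8 DAS, so the default design emits
  160 records for them and 240 for every full-layout marker.
* **Primitives.** A second generator inverts the index formulas per
  replicate: A = LAI·GA with fixed ground area GA = 400 cm² per plant,
  DW = A/LAR, TW = DW/0.3 (dry matter set to 30% of turgid weight),
  FW = DW + (RWC/100)(TW − DW), water = DW/WUE, T_canopy = T_air − CTD with
  T_air fixed at 25 °C (V3) and 28 °C (R5). At zero SE, recomputing the five
  point indices from the primitives reproduces every target cell mean
  exactly (the round-trip oracle in the test suite). Interval rates computed
  from these trajectories are consistent with the LAI/LAR trajectories, not
  with the independently printed rate cells — the published tables are not
  mutually consistent at that level of detail, and the measurement generator
  (which samples rate cells directly) is the path used for analysis.
* **Yield.** Per-plant yields are not published. Defaults are realistic
  greenhouse soybean values chosen once: MUNASQA 21.0/17.2/15.1 g and
  TJ2049 24.0/15.6/10.8 g (control/V3-stress/R5-stress), SD ≈ 15% of the
  mean — the susceptible genotype loses proportionally more, so the DSI
  orders as expected (TJ2049 > 1 > MUNASQA).

Everything is a pure function of (config, fixtures, seed); one
`numpy.random.default_rng` per generator, cells visited in canonical sort
order.

## Index conventions

* RGR = (ln W2 − ln W1)/Δt; NAR uses the log-mean leaf area weighting
  (ΔW/Δt)·(Δln A/ΔA) with the analytic limit ΔW/(A·Δt) when A1 = A2;
  CGR = ΔW/(GA·Δt). Rates are computed over the 0→4 and 4→8 DAS intervals
  and assigned to the right endpoint, which is why 4- and 8-DAS rate cells
  exist and 0-DAS ones do not.
* RWC = 100(FW − DW)/(TW − DW); WUE uses cumulative water applied from
  stress onset to the sampling day; CTD = T_air − T_canopy, so a stressed
  canopy with closed stomata (warmer than air) has negative CTD.
* DSI_g = (1 − Ys_g/Yp_g)/D with D = 1 − Xs/Xp over the across-genotype
  mean yields; the Yp-weighted mean DSI is identically 1, a property test.

## Statistics

* **Letters.** One-way ANOVA (scipy `f_oneway`) with all-pairs Tukey HSD
  (scipy `tukey_hsd`), summarized by an insert-and-absorb compact letter
  display: groups sharing a letter never differ at α, groups sharing none
  always do (verified against the exhaustive pairwise oracle). Letter
  columns are ordered by ascending group mean; ties break lexically. If all
  within-group variance is zero with unequal means the Tukey distribution
  degenerates; distinct letters per distinct mean are returned with a
  warning. The dual-letter table convention: uppercase letters compare the
  four genotype × treatment groups within each stage × DAS column, lowercase
  letters compare the three sampling days within each group × stage row,
  each family at α = 0.05.
* **Stage-accuracy screen.** Per marker, the V3 and R5 streams are paired by
  (genotype, treatment, DAS, replicate rank) — the default, conservative
  because replicate rank is arbitrary, so correlation reflects only the
  shared cell-level structure — or by cell means. The published per-group
  coefficients are near the cell-mean end of that spectrum. Bonferroni
  family = all correlations computed in one invocation (logged on each
  result); stars from the adjusted p (≤0.05 *, ≤0.01 **, ≤0.001 ***).
  Strength is Strong iff |r| ≥ 0.60: the published classification leaves a
  gap between "> ±0.60" and "below ±0.59", and the closed threshold at 0.60
  is the unique rule consistent with every printed label (batch-checked in
  the acceptance suite). Printed coefficients are labelled "r²" yet include
  negative values; they are treated as signed Pearson r throughout.

## PCA

Markers are standardized before decomposition (correlation-matrix PCA) —
they live on scales from µmol·gDW⁻¹·min⁻¹ to °C, so covariance PCA would be
dominated by unit choices. The **observation unit defaults to genotype ×
treatment group means** (4 observations). The published variance splits pin
this down: with group means the morphological water-use PCA reproduces the
printed split exactly (96.6% = 73.8 + 22.8) and the stress-response set gives
97.0 vs the printed 96.6, whereas design-cell means give 78.4. Cell-mean and
replicate-level observation modes remain available and agree with the default
on the leading loading direction (|cos| > 0.95) at the shipped noise levels.
With only 4 observations a PCA has at most 3 nonzero eigenvalues — the
concentration of variance on PC1+PC2 partly reflects that rank limit, which
is also true of the published analysis. Loadings are unit-norm with the
largest-magnitude coefficient of each component made positive, so downstream
SW labels are reproducible. Markers confined to reduced layouts (morphology,
stomatal aperture) can only enter observation units coarse enough to cover
them; finer-grained matrices drop them (mostly-empty rows, then sparse
columns, then listwise).

## The CF × SW rubric

CF categories are registry metadata (lab economics): the shipped registry
reproduces the published categories for the nine CF-passing markers; the
remaining 13 are assigned 3 or 4 (any non-passing value behaves
identically). Selection = CF ∈ {1, 2} ∧ High on PC1 ∧ High on PC2; it is
monotone in label upgrades and depends only on (cf, sw_pc1, sw_pc2), both
property-tested.

The published SW scale "High outside [−2, 2]" cannot act on raw unit-norm
loadings (bounded by 1), and its exact transform is undocumented. The
transform is therefore pluggable:

* `zscore` (default for loading-derived labels): standardize each
  component's coefficients across markers.
* `rank`: the rank-based robust score (x − median)/(1.4826·MAD). A literal
  rank-then-z-score transform is provably bounded by
  √(3(m−1)/(m+1)) < √3 < 2 for m markers and could never emit a High call at
  threshold 2, so the robust score is used as the rank-flavoured option.
* `external`: pass published High/Low calls through unchanged (provenance
  recorded). The shipped fixture carries the published calls for the nine
  CF-passing markers and is the default pipeline path, since guessing the
  undocumented scale would manufacture agreement.

When labels are derived from loadings, each marker is labelled from the PCA
of its own biological-process set.

## Numerical and degenerate-input choices

Eigendecomposition via `numpy.linalg.eigh` on the correlation/covariance
matrix (symmetric, stable); tiny negative eigenvalues are clipped to 0.
Constant columns are rejected when standardizing. Pearson p-values from
scipy's two-sided t-test; constant streams are rejected rather than returning
NaN. Bonferroni p_adj = min(1, m·p_raw). MAD = 0 in the rank transform falls
back to the z-score. Group summaries use ddof = 1 with SE = 0 for n = 1.

## Known limitations

* The generator emulates sampling noise only — no pot/bench/experiment
  random effects, no between-experiment pooling (the trial ran two
  independent experiments per assay; printed SEs are treated as one pooled
  sample of n = 10, the stated resolution of an open design question).
* Published in-text percent changes are reproducible from the shipped
  morphology means for the abaxial stomatal density (88.7 ≈ 89%) and the
  control stomatal aperture contrast (22.5 ≈ 22%), but the in-text 65%
  adaxial increase is not (the means give ≈ 53%); the package computes, it
  does not force, such claims.
* Two-way ANOVA assumes a complete factorial with replicates; unbalanced
  data are out of scope (type-II sums of squares on a balanced layout).
* Monte-Carlo checks quoted at 1000 seeds run at 200–400 seeds in the
  default suite (with correspondingly widened binomial tolerances) to stay
  within the test-time budget; the 1000-seed null calibration of the
  correlation screen runs at full size.
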