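# Methods

## Model chain

1. **Calibration.** Amplitude digital numbers are converted to
   gamma-naught with γ⁰_dB = 10·log₁₀(DN²) + offset (offset −83.0 dB, the
   standard mosaic calibration factor, configurable), then to linear
   power. All averaging is arithmetic in linear units; decibels appear
   only at I/O boundaries. DN = 0 cannot be calibrated and becomes
   nodata.

2. **Speckle filtering.** The enhanced (three-regime) Lee filter with a
   5×5 window: pure window averaging below the speckle coefficient of
   variation Cu = 1/√ENL, identity above Cmax = √(1 + 2/ENL) (point
   targets), and an exponentially damped blend between. ENL defaults to
   the gamma shape parameter of the speckle model at the scene mean.
   Window statistics use valid pixels only; all-nodata windows stay
   nodata. The filter variant and its damping are configuration, since
   only the window size is pinned by the source material.

3. **Biomass regression.** OLS of plot AGC on plot-mean linear γ⁰.
   Stored error statistics: residual SD (degrees-of-freedom corrected),
   r², and bias as the mean signed leave-one-out prediction error.
   Negative predictions are clamped to zero and counted (they sit at the
   non-wooded boundary). Bias is reported, not subtracted; a switch
   enables bias-corrected prediction for sensitivity runs.

4. **Speckle model.** Per-region gamma fits by method of moments
   (θᵢ = varᵢ/meanᵢ; maximum likelihood available as a cross-check),
   then unweighted OLS of θᵢ on meanᵢ giving (α, β). k = mean/θ, so the
   gamma mean k·θ equals the target mean exactly; a zero mean degenerates
   to a constant zero. Simulating speckle around an *observed* (already
   speckled) value double-counts speckle; this deliberate conservatism
   (estimates of change err low) is retained, not corrected.

5. **Change probabilities.** Nested Monte Carlo per observed pair:
   n_outer gamma draws per year, n_inner normal biomass draws per gamma
   draw (clamped at zero), 2007 and 2010 paired elementwise, and each of
   the five states counted as a joint event. The production sizes are
   10,000 × 200; unit tests run 2,000 × 50 with correspondingly widened
   tolerances. Joint-event counting is the primary semantics; a
   product-of-marginals mode exists for comparison and differs by less
   than 0.01 at the worked examples. Exact ties B₁₀ = B₀₇ have measure
   zero and are counted diagnostically. Lookup tables discretise
   (γ⁰₀₇, γ⁰₁₀) on a uniform linear grid (default bin 0.001 ≈
   0.7 MgC ha⁻¹); each cell is simulated independently with a seed
   derived from (master seed, i, j), so any cell is reproducible by a
   direct call. Nearest-bin lookup by default; renormalised bilinear
   interpolation optionally.

6. **The biomass-simulation SD.** The SD σ of the normal biomass
   realisations defaults to the *model standard error*
   (RMSE/√n ≈ 8.5/√137 ≈ 0.73 MgC ha⁻¹), i.e. the uncertainty of the
   fitted mean response, on top of the speckle already simulated. Using
   the full single-pixel RMSE (8.5) here would double-count the scatter
   that speckle produces and drives the worked-example probabilities far
   below their reported values (0.39 instead of ~0.75 for the
   degradation example); the model-standard-error reading reproduces
   both reported single-pixel probabilities inside their intervals. σ is
   a configuration field (`sim_sigma`) so the sensitivity is one flag
   away.

7. **Aggregation.** Class areas are per-pixel probability sums times
   pixel area (speckle has no spatial structure, so expectation is
   additive); carbon changes weight observed ΔAGC by class probability.
   The probability-weighted wooded area Σ(1 − p_nonwooded) is the base
   for percentage rates. Annual rates are pro-rata over the (default
   3-year) window; a compound-rate option exists but is off. Pixel area
   is constant per raster; geodesic per-pixel areas are a production
   concern, out of scope here.

8. **Soil moisture.** The correction is a minimal configurable stand-in:
   a tabulated non-increasing strength as a function of AGC (canopy
   attenuates the soil term), multiplied by an externally supplied
   moisture-difference proxy, capped, and subtracted from the later
   date. It defaults to disabled so no headline number depends silently
   on its invented parameters; the moisture-difference mask (|Δ| above a
   threshold) is independent of the correction.

9. **Uncertainty.** Repeated 2-fold cross-validation of the biomass
   regression: each replicate refits on a random half and records its
   holdout bias, then re-runs prediction, lookup-table construction and
   aggregation over a random tile subsample. CIs are the 2.5/97.5
   percentiles of the replicate estimates, widened if needed so the
   point estimate is always inside. Desk-scale defaults are 200
   replicates over 20 tiles with a coarsened per-replicate lookup table
   (1,000 × 20 draws, bin 0.004); production-scale replication (5,000
   replicates, 2,000 tiles) is a configuration change, not a code
   change.

## Synthetic landscapes

The generator builds a noise-free two-date AGC world first, then observes
it through the same forward model the pipeline assumes (inverted
regression mean, one gamma speckle draw per pixel-year, independent
years). Class labels are therefore re-derivable from the AGC pair and the
change definition, exactly, and class counts match the requested
fractions up to rounding (largest-remainder apportionment over a
quantile-sliced smoothed noise field, giving contiguous patches).

Default intensities echo the study system: gamma-shaped background AGC
with mean 24 MgC ha⁻¹; degradation removing 20–50% of initial stock;
deforestation ending below 10 MgC ha⁻¹ with >20% loss and residual
biomass allowed; growth increments lognormal with median 1.3 and SD
0.9 MgC ha⁻¹ yr⁻¹ over 3 years; class fractions 8/17/12/48% of pixels
(deforestation/degradation/minor loss/gain) over a 15% non-wooded
background. Plot records carry a field-error SD of 8.5 MgC ha⁻¹ as a
total-error stand-in, with plot backscatter the mean of ~10 pixel draws
(≈0.6 ha footprint).

What the generator does *not* emulate: spatial correlation of speckle,
terrain and seasonal acquisition artefacts, saturation roll-off (the
regression is treated as exact up to a hard 75 MgC ha⁻¹ ceiling), and
real floristic heterogeneity. Passing recovery tests therefore shows the
estimator is consistent with its own forward model, not that the forward
model matches any particular sensor.

### The separated validation scenario

With the realistic intensities, adjacent classes sit within one
observation-σ of the loss-ratio and threshold boundaries (a median gain
of ~4 MgC ha⁻¹ against an observation σ of ~4 MgC ha⁻¹), so class
probabilities necessarily spread over neighbouring classes and
probability-summed areas for those classes are biased by asymmetric
leakage — by construction, not by defect. Area recovery within 10%
is therefore asserted on `SyntheticScenario.separated()`, where every
class present sits ≥1–2σ clear of the boundaries (measured recovery:
deforested ±0.5%, degraded −6%, gain −1%, non-wooded +1%); on the default
landscape the deforestation class, whose pixels are far from the
boundaries in the loss direction, recovers within a few percent. Minor
loss is absent from the separated scenario: the (r, 1) ratio band is
narrower than the ratio noise, so that class cannot be separated from
its neighbours in principle.

## Numerical choices

- All simulation RNG is NumPy `default_rng`; per-cell seeds are
  `SeedSequence([master, i, j])`; the two observation years use
  independent spawned streams. The degenerate normal scale σ = 0 is
  drawn (not branched around) so runs differing only in σ share their
  speckle realisations.
- Monte-Carlo tolerances in tests are 2–3 binomial standard errors at
  the simulation size used.
- Problem sizes: unit tests run lookup tables at coarse bins and
  2,000 × 50 draws; the end-to-end recovery checks use 300×300
  landscapes with bin 0.002. These sizes were chosen so the whole suite
  runs on a single CPU in a few minutes while keeping Monte-Carlo error
  well inside the asserted tolerances.
- Degenerate inputs: all-nodata images are flagged, empty regions produce
  zero summaries with a warning, degenerate cross-validation halves are
  redrawn and counted.

## Known limitations

- Conditioning each pixel's simulation on its *observed* value
  overstates speckle (acknowledged above); probabilities are
  conservative and probability-summed areas are biased where classes
  crowd the decision boundaries.
- The tile-to-whole-area CI scaling is a ratio approximation; spatial
  autocorrelation of regression residuals is not modelled.
- The soil-moisture module is an interface with placeholder physics, not
  a retrieval.
- Only the HV-polarisation single-band chain is implemented; terrain
  correction and mosaic tiling are assumed done upstream.
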