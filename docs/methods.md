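# Methods

## Problem and model

A peptide–carrier conjugate is a statistical mixture: each carrier molecule
carries an integer number *n* of peptides. In a linear-MALDI spectrum the
mixture shows up as an arithmetic ladder of peaks at

    c(n) = (M0 + n·Δ + z·m_p) / z,

observed at a fixed charge state *z* (doubly charged for a ~58 kDa
carrier; linear MALDI of large analytes produces mostly low charge
states). `M0` is the neutral mass of the load-0 species, `Δ` the neutral
mass gained per conjugated peptide, and `m_p = 1.007276` Da the proton
mass. All masses are average (not monoisotopic): at ~60 kDa in linear
mode the isotope envelope is unresolved.

The pipeline estimates the per-species abundances by fitting the ladder
jointly as a sum of Gaussians and summarises them as

    HD = Σ VUC_n·n / Σ VUC_n,      σ = sqrt(Σ VUC_n·(n − HD)² / Σ VUC_n),

with `VUC_n = A_n·σ_n·√(2π)` the closed-form Gaussian area (closed form,
not a numerical quadrature, for consistency with the fitted model). σ is
the area-weighted *population* standard deviation of the load — the
parameter-free reading of "dispersity of HD"; whether it should instead be
weighted by molar fraction is an open modelling choice, and area-weighting
is what all outputs state. Both statistics are invariant to rescaling all
areas, so only relative abundances matter; the underlying assumption —
reasonable for chemically near-identical species in a narrow m/z range —
is that peak area is proportional to molar abundance.

## Calibration

Calibration is a degree-1 or degree-2 polynomial on the m/z axis fitted by
least squares to calibrant ions (reference m/z = (M + z·m_p)/z). No
time-of-flight physics is modelled: downstream arithmetic needs only a
corrected m/z axis. Both degrees are exposed because the appropriate
order depends on the instrument; with perfect calibrants the fitted map is
the identity to machine precision. Degenerate (duplicate) calibrant
positions and under-determined fits are rejected.

## Preprocessing

* **Savitzky–Golay** smoothing (default window 11 points, polyorder 3 —
  standard practice for profile TOF data). The filter reproduces any
  local polynomial up to its order exactly; edges use the boundary
  polynomial on the truncated window. A warning is emitted if the m/z
  grid spacing varies by more than 10%.
* **SNIP** baseline estimation: iterative clipping
  `y_i ← min(y_i, (y_{i−m}+y_{i+m})/2)` for m = 1..m_max (the classic
  increasing sweep; the decreasing variant is available since both appear
  in the literature). By default clipping runs in log-log-sqrt (LLS)
  compressed space so tall peaks are eroded as readily as small ones; the
  un-compressed path is provided because either choice is defensible for
  this data. The returned baseline is point-wise ≤ the input, and is
  monotonically non-increasing in m_max.
* `m_max` defaults to `round(0.5 · 4 · FWHM_points)`, i.e. twice the peak
  width in points; the pipeline helper measures the width of the tallest
  feature to set this automatically. Endpoints are held fixed.
* Subtraction optionally clips negatives at zero (default on). Note that
  on noisy data SNIP hugs the *lower envelope* of the noise, so the
  subtracted spectrum retains a small positive pedestal of order the noise
  SD; see "Load-range selection" for the one place this matters.

## Ladder deconvolution

The model over the fit window is `y(x) = Σ_n A_n·exp(−(x−c_n)²/(2σ_n²))`
with:

* centres `c_n = predicted(n) + shift + jitter_n`, where the common shift
  (bounded, default 0.2·Δ/z) absorbs residual calibration and M0 error and
  per-peak jitter (default 0.05·Δ/z) absorbs local imperfections. The
  shift/jitter split for a pure offset is deliberately not identifiable —
  only the resulting centres matter — but the bounds keep the *load
  assignment* unambiguous, which is what HD depends on. `M0` itself is
  never fit freely.
* amplitudes `A_n ≥ 0`, bounded above by 1.05× the observed maximum
  (prevents runaway amplitudes in flat regions);
* widths either one shared σ (default) or σ linear in m/z. TOF resolution
  varies slowly, so the shared width is adequate for HD; when peak widths
  visibly scale with m/z (as in the simulator, where FWHM is a fixed
  fraction of m/z) the linear model removes a small systematic bias in the
  areas of edge species (a few per cent), and the area-recovery guarantees
  are stated under it.

Fitting is bounded trust-region least squares (`scipy.optimize.
least_squares`), initialised from the local maxima nearest the predicted
centres and a half-height width estimate of the tallest peak; up to 3
restarts with seeded multiplicative perturbation of the start point on
non-convergence, so the whole procedure is deterministic given the config.
Ladder species whose predicted centre falls outside the data range are
dropped before fitting (their amplitudes would be unidentifiable), and
species fitted below 1% of the maximum amplitude are pruned — the load
range is trimmed to the surviving contiguous span — followed by one refit.
Fit quality is reported as the adjusted R² of the cumulative fit,
`1 − (1−R²)(N−1)/(N−k−1)` with k the number of free parameters, plus the
residual RMS.

### Load-range selection

`select_load_range` trims a candidate superset range. The
`amplitude_threshold` criterion keeps the contiguous span surviving the
pruning threshold. The `bic` criterion then shrinks/grows the range one
species at a time while the BIC (`N·ln(SS/N) + k·ln N`) of a refit on one
*fixed* window improves; trial fits keep the pruning threshold so that BIC
cannot reward phantom species that fit the clipped-noise pedestal left by
baseline subtraction.

## Conjugation chemistry

Peptide masses are summed from a standard residue-mass table (average and
monoisotopic) plus water and terminal modifications (N-acetylation
+42.037/+42.0106 Da; C-terminal amidation −0.985 Da), with the conjugate
peptide assembled as `(epitope + GG linker) × repeats + Cys`. The SBAP
(succinimidyl 3-(bromoacetamido)propionate) coupling arithmetic is done
from molecular formulas rather than hard-coded constants: per conjugated
peptide the carrier gains the acid remnant minus H₂O (amide bond to
lysine) minus HBr (thioether to the peptide cysteine), C₅H₅NO₂ = 111.10 Da
average; a cysteine-capped unreacted site gains 232.25 Da. Under the
default capping policy (all activated-but-unconjugated sites capped,
~20 activatable sites per carrier, configurable) each conjugation
displaces one cap, so the *observed* ladder spacing is
`Δ − cap = peptide + 111.10 − 232.25` rather than `Δ`; both conventions
are exposed (`ladder_spacing` vs `observed_ladder_spacing`) because
published workflows are usually silent about which baseline they quote.

`percent_identity` is strict identity (matches/length) over gap-free,
equal-length sequences, and is labelled as such: no substitution-matrix
similarity is computed, so conservative substitutions count as
mismatches. For the three IRIS homologs this gives mouse–bovine 12/13 =
92.3%, human–bovine 9/13 = 69.2% and human–mouse 10/13 = 76.9%; a
"similarity" scheme that counts conservative substitutions would give
higher human figures, which is why the tool's outputs always say
"identity".

## Simulator

The simulator is the package's source of ground truth. Species fractions
are computed analytically from the load model (binomial over n_sites —
independent site occupancy, the natural stand-in for conjugation at
increasing molar excess; Poisson; or an explicit table), truncated at
1e-6 and renormalised, so `true_hd`/`true_sigma` are exact moments, not
Monte-Carlo estimates. Rendering places one Gaussian per species and
charge state at the ladder-predicted centre with FWHM a fixed fraction of
m/z (default 0.8%, i.e. resolving power ~125, typical of linear-mode
protein work) and **area** proportional to molar fraction × charge-state
weight — areas rather than heights, since proportionality of area to
abundance is exactly the assumption the HD estimator makes. An
exponential baseline (default 20% of the tallest peak, decay 5·10⁻⁴/Th)
and seeded additive Gaussian noise (default SD 1% of the tallest peak,
SNR 100) are added and the result clipped at zero. Defaults for the
conjugate itself are the targeted system: carrier 58 408 Da (CRM197),
Δ = 1835.02 Da (single-repeat IRIS peptide + SBAP remnant), z = 2 only,
with an optional low-weight z = 1 satellite for robustness tests.

What the simulator does **not** emulate: Poisson counting noise, detector
saturation, matrix adducts and clusters, isotope structure, peak-shape
asymmetry (real MALDI peaks tail), or ionisation bias between species.
Passing tests therefore demonstrate correctness of the deconvolution and
statistics under the stated noise model, not robustness to every
instrument artefact; in particular a real ionisation bias across loads
would propagate directly into HD and cannot be detected from a single
spectrum.

## Problem sizes and numerical choices

Simulated spectra use 4000-point grids spanning the ladder ±6 FWHM —
ample sampling (~25 points per σ) at modest cost. End-to-end recovery is
validated over 50 seeded simulations with true HD in [1, 8] at SNR 50,
where the pipeline recovers HD within ±0.25 peptides; the three-condition
series (occupancy 0.1/0.2/0.35) fits with adjusted R² ≈ 0.998. Ties and
degenerate inputs are handled by explicit errors: empty spectra,
all-zero fit windows, zero total variance in R², all-zero abundance
tables, monotone curves in FWHM. mzML I/O writes single-spectrum
documents (64-bit floats, zlib+base64) parsed back with lxml; duplicate
m/z values on read are merged by summing (conserves total ion count) and
negative intensities are clipped with a provenance flag in the metadata.
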