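# Methods

This note documents the models, conventions and design choices behind
proxispec, in the spirit of a package methods appendix: what is computed,
with which defaults, and what the synthetic test bed does and does not
establish about real data.

## Spectral collection model

All analysis operates on a `SpectralCollection`: a samples × wavelengths
reflectance matrix on one shared, strictly increasing integer-nm grid.
Building a collection from spectra on different grids first rounds each
grid to integer nanometres (1-nm acquisition is the recommended instrument
resolution) and then takes the **intersection** of the rounded grids; each
sample contributes its own measured value at every shared wavelength.
Nothing is ever interpolated or resampled — sub-nm or coarser instruments
must be harmonized upstream, and spectra with no common wavelength are an
error rather than a silently resampled dataset. This strictness is the
foundation of the missing-value rule for indices (below): a value reported
by proxispec is always a value the instrument measured, or arithmetic on
such values.

Trimming keeps a **closed** interval `[min, max]`, so the documented
analysis range of 400–1,000 nm retains both endpoints; masking removes
closed intervals and is exactly the complement of trimming (a property the
suite verifies on random grids). The 400–1,000 nm constant
(`ANALYSIS_RANGE_NM`) reflects the low signal-to-noise edges of the
supported field instruments; it is applied only when requested, never
silently. Masking endpoints are inclusive by the same convention; this is
a deliberate, documented choice where reasonable tools could differ.

Per-wavelength summaries are the mean, median, and the unbiased (n−1)
sample variance.

## File formats

* **ASD FieldSpec binary**: the reader supports a documented subset of the
  binary container — a 3-byte version magic (`ASD`, `as6`, `as7`, `as8`),
  a little-endian header (start wavelength f32, step f32, channel count
  i32, data-type code u8, payload format u8 = float32/float64, reference
  flag u8), the spectrum block, and an optional white-reference block.
  Raw target spectra are divided element-wise by the reference;
  zero-valued reference channels become per-channel missing values with a
  logged warning. Unrecognized versions fail loudly, naming the detected
  magic, rather than guessing at a layout. The fixture writer emits one
  canonical sub-format (float64, version `as7`) so round-trip tests are
  bit-exact and hermetic.
* **SpectraWiz text**: whitespace- or tab-delimited rows; any leading line
  whose first token does not parse as a number is treated as a header and
  skipped; the first two numeric columns are wavelength and reflectance.
* **Generic merged table**: delimiter sniffed from {tab, comma, semicolon}
  on the first line (ties broken in that order). Orientation is
  auto-detected: if the column labels parse as numbers they are the
  wavelength axis (samples as rows); otherwise the first column is the
  wavelength axis and the header carries sample ids. Reading a table and
  its transpose yields the same collection.
* **Attribute table**: tab-delimited, first column `filename`. A column is
  tagged *continuous* when every non-missing entry parses as a number and
  *discrete* otherwise. Note the consequence: purely numeric treatment
  labels (e.g. `140`/`180`) re-read from disk tag as continuous; users who
  want file-driven grouping should use labels like `N140`, or select the
  ANOVA branch explicitly (the CLI's `--method anova` does not consult the
  tag). Attribute keys match the exact filename first, then the basename
  without extension; unmatched samples are logged and excluded from
  attribute-dependent operations only.
* **Field layout**: comma-delimited matrix of filenames, no header; the
  first file row is the top field row, empty cells are empty plots, and a
  filename may occupy at most one cell.

Exports are tab-delimited with `.` decimals and 6 significant digits;
optional aggregation averages (or takes medians of) samples over
combinations of discrete attributes, ignoring missing entries.

## Vegetation-index registry and band math

The bundled registry holds **140 indices**, compiled from the primary
literature with band choices following the conventions established by the
hsdar spectral-analysis package where a source lists an index by name
only; each entry's reference column records its source. The registry is
restricted to closed-form *rational* expressions (no derivatives,
integrals, square roots or min/max over band windows) with all bands
inside 400–1,000 nm; red-edge inflection methods that need derivative
spectra are out of scope. A fourth column flags indices that are
scale-invariant (homogeneous of degree zero, e.g. pure ratios and
normalized differences); the suite verifies the flag numerically by
evaluating each flagged index on a spectrum and on a rescaled copy.

Formulas are parsed by a small recursive-descent parser over the grammar
`term := R<int> | number; expr := term | expr op expr | (expr)` with the
usual precedence, left associativity, and unary minus; `×`, `÷` and the
typographic minus are accepted as aliases. Evaluation semantics:

* if any required wavelength is absent from the collection grid, the index
  is missing for **every** sample — there is no nearest-neighbour band
  fallback, which would silently change index values;
* any arithmetic on a missing operand is missing;
* division by zero yields missing for that sample rather than an
  exception, so one degenerate spectrum cannot abort a 140-column sweep.

Out-of-range bands in user formulas produce a warning, not an error: the
definition is kept and simply evaluates to missing wherever the band is
unavailable.

## PCA and outlier flagging

PCA mean-centers the wavelength columns and decomposes via SVD. Columns
are deliberately **not** scaled to unit variance: all columns share
reflectance units, and autoscaling would inflate the noisy low-signal
bands the QC step exists to guard against. Signs are fixed by flipping
each component so its largest-magnitude loading is positive, making
results deterministic. Explained-variance fractions use the total variance
of the full decomposition as denominator.

The automatic outlier rule works in **score space**: samples, not
wavelengths, are the objects being screened, so "distance from the mean"
is computed on the per-sample PC1 and PC2 scores. For each axis,
`z = |score − mean| / sd` with the unbiased sd; a sample is flagged when
either axis exceeds `threshold_sd`. Per-axis thresholding (rather than a
Euclidean or Mahalanobis radius) is the simplest reading of an
"SD-from-the-mean" rule; the default threshold of 3 is a conventional
choice and is exposed as a parameter. A zero-variance axis contributes
z = 0, so degenerate inputs flag nothing.

## Trait association

For a continuous trait, each index is tested by Pearson correlation on
pairwise-complete observations, with the two-sided p-value from
`t = r·√((n−2)/(1−r²))` on n−2 degrees of freedom. For a discrete trait,
classical one-way ANOVA: `F = (SSB/(g−1)) / (SSW/(n−g))` with p from
F(g−1, n−g). Both statistics are computed from their defining sums, which
keeps scipy's `pearsonr`/`f_oneway` available as independent cross-checks
in the tests (the suite also verifies the two-group identity F = t²).
Levels with fewer than two complete observations are dropped with a
warning; indices left with fewer than two levels, fewer than three pairs,
or zero variance report a missing result carrying the reason. Because up
to 140 indices are swept at once, Benjamini–Hochberg adjusted p-values are
reported alongside the raw ones. The choice of pairwise-complete deletion
and of BH (rather than a family-wise method) are design decisions: the
sweep is exploratory screening, not confirmatory testing.

## Field maps

`build_fieldmap` fills the layout grid with each cell's sample value,
leaving empty cells and unmatched filenames missing (logged, never
imputed). Rendering draws one rectangle per cell with row 0 at the top
(reading order of the layout file), missing cells in neutral grey, a
colour bar, and a perceptually uniform sequential colormap (viridis) by
default.

## Synthetic data generator

The generator emulates the case this toolkit targets: a winter-wheat
fertilizer trial measured with a handheld spectroradiometer at 1-nm
resolution over 339–1,100 nm. A canopy spectrum is the closed form

    R(λ) = base + green·G(λ; 550, 25) − chl·G(λ; 670, 15)
         + plateau·logistic((λ − 720)/15) − water·G(λ; 970, 20) + ε(λ)

with G a unit-height Gaussian, ε ~ N(0, noise_sd) i.i.d. per wavelength,
and the result clipped at zero. Defaults: base 0.04, green peak 0.06,
chlorophyll dip 0.03, NIR plateau 0.45, red edge centred at 720 nm with
width 15 nm, water dip 0.05, noise sd 0.005. A trial draws one NIR offset
per breeding line (sd 0.02, shared across treatments and replicates) and
adds 0.06 to the plateau per step up in fertilizer level; the default
design is 10 lines × 2 treatments (140/180 kg ha⁻¹ labels) × 2
replicates. The dry-leaf control used as a planted outlier is a smooth
linear rise from 0.15 to 0.45 with no chlorophyll dip and no red-edge
step, which separates it decisively from any canopy spectrum in PC1–PC2
space. The replicate count of real trials varies; two is a fixture
choice, configurable in `TrialDesign`.

This is a pragmatic parametric model, not a radiative-transfer simulation
(no PROSPECT/SAIL physics, no band-correlated or signal-dependent sensor
noise, no spatial field trends). Passing tests therefore demonstrate that
the pipeline's mechanics are correct on data with the right qualitative
shape; they do not validate radiometric realism. One consequence worth
stating plainly: because the generator's band noise is i.i.d. and additive,
the red band (R670 ≈ 0.026) is proportionally very noisy, and NDVI — whose
sensitivity to R670 is large near saturation — inherits a per-sample
standard deviation an order of magnitude larger than the treatment-induced
NDVI shift. The higher-fertilizer group reliably shows higher mean NIR
reflectance (averaging across the plateau suppresses the noise), but a
one-way ANOVA on per-sample NDVI by treatment detects the effect only in a
minority of runs under these defaults. The acceptance script reports both
rates as it measures them.

## Problem sizes and numerics

The repeated-trial studies use 100 generated trials for outlier recovery
(21 samples × 601 wavelengths each after the QC trim) and 50 trials for
treatment recovery (40 samples each); these sizes give stable rate
estimates while keeping the whole suite fast on a single core. Numerical
tolerances in the oracle tests are 1e-12 for band-math and correlation
identities, 1e-10 for the F = t² identity, and 1e-8 for PCA
reconstruction. Ties and degenerate cases (zero variance, constant
groups, empty masks, zero denominators) are all handled by explicit
branches described above rather than by exception.

## Known limitations

* No radiometric calibration, dark-current or white-reference processing:
  inputs are assumed to be reflectance (or raw target plus reference in
  the same file).
* No smoothing, derivative spectra, continuum removal, or sub-nm support.
* No robust PCA or Mahalanobis/Hotelling outlier alternatives; the score
  z-rule is intentionally simple.
* No post-hoc tests, mixed models, or spatial-field correction in the
  association module; no machine-learning index selection.
* The ASD reader targets the documented subset described above; exotic or
  future file versions fail with an explicit format error.
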