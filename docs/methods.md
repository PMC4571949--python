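# Methods

## The α-band template

The package models the main visible absorbance band (α-band) of a visual
pigment with a log-normal template

A(λ) = exp[ −a x² (1 + b x + c x²) ],  x = log10(λ / λmax),

normalized so A(λmax) = 1. Default coefficients a = 380, b = 6.09,
c = 25.02 give the canonical rhodopsin band shape: FWHM ≈ 95 nm at
λmax = 480 nm, the long-wavelength limb steeper than the
short-wavelength limb, and strict unimodality (the quartic
a x²(1+bx+cx²) has a single stationary point at x = 0 for these values,
verified analytically via its derivative's discriminant and asserted on
a dense grid in the tests). The coefficients live in `TemplateParams`
as data and can be replaced from a YAML config, so alternative published
α-band parameterizations drop in without code changes. The β-band is
deliberately omitted: in fly R1–6 photoreceptors the UV peak of the
sensitivity spectrum is dominated by the sensitizing pigment, not a
pigment β-band, and the fitting windows exclude the UV region anyway.

Assumptions inherited from the template approach: band shape is
independent of λmax (shape invariance in x, asserted in the tests), and
measured sensitivity in the visible window is proportional to R-form
absorbance.

## Sensitivity fitting (R form)

Window: 420–620 nm by default. The lower edge excludes the sensitizing
pigment band (centered near 350 nm); the upper edge keeps the
long-wavelength tail where signal-to-noise is still useful. The source
measurements never state their window, so this is the package's choice
and it is configurable.

Procedure: windowed data are normalized to unit maximum (numerical
conditioning only — the reported amplitude is refit on the raw data, so
`scale_` is in data units and scale-equivariance holds exactly). At each
candidate λmax the optimal amplitude is the closed-form nonnegative
least-squares solution, reducing the problem to a 1-D SSE profile over
λmax. That profile is scanned at 1-nm resolution over the search
interval (400–650 nm default), ties broken toward the smaller λmax, and
the bracketing ±1 nm is refined with scipy's bounded scalar minimizer to
0.001 nm. No random initialization anywhere; fits are bit-reproducible.

λmax is carried at full precision and rounded to whole nm (half away
from zero) only in rendered tables.

Degenerate inputs: fewer than 5 window points raises
`InsufficientDataError`; constant data raise `DegenerateFitError`.

Known bias: with the default synthetic UV band (Gaussian at 350 nm,
σ = 25 nm, twice the α-band amplitude), ~4% of the UV peak leaks past
420 nm and pulls a noiseless fit ≈ 0.19 nm below truth. The pull is
common mode across genotypes fitted with the same window, so λmax
*shifts* — the scientifically reported quantity — are unaffected, and
whole-nm rounding recovers the generating value. Narrowing the window or
setting the UV ratio to zero removes the bias entirely.

## Difference-spectrum decomposition (M form)

DS(λ) = a_M·A(λ; λmax_M) − a_R·A(λ; λmax_R), with λmax_R fixed (by
default to the same genotype's fitted sensitivity value, mirroring the
measurement design in which electrophysiology pins the R state and MSP
constrains only the M state). Two independent nonnegative amplitudes are
fit rather than a single photoconversion fraction: complete
photoconversion is not guaranteed and the MSP path length is
uncalibrated, and unequal amplitudes absorb both. At each candidate
λmax_M the amplitudes come from a 2-column linear least squares; if one
turns negative it is clamped to zero, the other refit in closed form,
and the result flagged (`clamped`). The λmax_M search uses the same
scan-plus-refine machinery as the sensitivity fit. Window default
440–650 nm.

No baseline offset is fit by default (difference spectra are nominally
zero in the far tails); raw transmission input can be converted with
A = −log10 T via `transmission_to_absorbance`.

On noiseless model-generated difference spectra the decomposition is an
exact self-inversion (generating and fitted models coincide), which is
what the acceptance checks exercise at the published wild-type and
mutant (R, M) pairs.

## Shift reporting

Shift = mutant λmax − reference λmax, in nm; positive = red. Rendered
tables round to whole nm, half away from zero; machine-readable output
keeps full precision. Missing quantities (a genotype whose M state could
not be measured, a failed fit) render as NA, and a failed fit never
aborts a batch — each genotype is isolated and errors are logged.

## Synthetic data

The generators produce inputs with the *structure* the analysis assumes,
not realistic physiology:

* Sensitivity: UV Gaussian (center 350 nm, σ 25 nm, ratio 2 — the
  dominant-UV-peak regime of fly R1–6 recordings) + α-band + optional
  additive homoscedastic Gaussian noise, clipped at zero. Not modeled:
  photon-noise heteroscedasticity, lamp-line artifacts, energy-transfer
  spectra of the sensitizing pigment. Passing tests therefore show
  estimator correctness under the stated noise model, not robustness to
  every instrumental artifact.
* Difference spectra: the two-template model plus Gaussian noise — by
  construction the fitted model class, so noiseless recovery is exact.
* Alignments: root sequence uniform over 20 amino acids; per site a
  Poisson(branch length) number of substitution events, each replacing
  the residue with one of the other 19 uniformly. Expected p-distance at
  total divergence d is 1 − [1/20 + (19/20)e^(−20d/19)], used as the
  closed-form oracle. No rate heterogeneity or empirical exchange
  matrices — sufficient to produce cleanly supported clades, which is
  all the bootstrap checks need.
* Toy coordinates: a chromophore stub (Schiff-base nitrogen at the
  origin, carbons along −z) and residues on upper-hemisphere directions
  so each residue's constructed oxygen–nitrogen distance is exactly its
  minimum distance to the chromophore.

All generators are pure functions of (parameters, seed).

## Phylogeny stage

Input is an existing protein alignment; distances are gap-excluding
p-distances (the distance implicit in common alignment GUIs is not
specified anywhere reproducible, so the package documents its own
choice). NJ uses the standard Q-criterion with closed-form branch
lengths; negative lengths are clamped to zero with the deficit moved to
the sister branch, preserving the joined pair's path length. UPGMA uses
average linkage with node height = half the merge distance, so output is
exactly ultrametric. Ties in either criterion join the lexicographically
smallest label pair, making topologies deterministic. Bootstrap
resamples columns with replacement; supports attach to *splits*
(bipartitions for NJ, clades for UPGMA), so they survive outgroup
rerooting, and are invariant to taxon order. Tests cross-check NJ
against scikit-bio's implementation and a least-squares quartet brute
force, and UPGMA against a naive O(n³) average-linkage oracle.

## Pocket geometry

PDB files are parsed with biotite: fixed-column, first model,
first-listed altloc. Hydrogens are excluded by default (model and
crystal structures disagree on their placement); configurable. Side-chain
oxygens are identified by standard PDB atom names (OD1/OD2, OE1/OE2, OG,
OG1, OH), excluding backbone O/OXT. The published model-derived
distances for Rh1 (6.7–29.6 Å) come from coordinates that were never
deposited; they appear in this package only as documentation examples
and toy-generator inputs, never as test expectations about real
structures.

## Problem sizes and tolerances

The working grid is 300–700 nm at 1 nm (401 points), covering the UV
band through the M-form tail. Monte-Carlo bias checks use 100 replicates
at σ = 0.02 (sensitivity) and σ = 5% of DS peak-to-peak (MSP), with the
±0.5 nm / ±1 nm bounds asserted on the mean error. Bootstrap checks use
a 7-taxon tree with internal branches ≥ 0.3 and terminals 0.1
substitutions/site, 2000 columns, 100 replicates per method — deep
enough that every split is recovered in every replicate. λmax refinement
tolerance is 0.001 nm, two orders below the 0.1 nm recovery assertions
and five below tabulated precision.

## Known limitations

* Template-shape misspecification (real pigments deviating from the
  log-normal) propagates directly into λmax; only the template family is
  fit, by design.
* The sensitivity fit assumes the UV band is negligible inside the
  window; strongly blue-shifted pigments would need a narrower window or
  explicit two-component fitting, which is out of scope.
* p-distances are uncorrected; for deeply diverged sequences NJ branch
  lengths compress, though topology on the clean synthetic regime is
  unaffected.
* No photoequilibrium or M-decay modeling: amplitudes are free
  parameters, not photochemical fractions.
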