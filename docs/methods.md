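# Methods

This note documents the measurement models behind the synthetic-data
generators, the analysis conventions, the numerically delicate choices, and
what passing the test suite does and does not establish about real data.

## Dual-reporter flow cytometry

### Generative model

Each event is debris with probability `debris_fraction`, otherwise
transfected with probability `transfected_fraction`. Transfected cells draw
a reporter expression level `E ~ LogNormal(mu, sigma)` (arbitrary linear
instrument units). Channels read

```
RFP = rfp_gain · E · f_R + a_R          GFP = theta · gfp_gain · E · f_G + a_G
```

with `theta` the true per-transcript readthrough fraction (`theta = 1`
encodes the stop-free fusion control), `f` multiplicative lognormal
measurement noise with exact unit mean (`sigma_f^2 = ln(1 + cv^2)`,
`mu_f = -sigma_f^2/2` — chosen so the noise is unbiased on channel means,
which the ratio-of-means estimator relies on), and `a` additive Gaussian
autofluorescence clipped at zero. Untransfected cells and debris carry only
autofluorescence; debris scatter is drawn at 0.15× the cell scatter means
so it falls outside the scatter gate with high probability. Intensities are
simulated on a raw linear scale because the published inclusion thresholds
(900 / 100) are raw instrument values.

Default parameters (the `flow_base` block of `presets.yaml`): expression
`LogNormal(10.8, 0.5)` (mean ≈ 5.6 × 10⁴ AU), unit gains, RFP baseline
45 AU, GFP baseline 0.5 AU with s.d. 0.8, scatter 49 000 ± 8 000 (FSC) and
40 000 ± 9 000 (SSC), 8 % debris, 15 % measurement CV, 35 % transfection.
The GFP baseline sits ~90× below the RFP baseline, mirroring the 9×
asymmetry of the published inclusion thresholds; this matters because the
smallest encoded readthrough fraction (0.02 %) produces a mean GFP signal
of only ~11 AU, and a baseline comparable to that signal would bias the
estimator upward. With these defaults the residual autofluorescence bias is
about +5 % relative at theta = 2 × 10⁻⁴ and negligible above 10⁻³.

### Estimator

The default statistic is the ratio of channel means over included events,
normalized to the plate's fusion control; it remains well-defined when
per-cell GFP is near zero, where per-cell ratios are unstable. A
median-of-per-cell-ratios estimator is available for comparison. Scatter
bounds are inclusive ("between"), fluorescence thresholds strict ("above").
Optional background correction subtracts per-channel medians of an
untransfected sample before forming ratios; it is off by default because
the published inclusion rule already excludes untransfected events. Wells
with fewer than 100 included events are flagged low-quality, not dropped.
No spectral compensation is modeled or applied.

### FCS profile

Files are FCS3.0, one dataset, list mode, 32-bit float or unsigned-integer
data, both byte orders, no analysis segment. The reader honors
`$DATATYPE`, `$BYTEORD`, `$PnB` and resolves channels through a
role → `$PnN` map, listing available names on failure.

## Synthetic coding sequence

The studied gene's precursor is emulated as a 466-residue CDS (27-residue
signal peptide + 439-residue mature chain) of random sense codons with
fixed anchors: codon 82 CAG, codon 188 TGG, codon 427 CAA, so the three
clinical substitutions c.244C>T, c.564G>A and c.1279C>T create UAG, UGA and
UAA stops at the published codon positions. Codons 78–86 reproduce the
published p.Q82X mutagenesis-primer context, so the extracted 23-nt SCC for
that variant is a substring of a printed oligonucleotide; the other two
contexts use synthetic stop-free flanks. Truncation masses use either the
actual residue composition (average or monoisotopic tables) or a
configurable mean residue mass (110 Da default); N-glycosylation (~2–3 kDa
on the mature enzyme) is noted as a caveat, not modeled. Conventions
(precursor vs mature, i.e. minus the signal peptide) are explicit
parameters because published expected masses do not pin down a single
convention.

## Proximity imaging

### Scene model

Two channels over a 512 × 512 field at 0.1 µm/pixel: channel 0 holds
lysosome-like discs (diameters U(0.2, 0.3) µm — the small end of the
sub-700-nm lysosome range), channel 1 holds enzyme puncta (0.2 µm). The
punctum-to-nearest-disc edge distance follows a two-component mixture:

* **within** (probability `fraction_within_02um`, default 0.6): the punctum
  is luminal — placed inside a disc at center offset U(0.05 µm,
  r_disc + r_punctum − 0.06 µm), so punctum and disc genuinely overlap and
  the true edge distance is 0;
* **beyond**: the punctum sits at an edge gap U(0.44, 0.54) µm.

Each luminal punctum occupies a *distinct* disc, hence the default of 60
discs per field (one per expected luminal punctum at 100 puncta; also the
realistic lysosome density for a ~51 µm field of cultured cells). Puncta
keep a pairwise separation of ≥ 0.5–0.7 µm via a relaxation ladder so
neighboring puncta do not fuse optically. Rendering: antialiased discs,
Gaussian PSF (σ 0.8 px ≈ 0.19 µm FWHM), flat background (20 AU) plus a
linear gradient (10 AU), Poisson photon noise at 8 counts/AU. Ground truth
stores every centroid, radius and the realized nearest center/edge
distance; a test verifies these reproduce exactly from the stored geometry.

With this mixture the expected mean center-to-center distance is ≈ 0.35 µm
and the expected within-0.2 µm fraction is the preset value — the wild-type
study condition.

### Why the guard band and disc count look the way they do

The threshold stage marks foreground down to roughly 6 % of an object's
peak, so masks extend ~1 px beyond the geometric boundary and measured edge
gaps run ~0.10 ± 0.04 µm short (quantified on calibration pairs; at PSF
σ = 1 px the shortfall doubles). The beyond-component gap therefore starts
at 0.44 µm: no generated punctum sits close enough to the 0.2 µm
classification radius for mask dilation to flip its class. Likewise,
luminal puncta sharing one sub-micrometer lumen cannot be separated at
these optics; they would merge into single segmented objects and distort
the object-count-weighted within fraction — hence one luminal punctum per
disc. These are properties of the measurement chain, reproduced faithfully
rather than corrected away.

### Analysis chain

`normalize → rolling ball → Phansalkar → median → watershed → label →
distances`, all 2D (single plane):

* **Contrast normalization** maps the p-th/(100−p)-th percentiles to
  [0, 1]; the operation's general-purpose default is p = 0.35, but the
  proximity chain uses p = 0.02 because sub-micrometer organelles cover
  well under 1 % of the field — with p = 0.35 the upper percentile falls in
  the background noise band and every object saturates.
* **Rolling-ball background** (radius 50 px) is implemented as grayscale
  opening with a disc: exact for radii ≤ 20 px, and via block-mean
  downsampling + resampling for larger radii. The downsampled envelope is
  re-anchored to the noise floor (`median − 3 × 1.4826 · MAD` of the
  residuals) because block averaging suppresses the pixel noise the exact
  opening rides under; without the anchor the local threshold sees a
  near-zero background mean and floods with speckle. Exactness versus the
  classical paraboloid ball is not claimed.
* **Phansalkar threshold** (radius 15 px): foreground iff
  `v > m·(1 + p·e^(−q·m) + k·(s/r − 1))` with the published defaults
  k = 0.25, r = 0.5, p = 2, q = 10; local moments over a disc via
  FFT convolution with reflective boundaries.
* **Adaptive filtering** (radius 1 px) is a median filter over the 5-point
  cross — a documented stand-in for the named plugin, sufficient to remove
  the isolated speckle the threshold admits.
* **Watershed** markers are components surviving 5 single-pixel erosions;
  components that erode away are rescued whole (small organelles are never
  lost — at these object sizes the stage effectively reduces to connected
  components, splitting only larger fused structures).
* **Distances**: per source object, the nearest target by edge-to-edge
  distance (boundary pixels, 4-connectivity; intersecting objects get 0;
  ties break to the lowest label), with the centroid distance to that
  partner. Objects under 8 px (chain default; true masks are ~17–25 px) are
  dropped and counted. Cell "volume" normalization for per-cell intensity
  is 2D mask area — a documented deviation from volumetric normalization.

## Activity and densitometry

The standard curve is OLS with free intercept (the blank is a data point at
0 nmol). Negative back-calculated 4-MU amounts floor to zero with an
explicit flag. The specific-activity bookkeeping takes the
undiluted-equivalent protein mass in the reaction, so the dilution factor
enters the formula exactly once; reaction-volume terms cancel by
construction. The diluted wild-type reference load is a parameter
(`wt_reference_load_fraction`, default 0.01), not a hard-coded 1 %.
Activity presets encode the study conditions: wild-type untreated
100 mU/mg, p.Q82X 1.46 mU/mg (G418 maximum) and 3.65 mU/mg (dual
treatment, i.e. 3.65 % of wild type), p.W188X 0.88 and 1.19 mU/mg.

## Reproducibility conventions

Every generator takes an explicit integer seed and is bitwise reproducible;
multi-stage runs draw one child seed per stochastic stage from the run seed
and echo all parameters, seeds and input digests in the run report. The
acceptance script uses 10 replicate seeds per stochastic quantity, 10⁵–
2 × 10⁵ events per flow sample and ten 512 × 512 scenes — sizes at which
the estimator's Monte-Carlo error is well below the tolerances being
checked while a full run stays under a minute.

## What the synthetic tests do and do not show

The generators emulate the *measurement models* of the assays — mixture
structure, noise, gating, optics, calibration arithmetic — with known
truth, so the tests establish that the pipeline recovers truth through the
full chains under realistic noise. They do not emulate: spectral spillover
or compensation, cell-cycle/size correlations in expression, 3D organelle
structure and z-projection effects, chromatic aberration between channels,
saturation/quantization of real detectors, or blot nonlinearity
(densitometry starts from band-intensity tables by design). Agreement on
synthetic data therefore validates the computation, not instrument-specific
artifacts, which real deployments should assess with instrument controls.

## Known limitations

* The readthrough estimator inherits a small upward bias at very low theta
  from GFP-channel baseline signal; with the default model it is ~5 %
  relative at theta = 2 × 10⁻⁴. Background correction with an
  untransfected control removes it when needed.
* Edge-to-edge distances shorten by ~1 px of mask dilation per boundary;
  fractions-within at radii close to typical gap distances are sensitive to
  this (see the guard-band discussion above).
* 2D analysis of single planes throughout; no deconvolution, no
  colocalization coefficients, no statistical testing beyond mean ± s.d.
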