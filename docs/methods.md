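# Methods

`wpalign` straightens nanochannel kymographs of fluorescently labelled DNA.
A kymograph is an `m x n` matrix `I(x, y)`: row `y` is one camera frame of a
single confined molecule, column `x` is position along the channel.  Thermal
center-of-mass diffusion and local conformational fluctuations make the
molecule's intensity pattern wander and breathe from frame to frame, so a
naive time average blurs the sequence-dependent barcode.  Alignment warps
each frame horizontally so that intensity features are straight in time,
after which the column-wise time average is a low-noise consensus barcode.

## The alignment model

A *feature* is a complete, continuity-constrained trajectory of one bright
ridge or dark valley: a column `F(y)` for every row `y` with
`|F(y+1) - F(y)| <= k`.  The continuity bound `k` (default 2 px/frame)
reflects that between consecutive frames a feature moves diffusively; for a
molecule of length `L` (um) the bound is scaled from a 24-um reference via
`choose_k` — linearly (`k = k_ref * L_ref / L`, the default) or with the
square-root dependence that the center-of-mass diffusion argument
(`dL^2 ~ D t`, `D ~ 1/L`) strictly implies.  Both modes are provided because
the two scalings disagree; the discrepancy is documented, not resolved.

Detection proceeds in three steps:

1. **Pre-processing.** The image is smoothed with an anisotropic Gaussian
   (`sigma_h = 10` px along the channel, `sigma_v = 3` px along time), then a
   Laplacian-of-Gaussian (`sigma_log = 10` px) produces the response image
   `K`, positive in dark bands and negative in bright bands, rescaled so its
   positive part peaks at +1 and its negative part at -1.  The LoG is
   implemented as a discrete Laplacian of the Gaussian-filtered image; the
   `[1, -2, 1]` stencil is exactly zero-sum, so a constant image maps to an
   exactly zero response (the truncated analytic LoG kernel does not).
   Filters use reflective boundaries.  `K` is split into two nonnegative
   cost images in `[0, 1]` whose low values mark candidate features:
   `K_B = 1 + K` on bright (`K < 0`) pixels and `K_D = 1 - K` on dark
   (`K > 0`) pixels, barrier value 1 elsewhere.

2. **Path search.** The admissible-path graph has one node per pixel plus a
   source above row 0 and a sink below row m-1; pixel `(y, j)` connects to
   `(y+1, j')` for `|j' - j| <= k`, each edge weighted by the cost of the
   pixel it points to (sink edges weigh 1).  The graph is acyclic by
   construction, so the minimum-cost complete path is found by a row-wise
   dynamic program over the implicit graph (a sliding-window minimum per
   row); the graph is never materialised, which is what keeps the search
   linear in `m * n * (2k+1)`.  Ties break toward the smaller column index,
   applied per cell, so results are platform-independent.  The lower-cost of
   the bright and dark paths is the candidate feature; exact ties go to
   dark.  (Note that because the bright and dark parts of `K` are rescaled
   independently, a noiseless image gives both polarities an exact
   zero-cost ridge and the tie rule decides; with camera noise the deeper
   basin wins.)

3. **Distinctness.** A candidate is accepted as a feature only if
   (a) its height-normalised cost `cost/m` is below `theta`, and
   (b) its total column excursion `max F - min F` is at most
   `k * sqrt(m)`.  Test (b) is the whole-movie counterpart of the per-frame
   continuity bound: a genuine feature wanders diffusively, accumulating at
   most ~`step * sqrt(m)` of excursion, whereas a path that rides a broad
   featureless gap drifts far more.  Regions with no distinct feature are
   left untouched and recursion stops there.

An accepted feature is straightened by mapping, in every row, column `F(y)`
to the fixed column `c* = round(<F(y)>)` (its time-averaged — equilibrium —
position; rounding is half-away-from-zero) while the pixels left and right
of it stretch linearly to the region ends; each row is resampled at the
mapped coordinates with a natural cubic spline.  The image is then split at
`c*`, a margin of `w = 5` columns on each side of the split is excluded from
further search (`w` is half a typical 10-px raw feature width; the margins
and the feature itself are written through to the output unchanged), and
the procedure recurses left, then right, stopping when a region is narrower
than a typical feature (`2w`).  Because each accepted feature removes at
least `2w + 1` columns from further consideration, termination is
guaranteed, with at most `~n / (2w+1)` detections per sweep.

### Recursive search details

Three details matter for robustness; the exact cost construction and
acceptance rule are genuinely open design territory, and the choices below
are this package's own:

* **One global pre-processing, co-warped.** The filters run once on the
  whole kymograph.  When a feature is straightened, the response image `K`
  is resampled with the same per-row maps as the intensities, so subsequent
  regions search a response that is consistent with the current geometry.
  Re-filtering each sub-region instead would let reflective boundaries
  dominate regions narrower than the filter scale and would amplify the
  noise floor of featureless regions to full contrast.

* **Rank-equalised region costs.** Within each search region the bright
  (dark) cost of an on-polarity pixel is one minus the empirical CDF rank of
  its response strength among the region's on-polarity pixels; off-polarity
  pixels are barriers.  With amplitude-graded costs the exact minimum-cost
  path exploits a bad economy: hopping from a weak band to a strong one
  costs a fixed barrier crossing but pays a depth dividend on every
  subsequent frame, so for long movies "chimera" paths that switch bands
  mid-movie beat faithful single-band tracks and their warps tear the image
  apart.  Ranking makes every coherent ridge uniformly deep, so riding one
  ridge always beats hopping.  Ranks are invariant under monotone rescaling
  of the response, which also removes any global-versus-local rescaling
  ambiguity.  Under this construction `cost/m` is the mean contrast quantile
  along the path, giving `theta` an absolute meaning; the default
  `theta = 0.3` ("on average in the top 30% of the region's contrast")
  cleanly separates measured genuine tracks (<= 0.2) from incoherent paths
  (>= 0.4).  The affine `K_B`/`K_D` construction remains available as
  `preprocess.cost_images` and drives the standalone single-region detector.

* **Basin suppression.** A straightened feature's response basin spans about
  `sqrt(sigma_h^2 + sigma_log^2) ~ 15` px on each side — three times the
  split margin `w` — so after alignment the feature's own polarity is
  cleared from the co-warped response over that span.  Without this the
  search re-detects the same ridge's flank just outside the margin, wasting
  splits and shrinking the regions available to genuine neighbours.

### Convergence iteration

One recursive sweep is not a fixed point: straightening sharpens the image,
which lets a second sweep see and correct residual misalignment (re-running
it reduced the mean column variance by up to a third on some simulations).
`align_kymograph` therefore iterates the sweep (default at most 4 passes),
accepting a pass only if it lowers the mean column variance by more than 2%
relative; the first non-improving pass is discarded and iteration stops.
Alignment consequently never degrades an image, and aligning an
already-aligned kymograph returns it bitwise unchanged.  The per-row warp
maps of accepted passes are composed and reported (`row_maps`), which is
how simulation studies measure where any material point of the molecule
ended up.

## Quality metrics

For an aligned kymograph the *time trace* is the column mean
`<I(x)> = (1/m) sum_y I(x, y)`; residual misalignment and camera noise are
summarised by the column-wise population variance
`sigma^2(x) = (1/m) sum_y [I(x,y) - <I(x)>]^2` and its flat average
`<sigma^2(x)>` (population convention deliberately, not `1/(m-1)`).

The *information score* condenses a trace into the total self-information
of its peak/valley contrasts: with noise `s2` and regularisation
`chi >= 1` (default 1, keeping `ln(s2 + chi) >= 0`),

    IS = sum_k [ 1/2 ln(2 pi ln(s2 + chi)) + ln(|dI_k|)^2 / (2 ln(s2 + chi)) ]

in nats (a `base` option converts).  The squared-log reading treats each
contrast as a Gaussian variate in log intensity, so each term is a negative
log density; the alternative reading `ln(|dI|^2)` is noted but not
implemented.  `s2` is taken as `<sigma^2(x)>` of the aligned kymograph.  An
empty contrast list scores 0; a noise-free trace with `chi = 1` makes the
denominator vanish and the score is reported as the `+inf` sentinel.  The
score is additive and permutation-invariant over contrasts, and for fixed
noise strictly increasing in each contrast on `|dI| >= 1`; below 1 the
quadratic in `ln|dI|` turns around, so monotonicity statements (and the
property tests) are restricted to contrasts of at least one intensity unit.

The contrasts `|dI_k|` come from a robust extrema pass: the trace is
smoothed with a 1D Gaussian (default 2 px), interior peaks and valleys are
kept when their prominence clears half the noise scale
(`0.5 * sqrt(s2 + chi)` by default), trace endpoints join when they extend
the alternation by the same margin, same-type runs collapse to their most
extreme member, and the absolute differences of the surviving alternating
values are returned.  The smoothing width and prominence floor are design
choices of this package; both are exposed in configuration and logged in
reports.

## The synthetic-data generator

All validation runs on simulated kymographs with known ground truth; no
external data is needed.  The generator emulates, qualitatively, what a
melt-mapped molecule looks like in a nanochannel:

* **Barcode** (`BarcodeSpec`): a 170-px field holding a molecule that spans
  the field minus 32-px end margins (~17 um at 0.16 um/px), stepping
  logistically (2-px scale) from background level 10 to baseline 100 at the
  molecule ends; on the molecule, a smooth random undulation (sd 15,
  correlation 20 px) — melt-map barcodes are continuous profiles, and the
  undulation gives every column a nonzero gradient so that thermal motion,
  not camera noise, dominates the raw column variance, the regime alignment
  addresses; plus Gaussian bands of FWHM 10 px with amplitudes uniform in
  (50, 100).  Band centers keep at least 45 px from each other and from the
  end steps: the detection filters have a combined scale of
  `sigma_r ~ 15` px, and two like-polarity structures closer than `~3
  sigma_r` merge into one ridge with no opposite-polarity barrier between
  them — they are then one feature, not two, at the scale the method
  operates on.  With those clearances a 170-px field fits one interior band
  (the default), giving 3-4 alignment anchors per molecule including the
  end steps; wider fields fit proportionally more.  The 32-px margins keep
  both detection-scale lobes of each end step inside the field even at the
  walk's excursion tails.

* **Dynamics** (`DynamicsSpec`): frame `t` samples the barcode at
  `phi_t(x) = x + offset_t + d_t(x)` (cubic interpolation, additive
  Gaussian camera noise of sd 5).  `offset_t` is a Gaussian random walk
  (step sd 0.5 px/frame — over 200 frames the molecule wanders by roughly
  +-7 px, about a micron, a typical band wander for confined molecules on
  these timescales).
  `d_t` is a spatially smooth field (stationary sd 1 px, correlation 30 px)
  evolving as a mean-reverting AR(1) process with a 20-frame relaxation
  time (~2 s at 10 fps): conformational modes decorrelate over seconds, and
  a field white in time would jitter faster than any method that smooths
  over `sigma_v = 3` frames could track — it would violate the same
  diffusion picture that motivates the continuity bound.  The field's slope
  is capped at 0.9 so every warp is strictly increasing.  All draws are
  pure functions of the seeds.

* **Ground truth** (`SyntheticTruth`): every warp and every band's
  per-frame image position are stored.  `alignment_error` inverts the
  aligner's composed row maps to measure (a) each band's RMS deviation from
  constancy after alignment, (b) the raw/aligned mean-variance reduction
  factor, and (c) the fraction of true bands matched by a detected feature
  within one feature width.

What the simulations do *not* model: photobleaching, shot-noise intensity
dependence, molecule rotation or out-of-focus drift, DNA breakage or
molecules entering/leaving the field (explicitly out of scope for
alignment), and physically calibrated polymer dynamics (no Rouse/Zimm
modes).  Passing tests therefore demonstrate correct behaviour under
diffusive-plus-elastic planar motion with additive noise, not performance
on every experimental pathology.

## Problem sizes and measured behaviour

The test suite validates, among others: exact agreement of the dynamic
program with exhaustive path enumeration (500 random cost images up to 8x8,
`k` in {0, 1, 2}) and with an independent sparse-graph shortest-path
solver; continuity/completeness of every detected feature across 100
random simulations; on 10 seeded default simulations (200x170), a mean
variance-reduction factor of at least 4 with every true band held to 1.5 px
RMS on average; flatness of the aligned variance across movie lengths of
20-200 frames (all pairs within two standard errors, no Mann-Kendall trend
at alpha = 0.05); and identity behaviour on straight or too-narrow inputs.
`scripts/acceptance.py` re-measures the time scaling on widths 200-10000 px
at 200 frames (two decades, ~1.5 min total); the fitted power-law exponent
lands near 1.07, consistent with linear scaling.  These sizes keep the full
validation suite within a few minutes on one CPU while still spanning the
regimes the claims are about.

## Known limitations

* Feature positions are integer columns and the equilibrium position is a
  rounded mean, so each anchor carries up to half a pixel of quantisation;
  combined with temporal smoothing over ~3 frames, the intrinsic tracking
  floor is roughly half a pixel RMS per feature.  Sharp structures (the
  molecule ends) convert that into the dominant share of residual variance.
* Content outside the outermost aligned features is pinned to the image
  edges; for a pre-cropped kymograph that zone is static background, but a
  field-filling barcode without visible molecule ends would retain drift
  there.
* Bands closer than ~3x the filter scale are one feature to the method;
  aligning them as a unit is correct behaviour, but their individual
  centers are then only constrained by interpolation.
* `theta` and the wander bound are this package's distinctness rule; data
  with very different contrast statistics may need the exposed parameters
  adjusted.
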