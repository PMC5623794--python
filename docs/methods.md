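# Methods

This note documents the models, parameters and numerical choices behind
`radiopos`, and what the synthetic data does and does not establish.

## Pipeline overview

Every input radiograph passes through four stages (all deterministic for a
fixed input and configuration):

1. **Preprocessing** (`io_prep`): linear histogram stretch onto
   [0, 65535], then a 5×5 median filter, then optional CLAHE.
2. **Signature extraction** (`freq_signature`): normalized centred 2D FFT
   magnitude, reduced to a 1D curve over the lowest radial-frequency band.
3. **Classification** (`classifier`): nearest reference curve by RMS
   difference, with a cosine tie-break for near-ties.
4. **Localization + annotation** (`template_match`, `phantom_atlas`):
   sliding-window matrix-product and Pearson score maps over the
   whole-body template; the intersection of their argmax rectangles is
   labelled with the overlapping atlas regions.

## Preprocessing

* Stretch: `out = round(65535·(f − A)/(B − A))`, `A = min f`, `B = max f`.
  Output is always 16-bit; all later stages assume that scale. A constant
  image maps to all zeros with a warning (the stretch is undefined).
  Rounding is round-half-up, which makes the chain bit-reproducible.
* The stretch cancels any positive affine exposure change exactly, as long
  as no pixel clips. Saturated pixels or salt-and-pepper impulses pin
  A and B to the range limits and reduce the stretch to the identity; the
  median filter then removes the impulses but the gain remains. This
  interaction is why reference (library) images should be acquired at
  nominal exposure — see *Synthetic data* below.
* Median filter: centred `w×w` window, `w = 5` by default, borders by edge
  replication (preserves the constant-image fixed point used in tests);
  `w` must be odd and fit in the image, so images must be at least 5×5.
* CLAHE (off by default): clip limit 0.01, 8×8 tile grid. The method name
  is the contract; the parameters are package conventions exposed in the
  call signature.

## Frequency signature

* Spectrum: `|F(u,v)|` with the 1/(MN) normalization, zero frequency
  centred, so the DC cell equals the image mean.
* Radial frequency per cell: `r(u,v) = sqrt((u/M)² + (v/N)²)` in
  cycles/pixel — signatures of images of different sizes live on a common
  physical-frequency axis.
* Curve: cells with `0 < r ≤ fraction·r_max` (default fraction 0.02, the
  "lowest 2 %" band; `r_max` is the grid's largest radial frequency,
  ≈ 0.707) are binned into `n_bins = 256` equal-width rings; each entry is
  the ring's mean magnitude. Empty rings are linearly interpolated from
  populated neighbours (endpoints replicated) so the curve length is
  always `n_bins`. The DC cell is excluded so exposure offset does not
  dominate similarity. AUC is the trapezoidal integral of the curve.
* Practical resolution limit: at fraction 0.02 the band only contains
  non-DC cells for images of side ≳ 71 pixels; smaller inputs need a
  larger fraction (a validation error says so). Fewer than two populated
  rings is rejected.
* Butterworth band-pass: radial gain
  `H(r) = [1/(1+(low/r)^{2k})]·[1/(1+(r/high)^{2k})]`, order `k = 2` by
  default. The band is open at zero, so the DC term is always removed;
  the edges are special-cased: `low = 0` disables the high-pass roll-off
  and `high = 0.5` (Nyquist) disables the low-pass roll-off, making
  `(0, 0.5]` an exact all-pass-above-DC. Output is clipped to [0, 65535]
  and rounded. Default texture bands: lungs (0.02, 0.15], trabeculae
  (0.05, 0.25] — conventions of this package, exposed in `BandSpec`.

## Classification

* Scores: `a(f, F) = sqrt(Σ(fᵢ−Fᵢ)²/n)` (a metric up to the 1/√n factor)
  and `cos θ = f·F/(‖f‖‖F‖)`.
* Scale convention: the decision threshold (default 0.02) is only
  meaningful on a fixed scale, so before computing `a` both curves are
  divided by the library's global norm — the maximum amplitude over all
  six reference curves, stored in the library file. Cosines are
  scale-free and use raw curves.
* Decision rule: rank the six `a` ascending (ties broken by canonical
  position order). If both of the two smallest values are below the
  threshold, the one of the two with the larger cosine wins
  (`decided_by = cosine_tiebreak`); otherwise the smallest `a` wins. An
  alternative reading — tie-break when the *gap* between the top two is
  below the threshold — is available as `tiebreak_mode="gap_below"`.
* The library requires exactly the six canonical positions; each reference
  curve is the mean of its members' curves, computed after preprocessing.

## Localization

* The single-offset score formulas are operationalized as maps over every
  valid top-left offset, because a maximum requires a search domain:
  `M(o) = Σ I·W_o / Σ I²` and `R(o)` the Pearson correlation of I with
  window `W_o`.
* Complementarity: R is invariant to affine intensity changes of either
  image; M is not, but rewards absolute intensity agreement. They fail
  differently, so the result is the intersection of the two argmax
  rectangles, with the R rectangle as recorded fallback when disjoint.
* Numerics: window sums use integral images over integer pixels — every
  partial sum is an exactly representable float64 integer, so
  `k·Σw² − (Σw)²` is exactly zero for flat windows and the zero-variance
  convention `r = 0` triggers exactly. Cross-correlations use FFT
  convolution; `r` is clipped to [−1, 1]. Argmax ties break at the first
  occurrence in row-major order. A constant input gets `r = 0` everywhere;
  an all-zero input is rejected (M undefined).
* Both images are downscaled by the same bilinear factor (default 0.25,
  with Gaussian pre-smoothing) before the sweep; boxes are reported in
  full-resolution template pixels. Downscaled inputs below 8×8 are
  rejected.
* M can exceed 1 at a misaligned window that is brighter than the input —
  on low-contrast templates its argmax may sit away from the true offset
  even for exact crops. Exact-recovery tests therefore use a high-contrast
  two-level pattern whose window variance is comparable to its squared
  mean; the R map does not have this failure mode, which is what the
  fallback rule exploits.

## Atlas conventions

* Region configs store corners the way they are written on the template:
  (column, row) pairs, 1-based inclusive; all internal arithmetic is
  0-based, row-major, half-open `(row0, col0, rows, cols)`. The default
  template is 2000×800 pixels for a 165 cm body.
* Annotation returns every region intersecting the matched box with
  overlap fraction |intersection|/|box|, by exact integer rectangle
  arithmetic. Regions may overlap each other (e.g. a head box and a lung
  box sharing a band of rows); overlapping definitions are kept as given.
* Stitching of part images: stretch, bilinear rescale, paste; overlapping
  pixels take the per-pixel mean of contributors (symmetric and
  order-independent), untouched canvas stays 0.

## Synthetic data

The generator stands in for phantom radiographs that are not
distributable. It renders a body-shaped canvas with six zones whose
spectral content mirrors what each body part contributes: a bright smooth
skull ellipse; two dark lung fields filled with band-limited (0.02–0.12
cycles/pixel) texture under a bright diaphragm dome; periodic vertebral
blocks; a thin wide pelvic ring with hip sockets; two knee rods with
condyles and fine (0.15–0.38) trabecular grain; and a comb of thin limb
bones whose periodic structure lies above the low-frequency band, keeping
the limb signature's curve and AUC far below the lungs'.

Design points:

* Each zone's structure is inset by ~13 % of its box. Since the magnitude
  spectrum is translation-invariant, a crop window jittered by up to 10 %
  sees the same structure merely shifted, and a position's signature is
  stable under framing variation.
* Dataset crops: per-position zone crops with uniform framing jitter
  (≤ 10 % of zone size), multiplicative exposure gain (default 0.8–1.2),
  Gaussian noise (default σ = 5 % of the 16-bit range) and salt-and-pepper
  impulses (default fraction 0.001), all reproducible from
  (seed, position, index).
* Splits: the library split (first 10 indices per position) emulates
  *reference* acquisitions — nominal gain 1 and no framing jitter, as
  reference curves are averaged from repeat exposures of the same view in
  a fixed coordinate frame — while the evaluation split carries the full
  clinical variability. Detector noise and impulses affect both. This
  matters because impulses pin the stretch range (see *Preprocessing*):
  with exposure gain leaking into evaluation curves, reference curves
  built from gain-varied images would smear the library and the
  between/within separation of the six curves would degrade by an order
  of magnitude.
* Default problem sizes: the shipped-scale atlas is 2000×800; tests that
  only need structure use a 500×200 or 250×100 canvas. The default study
  (also used by `scripts/acceptance.py`) is 30 images per position — 10
  library + 20 evaluation — which keeps a full end-to-end run in the tens
  of seconds on one CPU.

What the generator does **not** emulate: physical X-ray attenuation,
scatter, detector MTF, anatomical variability between patients, rotation
or out-of-plane projection changes, and non-standard radiography.
Passing tests on this data show that the pipeline's operators interact
correctly and that the six synthetic zones are separable under the stated
noise/exposure/framing conditions; they do not quantify accuracy on
clinical images.

## Known limitations

* No rejection class: an out-of-library position is forcibly assigned one
  of the six labels.
* Translation-only matching: no rotation or scale search; a rotated or
  strongly magnified exposure will localize poorly.
* The matrix-product map's brightness bias (above) means the intersection
  box can shrink when M's argmax drifts; the fallback and the IoU-based
  evaluation bound, but do not eliminate, the effect.
* DICOM support reads pixel data and BitsStored only — no modality/VOI
  LUTs, no MONOCHROME1 inversion.
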