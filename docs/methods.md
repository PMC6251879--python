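# Methods

This document records the computational model, the fixed parameters, and the
design decisions behind `autofoci`. Equation numbers refer to the formulas
below, all implemented in the package.

## Image model

A *field* is one microscope position: a DAPI page plus five z-planes per
marker channel (red = 53BP1, green = γH2AX), 8-bit. A *cell* is a
120 × 120 px crop around one segmented nucleus with one best focal plane per
channel. All downstream statistics (`I_nucl`, `I_STD`, DAPI sum) are computed
over the nucleus mask of the crop.

## Preprocessing

- **Segmentation** — Otsu threshold on a smoothed DAPI image,
  watershed-separated, border objects and sub-minimum areas removed.
- **Best plane** — per channel, the z-plane maximizing the ratio of the mean
  Sobel gradient magnitude to the mean intensity inside the nucleus. The
  ratio makes the choice invariant under multiplicative intensity scaling;
  ties break to the lowest plane index.
- **G0/G1 gating** — cells are excluded when their DAPI sum deviates from the
  sample median by more than `k_mad = 2.5` robust standard deviations
  (S/G2, verdict `excluded_dapi`) or their mean nuclear γH2AX does
  (pan-nuclear staining of dying cells, verdict `excluded_gamma`). Samples
  with fewer than 10 cells are left ungated rather than gated on noise.

## Detection

Candidate seeds are strict local maxima within a Euclidean radius of 3 px
inside the nucleus; a connected plateau of equal maxima contributes exactly
one representative. Each seed grows to the 8-connected region of pixels at or
above **half the seed intensity**, floored at **1.1 × I_nucl** of the
channel; brighter seeds claim pixels first so objects are disjoint. Objects
smaller than 3 px are discarded.

## Scoring (the object evaluation parameter)

Per channel and object:

    C      = 1 / Σ_i r_i² I_i                      (Eq. 1, compactness)
    OEP_ch = (I_TH / I_nucl) · I_LC · C            (Eq. 2)

with `r_i` the distance of pixel *i* from the intensity-weighted centroid,
`I_TH` the mean of the three brightest object pixels in the white top-hat
image (disc of diameter 10 px), and `I_LC` the same statistic in the
local-curvature image — the convolution with the fixed, unnormalized 5 × 5
Laplacian-of-Gaussian-like kernel

    -2  -4  -4  -4  -2
    -4   0   8   0  -4
    -4   8  32   8  -4
    -4   0   8   0  -4
    -2  -4  -4  -4  -2

(centre 32, sum 16). A negative `I_LC` (anti-blob) is clamped to zero. The
degenerate compactness of single-pixel objects is capped at the largest
finite compactness of the same cell. The channels are combined with the
per-cell weight

    w   = I_STDred / I_STDgreen                    (Eq. 3)
    OEP = OEP_red^w · OEP_green^(1/w)              (Eq. 4)

so the channel with the crisper staining carries more weight, and because
genuine foci colocalize while speckles are channel-independent, the product
collapses single-channel signals. Eq. 2 and 4 make the score invariant under
positive multiplicative intensity scaling (on un-quantized inputs), verified
by test.

## Threshold estimation

The log10 scores of all objects in a sample are bimodal: a background mode
and a foci mode with a transition valley. The starting threshold is the mean
of up to three independent estimators of the transition point, each
restricted to the interval between the two relevant histogram modes (modes
below 2% of the global maximum are ignored; in samples with an intermediate
coincidence population, the lower bracket edge is the rightmost qualifying
mode left of the foci mode):

1. **Kernel-density valley** — minimum of a Gaussian KDE between the modes.
2. **Gaussian-mixture intersection** — posterior crossing of a two-component
   mixture whose means are initialized at the two density modes; without the
   anchoring, EM on heavily unbalanced samples splits the background mode
   instead of separating background from foci.
3. **Valley-emphasis Otsu** — Otsu's between-class variance weighted by
   (1 − p) of the candidate bin, evaluated over the bracketed sample; the
   weight pulls the optimum into the sparse valley rather than the flank of
   the larger mode.

An estimate is kept only if it lies inside the bracket **and** its KDE
density is at most half the smaller mode height — a direct check that the
estimator landed in the valley. If no estimator survives, the sample is
rejected (`NoThresholdError`); the CLI maps this to exit code 3.

### Rater-in-the-loop refinement

Starting from the automated threshold, each iteration shows the rater the
four **not-yet-rated** objects whose log-scores are closest to the current
threshold; given the fraction `f` of them judged foci, the threshold moves by
`−step · (f − 0.5) · 2`, with the step decaying by 0.8 per iteration and
floored at one histogram bin width (score range / 60). The loop converges
when the standard deviation of the last six foci-per-cell values is below 5%
of their mean; the reported count is the mean of those six. Each object is
shown at most once (the pool resets only when exhausted): with re-showing
allowed, a deterministic rater that splits 2-of-4 on the first probe freezes
the threshold on a single four-object sample while the convergence rule is
trivially satisfied — rating each object once matches real practice and lets
successive probes sample the neighbourhood.

## Quality gate

A sample is analyzed only if (a) the mean per-cell Pearson correlation of the
two marker channels exceeds 0.4 — weak or non-colocalized staining fails
here — and (b) the smoothed score histogram has two modes with a valley at
least 10% below the smaller mode — high background that swallows the foci
mode fails here. Failures carry machine-readable reasons
(`pearson_below_threshold`, `no_histogram_minimum`).

## Repair model

DSB induction is linear in dose with 20 foci per cell per Gy, so 12 mGy
induces 0.24 foci per cell and 0.3 foci per cell (the upper bound of the
spontaneous level in untreated cells) corresponds to 15 mGy. Repair
efficiency after dose *D* is the persisting fraction
`(irradiated − control) / induced_foci(D)`; a negative difference is flagged
rather than silently clipped.

## Synthetic generator

`autofoci.synthetic` renders fields with full ground truth and is itself part
of the validated surface. The frozen default regime —
520 × 390 px fields, 6 nuclei of radius 28 ± 2 px, foci of amplitude
200 × U(0.8, 1.2) and σ 1.5 px, background speckles at 15 × the foci rate
with amplitude fraction U(0.12, 0.22) and σ fraction U(1.3, 1.7), marker
background 25, Gaussian noise σ 1.5, five z-planes at defocus
σ ∈ {0, 1.5, 3, 4.5, 6} — was chosen so that the physics of the detector are
actually exercised:

- the **noise floor margin** (1.1 × I_nucl − background ≈ 2.5) exceeds the
  noise σ, so the growth floor is meaningful rather than noise-triggered;
- **speckles are dimmer and more diffuse** than foci by enough that even
  overlapping speckles stay below the half-maximum cut of a focus — at
  larger speckle amplitudes adjacent speckles fuse into large diffuse
  objects that destroy the compactness term of nearby genuine foci;
- the **nucleus radius** makes planted objects resolvable at the 3 px
  local-maximum separation at realistic per-cell object counts.

The optional `artifact_rate` knob plants bright, focus-like signals in a
single random channel (dust, debris, unspecific binding) — the failure mode
the two-channel combination exists to solve — and is used by the
scorer-ordering test, where all scorers are otherwise perfect.

## Problem sizes and runtimes

- Oracle suites: ≥ 100 random ≤ 32 × 32 fixtures per primitive, ~1 min.
- Parameter recovery: four conditions (0.3–2 planted foci per cell, speckle
  rate 15 × the foci rate), 40 fields (~200–210 gated cells) each, fixed
  a-priori seed blocks; automated counts land within 15% of planted truth,
  rater-assisted within 10%; ~80 s total.
- The full test suite runs in ~3 min on one CPU; the acceptance script in
  under a second.

## Limitations

- The generator is a stylized model (Gaussian blobs, isotropic defocus,
  uniform backgrounds); absolute error rates on real micrographs will
  differ even though the algorithmic contracts are exercised.
- The start-threshold estimators assume an expressed bimodality; very small
  samples (≲ 200 objects) are often rejected rather than thresholded.
- G0/G1 gating is a robust-statistics heuristic on DAPI/γH2AX summaries, not
  a cell-cycle classifier.
- The 8-bit quantized path breaks exact scale invariance of the score, as on
  any real detector.
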