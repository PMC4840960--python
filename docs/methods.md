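# Methods

## The assay model

`myeliscreen` implements the analytics of a phenotypic myelination assay on
mixed embryonic cortical co-cultures. The biological readout is a
morphology change of oligodendrocytes (OLs): pre-myelinating OLs show
diffuse, branched MBP staining, while OLs initiating axon ensheathment show
condensed, straight, aligned MBP fibers. Three channels are acquired per
field — MBP, Olig2 (OL-lineage nuclei) and DAPI (all nuclei) — at 16-bit
depth; the native acquisition raster is 2560×2160 at 10×, and all analysis
here is resolution-agnostic (parameters are stated at the 512×512 test
scale; lengths are reported in pixels, with an optional µm conversion via
`pixel_size_um`, since the acquisition's pixel pitch is configurable, not
assumed).

## Per-field quantification

**Nuclei.** Gaussian smoothing (σ = 2 px) → global Otsu threshold →
distance-transform watershed with a minimum seed separation (7 px) →
area gate (20–4000 px). The published assay delegated this step to a
commercial toolbox without stating the algorithm, so this standard,
fully-parameterized chain is the package's own documented choice. An
all-zero raster yields an empty set, not an error.

**Olig2⁺ gating.** A nucleus is Olig2⁺ when the mean Olig2 intensity in a
small disc (radius 2.5 px) at its centroid exceeds 2.0× the median
non-nuclear background. Fold-over-background keeps the gate
exposure-invariant across preparations; the centroid disc is used because a
nuclear marker is brightest at the nucleus centre and — unlike a mask-wide
mean — is insensitive to bleed-through from a bright neighbouring nucleus
at the shared mask boundary (at the default packing distance the nuclear
blob of a neighbour still reaches the mask edge but not the centroid).

**MBP score.** `area(mask) × mean intensity in mask / N(Olig2⁺)` with the
mask strictly above an Otsu (default), fixed, or quantile threshold.
Within-field Otsu is the default; fixed-threshold mode exists for
cross-field comparability studies. In the purified-OPC differentiation
variant the denominator is the DAPI count and no fiber detection runs.

**Fiber score.** The fiber detector makes "continuous straight lines"
operational as: multiscale Sato tubeness filter (σ ∈ {1, 2} px) → binarize
at 15 % of the peak ridge response within the MBP mask → skeletonize →
decompose the skeleton at branch points into simple paths (orthogonal steps
count 1, diagonal √2) → keep paths with length ≥ 20 px and straightness
(end-to-end / path length) ≥ 0.8. Each kept fiber contributes
`length × mean raw intensity along its skeleton` (default weighting; a
`length_only` mode preserves the alternative reading in which fiber length
is unweighted), summed and divided by N(Olig2⁺). Branch decomposition means
a branched diffuse arbor contributes only short sub-segments, which the
length gate then removes — this is what makes the detector specific to the
condensed fibrous morphology. Fields with no Olig2⁺ nuclei are marked
unusable and excluded from aggregation rather than scored 0, to avoid
deflating condition means.

## Plate analytics

Each condition is screened in duplicate wells × 4 fields; the ≤ 8 usable
fields are averaged unweighted (mean ± SEM). %DAPT normalization
(`100·(x − μ_DMSO)/(μ_DAPT − μ_DMSO)`) is computed on condition means
against same-plate control means only, and never re-averaged afterwards.
Plate QC reports the Z′-factor (on per-well mean myelination), the DMSO
mean + 3 SD line, and the DAPT/DMSO fiber-score/MBP-score ratio; a plate
passes when that ratio clears the lower window edge (1.3 − 0.2 = 1.1 —
only the lower edge is enforced, since a high ratio indicates a *better*
window, and 1.3 is the stated cutoff with ±0.2 read as its tolerance) and
the DAPT mean clears the 3-SD line. Condition-vs-control statistics:
one-way ANOVA with Dunnett (multivariate-t, via `scipy.stats.dunnett`) or
Bonferroni post hoc tests, or plain t-tests.

## Hit cascade

1. Primary: at **either** screened concentration, %DAPT myelination > 50
   **or** fiber-score/MBP-score > 1.5. The OR across concentrations is a
   documented choice (screening at two concentrations exists to reduce
   false negatives); the quotient criterion uses raw condition-level
   quotients by default (`use_normalized_fiber_mbp` preserves the
   normalized reading). Ties exactly at a threshold fail (strict
   inequalities).
2. Olig2-depletion gate: Olig2⁺ count > 25 % of the DAPT Olig2⁺ count.
3. Anti-proliferation gate: DAPI/Olig2⁺ nuclei ratio ≤ 40.
4. Morphology: deliberately semi-automated. Refined hits are flagged
   pending visual review; an operator decision map resolves the flag. The
   cascade never auto-passes this criterion.
5. Confirmation: ≥ 2 independent dose–response experiments must fit a 4PL
   curve with R² ≥ 0.8, convergence, and positive span; the mean EC₅₀ over
   passing fits ranks the hit.

The 4PL fit is unconstrained nonlinear least squares on log₁₀ dose
(relative EC₅₀ = inflection), self-started at bottom = min, top = max,
log EC₅₀ = median log dose, hill = 1; flat responses raise a no-fit error
rather than returning a degenerate curve.

## Synthetic data: what it emulates and what it does not

The generator renders nuclei as 2-D Gaussians (σ = 4 px, clipped at 3σ,
minimum spacing 12 px, rejection-sampled with bounded retries), Olig2⁺
nuclei as bright blobs in the Olig2 channel, diffuse OLs as five superposed
soft-edged discs, and fibers as constant-width (~2.5 px) anti-aliased
polylines with optional sinusoidal waviness (default 0, so straightness
filtering is exactly testable). Rendering is integer-quantized before a
constant background (100) plus Gaussian noise (σ = 10) is added, and each
field's RNG stream derives from (seed, plate, well, field), so identical
seeds give bit-identical images. Ground truth carries every planted
quantity and the closed-form expected scores: the fiber score applied to
the planted polylines, and the MBP score applied to the noiseless footprint
(total planted flux — which is why rendered structures have compact
soft edges rather than long Gaussian tails: the planted flux is then
recoverable by thresholding).

Default field conditions (512×512): 150 nuclei, 22 % Olig2⁺ (the measured
OPC/OL share of the co-cultures), 8 diffuse + 6 fibrous OLs, 3 fibers/OL of
length 30–90 px and intensity 800–1200. The positive control multiplies
fiber density by 2.0 and halves the Olig2⁺ count (the control's known
pro-differentiation/anti-proliferation behaviour); the MBP score couples to
the fiber-density multiplier m as 1 + 0.25(m − 1), which reproduces the
assay's control behaviour (raw DAPT fiber/MBP quotient > 1.5; DAPT/DMSO
quotient ratio ≈ 1.6). Planted hits scale fiber density by
`1 + (effect − 1)·Hill(c; EC₅₀, slope)`.

Screens simulate at two fidelities. In image mode every field is rendered
and scored by the image pipeline; this is used for small end-to-end runs
(the test suite renders a miniature screen at 256×256). In score mode,
per-field scores are drawn from the same statistical field model
(multipliers × multiplicative field noise, CV 10 %; Poisson counts), which
is what makes the library-scale runs (727 compounds × 2 concentrations ×
8 fields) take seconds; the planted truth is identical in both modes. The
package's library-scale results therefore exercise the plate analytics and
cascade end-to-end, while the image pipeline's fidelity is established
separately against ground truth at field scale.

The generator deliberately omits: optics (PSF, spectral bleed-through),
vignetting and photobleaching, the axon (SMI 31/32) channel, spatially
correlated background, and plate-position effects. Passing tests therefore
demonstrate correctness of the analytics under a clean but non-trivial
noise model, not robustness to every real-microscope artifact.

## Numerical choices and tolerances

- Count recovery: median |relative error| ≤ 5 % over a 20-field density ×
  noise grid (observed: exact for Olig2⁺, ≈0.3 % for DAPI).
- Fiber length: single planted fibers recovered within 10 % at 0–90°
  orientations (skeletonization bias is ±2–9 px on a 100 px fiber).
- Field scores: MBP and fiber scores within 15 % of planted truth at
  default noise; diffuse-only fields score ≤ 5 % of matched fibrous fields.
- EC₅₀: noiseless recovery exact to 10⁻⁴ relative over EC₅₀ ∈ {0.01, …,
  10} µM × hill ∈ {0.5, 1, 2}; at 5 %-of-range noise the median relative
  error is ≤ 15 % when the dilution series brackets the potency (confirmation
  experiments use ten 3-fold dilutions; a series whose top dose does not
  saturate the curve leaves the upper asymptote — and hence EC₅₀ — poorly
  determined, which is a property of the design, not the fitter).
- Z′ uses sample SDs; degenerate control separation returns −∞ with a
  reason rather than raising.
- Problem sizes: the library-scale screen runs at 727 compounds in score
  mode; rendered screens in tests use 2–12 compounds at 256×256 with
  proportionally scaled densities.

## Known limitations

- Criterion 4 (morphology review) only flags; there is no automated
  morphology classifier.
- Fibers crossing other structures are split at skeleton branch points;
  sub-segments shorter than the length gate are lost, so extremely dense
  fiber mats undercount slightly.
- The score-mode field model draws fiber and MBP scores independently
  (beyond their shared multiplier); real fields correlate them through the
  shared OL population.
- No inter-plate batch correction (B-score, LOESS) is provided; the assay
  design normalizes per plate.
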