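# Methods

This note documents the models, conventions, parameter choices and known
limitations of `cellwarp`, in the spirit of a methods section a user could
cite when describing an analysis run.

## Registration model

### Forces

The registration is an optical-flow-style fixed-point iteration. Given the
moving image resampled under the current field (*m*) and the fixed target
image (*f*), the per-pixel displacement force is

    u = (m − f) ∇f / (α²(m − f)² + |∇f|²)
      + w · (m_mask − f_mask) ∇f_mask / (α²(m_mask − f_mask)² + |∇f_mask|²)

Both terms have the form x·y/(x² + y²) per component pair, whose supremum is
1/2, so with α = 1 the combined update magnitude never exceeds 1 pixel per
iteration. Wherever a numerator or denominator vanishes the term is defined
as 0 (the 0/0 case in flat, matched regions). ∇f is the central-difference
gradient of the target with replicated borders. ∇f_mask is the gradient of
the *signed* distance to the target-mask boundary (positive inside,
negative outside, zero on boundary pixels), unit-normalized so the mask
force obeys the same ≤ ½ px bound as the intensity force. The relative
weight *w* of the mask term is 1 by default (the two forces are summed with
equal weight); it is exposed as `DemonsConfig.mask_weight` because no
principled value other than 1 presents itself and users may want to explore
the trade-off.

Boundary pixels are foreground pixels with a 4-adjacent background pixel;
the frame edge itself does not create boundary, so a cell clipped by the
field of view contributes no spurious edge force there.

### Sign and warp conventions

All arrays are (time, row, col); displacement component 0 is the row
direction. Warping is *pull-back*: output(r, c) = input sampled at
(r + u₁, c + u₂), linear interpolation for intensities, nearest-neighbor
plus re-binarization for masks, replicate borders. Under this convention
the demons force above — the forward push of the moving image — must be
*subtracted* from the accumulated sampling field; the iteration is

    U ← sort(K_diff ∗ (U − u))

One iteration therefore: resample moving intensity and mask under U,
evaluate the force, decrement, Gaussian-smooth each component
(σ = `k_diff_sigma`, truncated at 4σ, replicate borders; σ = 0 is the
identity), then apply the diffeomorphism constraint. Constraint order
(smooth, then sort) guarantees the emitted field of every iteration
satisfies the monotonicity invariant.

### Diffeomorphism constraint

A displacement field is accepted as diffeomorphic iff its interpolation
mesh does not fold: along every row, the sampling coordinates u₂ + col are
non-decreasing, and along every column u₁ + row likewise. The constraint is
enforced by stably sorting each row's (u₂ + col) list and each column's
(u₁ + row) list and subtracting the indices back. Sorting preserves the
multiset of sampled coordinates exactly, is idempotent, and leaves already
monotone fields untouched. u₁ is sorted before u₂; the two sorts act on
different components and do not interact. Stable sorting makes ties
deterministic.

This replaces velocity-field (Lie-group) diffeomorphic demons, which over-
smooths the fine granularity that matters in cell images. Note the sorting
acts as a mild extra regularizer: where the true deformation has steep
gradients it can trade a little boundary accuracy for topology (see the
ablation discussion below).

### Whole-movie chaining

`register_sequence` maps every frame onto a reference frame (default: the
center frame, `len // 2`). Frames are processed outward from the reference;
each frame's field is initialized from its already-registered temporal
neighbor ("warm start") and refined with `n_iterations` demons iterations
directly against the reference frame. Frames at distance d from the
reference thus inherit (d−1)·n iterations and receive n more, preserving
the property that more distant frames get proportionally more work, at
O(T·n) total cost. An alternative reading — re-running the full
target-switching chain per frame — produces equivalent fields at O(T²·n)
cost and is not implemented. Per-frame fields are mutually independent
given the fiducial; no temporal smoothing is applied across fields.

Masks are warped alongside intensities each iteration so the mask force is
evaluated between the *warped* moving mask and the fixed target mask and
shrinks to zero as overlap is reached.

### Parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `alpha` | 1.0 | – | force throttle; 1.0 caps each iteration at 1 px |
| `k_diff_sigma` | 1.5 | px | field-smoothing kernel; set to the expected diffusion distance between frames (0.5 px for distant-frame jumps with large shape change) |
| `n_iterations` | 200 | – | per target frame; presets: 100 (`sequential`), 2000 (`first_to_last`), 200 (`half_distance_eval`) |
| `enforce_diffeomorphism` | on | – | topological sorting per iteration |
| `use_mask_term` | on | – | mask regularization force |
| `mask_weight` | 1.0 | – | relative weight of the mask force |
| `lowpass_sigma` | 20 | px | Gaussian σ for a lowpass-of-signal fiducial |

## Accuracy metrics

Live-cell movies have no landmarks, so accuracy is internal: the
*to-target* SSD compares the fully remapped moving frame with the target
frame; the *half-distance* SSD halves the field estimated over two frame
intervals and compares against the skipped middle frame (exact when the
deformation path is linear in time — halved monotone coordinates remain
monotone, so the half field is still diffeomorphic). SSD is reported as the
*mean* squared difference over evaluated pixels so values are comparable
across cell sizes; baselines zero the background (pixels outside each
frame's mask) and compare over the full frame, matching the reported
convention. Whether the original analysis used a union mask instead is not
documented; full-frame-with-zeroed-background is adopted.

Boundary mismatch is the symmetric-difference pixel count of two masks
divided by the target mask's perimeter (8-connected boundary pixel count).
The convergence trace of `register_pair` records this quantity per
iteration; being a quantized count it carries ±1–2 px jitter around a
decreasing trend. Edge displacement sums, over the later mask's boundary
pixels, the Euclidean distance to the earlier mask's boundary, scaled to
μm; `split_phases(..., "thirds")` labels the first/last thirds of a movie
for before/after comparisons of induced shape changes. `compare_groups`
wraps one-way ANOVA for cohort comparisons; reproducing any published
p-values would require the original movies.

## Fluctuation statistics

**Coherence.** For each pixel whose full 3×3 neighborhood lies inside the
reference-frame cell mask, the mean Pearson correlation over the 36
unordered pairs of the 9 neighborhood time-series (ρ with the 1/(N−1),
ddof = 1 normalization). Implementation: z-score each series, box-sum the
z-scores, and use Σᵢⱼ rᵢⱼ = ‖Σᵢ zᵢ‖²/(N−1); this is algebraically exact and
O(T·H·W). Zero-variance series are excluded pairwise (Pearson r is
undefined at σ = 0; defining it as 0 would bias the mean); a neighborhood
with fewer than two variable series is NaN. Values live in [−1, 1]:
anti-correlated neighborhoods are reported as negative rather than clamped,
although typical data concentrates in [0, 1]. Optional superpixel pooling
block-averages the movie first (blocks fully inside the mask); default 1.
Rolling windows default to 25 frames (with 20 as the documented
alternative used for symmetry-breaking analyses), step 1.

**Entropy.** Per pixel and window, intensities are histogrammed into
`n_bins` equal-width bins spanning the window's min–max range and
H = −Σ p log₂ p (0·log 0 := 0). H is non-negative by the standard sign
convention and bounded by log₂ n_bins; a constant series spans no range and
scores 0 bits. Bin count and range are free choices (nothing canonical is
documented for this transform); 8 equal-width bins over the per-window
range make the statistic scale-invariant per pixel and are exposed in the
config. Windows shorter than `n_bins` are allowed with a logged warning.

**Gini.** G = Σᵢⱼ|vᵢ − vⱼ|/(2n²v̄), computed by the sorted-form identity;
0 for homogeneous input, (n−1)/n for all mass in one pixel, scale-invariant,
undefined (error) for all-zero input. Coherence maps may be slightly
negative; clip at 0 before applying Gini, which assumes non-negative mass.

**Zone bands.** Pixels are labeled by interior distance to the cell edge
(from the signed distance map, converted to μm); default bands 0–1.2,
3.6–6 and 8.4–12 μm correspond to lamellipodium, transverse-arc and
perinuclear depths at the default 0.06 μm/px. The entropy–coherence
cross-correlation correlates each pixel's entropy and coherence window
series at lags in [−max_lag, +max_lag] (positive lag shifts the coherence
series forward) and averages per zone ("per-pixel" mode, the default);
"zone-mean" mode correlates zone-averaged series instead. Which of the two
the original figures used is not documented; per-pixel-then-average is the
default because it weights every sampled location equally.

## Synthetic phantoms

The generator emulates: a single adherent cell (Fourier-perturbed ellipse,
domed thickness profile with a bright rim plateau), a diffuse cytoplasmic
fiducial (thickness × smooth texture), a punctate fiducial (fixed dots plus
a faint diffuse pool), an actin-like signal (curvilinear fibers plus a
diffuse pool), smooth sub-pixel-per-frame diffeomorphic shape change
(translation, dilation, protrusion bump, smooth-random, or exactly
linear-in-time paths), and additive Gaussian camera noise (default σ = 2%
of the intensity scale, optional Poisson shot noise). Defaults (256×256,
64 frames, 0.06 μm/px, 5 s/frame, amplitude 3 px) reflect the published
acquisition regime.

Frame t is rendered as ref ∘ g⁻¹ with g(x) = x + U_t(x); g⁻¹ is computed by
fixed-point iteration, a contraction because the generator enforces
sup‖∇U‖ < 0.5 (which also guarantees axis-wise monotonicity analytically).
The stored frame→reference fields are therefore exact by construction;
rendering carries only interpolation error. Noise is added last. Masks
threshold the noise-free rendered thickness at half its rim plateau — the
thresholded support of the noise-free fiducial; at the reference frame the
mask equals the fiducial support exactly, on warped frames the boundary
sits mid-way through the one-pixel bilinear transition.

What phantoms do *not* emulate: a microscope PSF, photobleaching,
out-of-focus light, intensity non-conservation from axial motion,
multi-cell scenes, or fiducial/signal decoupling. A green phantom test
therefore establishes correctness of the algorithmic machinery under the
stated world, not performance on any particular real movie.

`plant_coherence` writes a channel whose in-zone pixel series share a
latent standard normal with mixture weight √ρ (expected pairwise Pearson
r exactly ρ); `plant_entropy_phases` writes a channel that is exactly
constant outside a planted region/phase (0 bits) and i.i.d. uniform inside
it. Both channels are laid down in reference-frame geometry, emulating an
already-remapped signal.

## Numerical choices and degenerate inputs

* 0/0 force guard → 0; Gaussian truncation 4σ; stable sorts for ties.
* Fields are float64 in memory, float32 on disk (two pages per frame,
  row component first, JSON sidecar with the reference index).
* `segment_cell`: Gaussian pre-smooth (σ = 2 px) → Otsu (or fixed)
  threshold → closing → hole fill → largest component; empty foreground is
  an error suggesting a manual threshold; masks touching the border are a
  logged warning, not fatal. External masks can be supplied anywhere a
  segmentation is consumed.
* `mask_gradient` rejects the all-true mask (degenerate distance field).
* Coherence needs ≥ 3 time points; correlation windows shorter than 3
  after lagging return NaN.
* Boundary mismatch with an empty target mask is an error.

## Validation surface and its limits

The test suite validates: the ≤ 1 px per-iteration bound (10⁶ randomized
inputs), sorting monotonicity/idempotence/multiset preservation (1000
random fields), brute-force distance-map equality on small masks, exact
closed forms for entropy, Gini and coherence, and parameter recovery on
phantoms — mean endpoint error < 1 px and remapped-signal SSD < 25% of the
unregistered baseline on a 32-frame smooth-random phantom (5 px amplitude),
the full ≤ no-mask ≤ no-sort ablation ordering of final boundary mismatch
on 10 punctate-fiducial phantoms, and half-distance validity on linear-path
phantoms. Phantom scales are reduced relative to production movies to keep
the suite inside a CI budget; thresholds are not relaxed.

Two honest caveats. First, with 2% camera noise the remapped-vs-reference
SSD of even a *perfect* field is dominated by the irreducible noise floor
(2σ² plus interpolation), so the SSD recovery criterion is scored against
the phantom's noise-free renders while registration runs on the noisy
fiducial; this isolates registration error, which is what the criterion
measures. Second, the ablation ordering is only observable where the
intensity term alone underdetermines the mapping (low-information punctate
fiducial, distant frames, K_diff = 0.5): on high-SNR diffuse fiducials all
three variants converge to near-perfect boundary alignment and the no-mask
vs no-sort comparison degenerates to ties — and because boundary mismatch
does not penalize mesh folding, an unconstrained field can even score
marginally better there while being topologically invalid.

## Known limitations

* 2D only; cells must stay in focus and deform laterally. Axial motion
  violates intensity conservation and degrades the estimate, partially
  mitigated by the mask term's geometric information.
* One cell per field of view; the masking module keeps the largest
  connected component and is not a multi-cell segmenter.
* The fiducial must be geometrically coupled to the signal of interest;
  registering a cytoplasmic signal on a substrate-bound fiducial will
  produce poor remappings.
* Additive field accumulation (not field composition) is accurate under
  the ≤ 1 px step bound but is an approximation for very large total
  deformations.
* No multi-resolution pyramid; very large displacements need more
  iterations rather than coarse-to-fine search.
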