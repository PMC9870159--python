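# cellwarp

Diffeomorphic registration and fluctuation analysis of live-cell time-lapse
movies.

Cells move and change shape while they are being imaged. Any attempt to
extract per-pixel intensity time-series from a movie of a migrating or
spreading cell therefore mixes genuine molecular dynamics with the motion of
the cell itself. `cellwarp` removes that motion: it estimates, for every
frame, a smooth invertible mapping (a diffeomorphism) onto a fixed reference
frame — by default the center frame of the sequence — using a *location
fiducial* channel (a membrane marker, a diffuse cytoplasmic protein, or a
lowpass-filtered copy of the signal itself), and applies those mappings to
every co-imaged signal channel. In the remapped movie every pixel occupies a
fixed piece of the cell, so per-pixel time-series analysis becomes
meaningful across the whole cell footprint, not just near the edge.

It is written for cell biologists and image analysts working with 2D
time-lapse fluorescence microscopy of single adherent cells.

## The method

Registration is a mask-regularized variant of Thirion's demons with an
explicit topological diffeomorphism constraint. Per iteration, with moving
intensity *m* (resampled under the current field), target intensity *f*,
and binary cell masks *m*ₘₐₛₖ, *f*ₘₐₛₖ:

```
u = (m − f) ∇f / (α²(m − f)² + |∇f|²)
  + (mₘₐₛₖ − fₘₐₛₖ) ∇fₘₐₛₖ / (α²(mₘₐₛₖ − fₘₐₛₖ)² + |∇fₘₐₛₖ|²)
```

where ∇*f*ₘₐₛₖ is the unit gradient of the signed distance to the target
cell boundary. With α = 1 each term is bounded by ½ pixel, so one iteration
moves at most 1 pixel. The accumulated field is smoothed with a Gaussian
kernel K_diff (default 1.5 px) and then forced to remain a diffeomorphism
by *sorting* the sampling coordinates: along every image row the values
u₂ + col must be non-decreasing, along every column u₁ + row likewise; any
fold-over of the interpolation mesh is repaired by a stable sort that
preserves the sampled coordinates exactly. The mask term pulls the
registration out of local minima wherever the two cell footprints disagree;
the sorting preserves fine image granularity without the smoothing-heavy
regularization a Lie-group diffeomorphic demons would need.

On the remapped movies the package computes:

* **local 3×3 coherence** — mean Pearson correlation of the 36 unordered
  pairs among the 9 time-series of each pixel's neighborhood (whole-movie
  or rolling window);
* **rolling Shannon entropy** — bits of per-pixel intensity variability in
  a temporal window (H = −Σ p log₂ p over equal-width bins);
* **Gini coefficient** — spatial heterogeneity of any per-pixel map over
  the cell footprint (0 homogeneous, →1 concentrated in one pixel);
* **accuracy metrics** — to-target and half-distance SSD transforms,
  perimeter-normalized boundary mismatch, and the integrated cell-edge
  displacement time course.

A synthetic-data module generates phantom cell movies with *exact*
ground-truth masks and deformation fields (frames are rendered through the
analytically inverted warp), so every operator is testable without any
external dataset.

## Worked example

```python
import numpy as np
import cellwarp as cw

spec = cw.PhantomSpec(image_size=128, n_frames=16, warp_amplitude=4.0, seed=7)
movie = cw.generate_phantom(spec)

config = cw.DemonsConfig(n_iterations=200, k_diff_sigma=1.5)
result = cw.register_sequence(movie.fiducial, movie.masks, config=config)
result = cw.remap_channels(result, {"signal": movie.channels["signal"]})

epes = []
for t in range(spec.n_frames):
    true, got = movie.true_field(t), result.field_for_frame(t)
    inside = movie.masks[t].mask
    epes.append(np.hypot(true.u1 - got.u1, true.u2 - got.u2)[inside].mean())
print(np.mean(epes))
```

Running `python examples/02_register_movie.py` (the same computation)
prints:

```
mean endpoint error inside the cell: 0.353 px (worst frame 0.477 px)
signal SSD frame 0 vs reference: 7.07e-04 remapped, 2.72e-03 unregistered (26.0% of baseline)
```

The first line compares the recovered frame→reference displacement fields
with the generator's exact ground truth: on average each pixel of the cell
is mapped to within ~a third of a pixel of its true position. The second
line shows that remapping the co-imaged signal channel with those fields
reduces its mean squared difference to the reference frame to about a
quarter of the unregistered value — the residual being camera noise and
interpolation, not motion.

The other scripts in `examples/` each demonstrate one capability:
`01_simulate_phantom.py` (generate and save a ground-truth movie),
`03_remapping_accuracy.py` (to-target / half-distance accuracy and the
edge-displacement time course), `04_fluctuation_maps.py` (coherence,
entropy, Gini and distance-from-edge zone bands).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch with the given seed, the package's analytic
guarantees: the coherence of nine identical time-series, the Gini
coefficient of a homogeneous signal, the maximum demons displacement per
iteration at α = 1 over 10⁶ randomized inputs, and the maximum Gini
coefficient over 10⁴ random non-negative vectors including single-pixel
concentrations. Results are written as JSON to `--out`.
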