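"""Register a movie to its center frame and remap a signal channel.

Generates a phantom movie, estimates the frame->reference deformation
fields on the diffuse fiducial channel with the mask-regularized,
diffeomorphism-constrained demons, remaps the actin-like signal channel,
and compares the recovered fields against the generator's exact ground
truth.
"""

import numpy as np

import cellwarp as cw

spec = cw.PhantomSpec(image_size=128, n_frames=16, warp_amplitude=4.0, seed=7)
movie = cw.generate_phantom(spec)

config = cw.DemonsConfig(n_iterations=200, k_diff_sigma=1.5)
result = cw.register_sequence(movie.fiducial, movie.masks, config=config)
result = cw.remap_channels(result, {"signal": movie.channels["signal"]})

# endpoint error: recovered vs ground-truth displacement, inside the cell
epes = []
for t in range(spec.n_frames):
    true, got = movie.true_field(t), result.field_for_frame(t)
    inside = movie.masks[t].mask
    epes.append(np.hypot(true.u1 - got.u1, true.u2 - got.u2)[inside].mean())
print(f"mean endpoint error inside the cell: {np.mean(epes):.3f} px "
      f"(worst frame {np.max(epes):.3f} px)")

# SSD of the remapped signal against the reference frame vs unregistered
ref = movie.channels["signal"].frames[movie.reference_index]
t = 0  # frame farthest from the reference
baseline = cw.ssd(movie.channels["signal"].frames[t], ref)
remapped = cw.ssd(result.remapped["signal"].frames[t], ref)
print(f"signal SSD frame 0 vs reference: {remapped:.2e} remapped, "
      f"{baseline:.2e} unregistered ({remapped / baseline:.1%} of baseline)")
# Sub-pixel endpoint error and a large SSD drop mean the fiducial-derived
# fields transport the co-imaged signal faithfully onto the reference frame.
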