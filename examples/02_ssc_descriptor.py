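"""Compute the self-similarity context descriptor and show its invariance.

The 12-channel SSC descriptor encodes how similar neighboring patches are
to each other, normalized by a local noise estimate.  Because every term
scales with the square of an affine intensity change, the descriptor is
unchanged under x -> a*x + b — the property that lets one network read
CT and MR alike.
"""
import numpy as np

from dgtta import PhantomSpec, compute_ssc, generate_phantom

label, source, target = generate_phantom(PhantomSpec(), np.random.default_rng(3))

d_src = compute_ssc(source)
d_affine = compute_ssc(5.0 * source.data - 2.0)
d_tgt = compute_ssc(target)

print(f"descriptor shape: {d_src.data.shape} (12 channels per voxel)")
print(f"value range: ({d_src.data.min():.3f}, {d_src.data.max():.3f}]")
dev = np.abs(d_affine.data - d_src.data).max()
print(f"max deviation under affine intensity change 5x-2: {dev:.2e}")
fg = label.data > 0
corr = np.corrcoef(d_src.data[:, fg].ravel(), d_tgt.data[:, fg].ravel())[0, 1]
print(f"source/target descriptor correlation on foreground: {corr:.2f}")
print("The affine deviation is at numerical precision; the cross-domain")
print("correlation stays clearly positive even though raw intensities are")
print("remapped non-monotonically (the gap itself is non-affine).")
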