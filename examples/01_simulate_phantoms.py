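"""Generate a paired source/target phantom cohort and inspect the gap.

Builds a small dataset of 3D phantoms whose label geometry is shared
between a CT-like source rendering and an MR-like target rendering
(non-monotone intensity remapping, independent noise, multiplicative bias
field), then prints how different the two domains look.
"""
import numpy as np
from scipy import stats

from dgtta import PhantomSpec, generate_phantom

spec = PhantomSpec()  # 64^3 voxels at 1.5 mm, 4 structure classes
label, source, target = generate_phantom(spec, np.random.default_rng(0))

fg = label.data > 0
ks = stats.ks_2samp(source.data[fg], target.data[fg]).statistic
print(f"phantom grid {label.shape}, foreground fraction {fg.mean():.3f}")
print(f"classes present: {label.class_ids}")
for c in label.class_ids:
    m = label.data == c
    print(f"  class {c}: source mean {source.data[m].mean():+.2f}, "
          f"target mean {target.data[m].mean():+.2f}")
print(f"source/target foreground KS statistic: {ks:.2f}")
print("A KS statistic this large means the two domains' intensity")
print("distributions differ substantially — a model keyed to absolute")
print("intensity will not transfer.")
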