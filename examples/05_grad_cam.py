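"""Grad-CAM on a trained tiny attention CNN.

Trains the pipeline's small model on synthetic data, builds a probe image
whose nuclei all sit in the top-left quadrant, and checks that the
high-grade class activation concentrates there.  Writes heatmap.png and
overlay.jpg to the current directory.
"""

import tempfile
from pathlib import Path

import numpy as np

from dieanet.explain import grad_cam, save_heatmap
from dieanet.preprocessing import GRADES, od_to_rgb
from dieanet.synthetic import CANONICAL_HE_BASIS
from dieanet.train import smoke_experiment

with tempfile.TemporaryDirectory() as work:
    res = smoke_experiment(work, seed=1)
model = res["model"]

size, q = 128, 64
rng = np.random.default_rng(0)
hema = np.zeros((size, size))
ax = np.arange(-9, 10)
kern = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / 18.0)
for _ in range(40):
    y, x = rng.integers(0, q - 19, 2)
    hema[y:y + 19, x:x + 19] += kern
img = od_to_rgb(hema[:, :, None] * CANONICAL_HE_BASIS.W[:, 0])

hm = grad_cam(model, img, target_class=GRADES.index("high"))
inside = hm.values[:q, :q].mean()
outside = (hm.values.sum() - hm.values[:q, :q].sum()) / (size * size - q * q)
print(f"mean activation inside the nucleus quadrant : {inside:.3f}")
print(f"mean activation outside                     : {outside:.3f}")
print("A higher value inside shows the class evidence is spatially grounded "
      "in the simulated tumor region, not spread uniformly.")

out = Path.cwd()
save_heatmap(hm, out / "heatmap.png", out / "overlay.jpg")
print(f"wrote {out / 'heatmap.png'} and {out / 'overlay.jpg'}")
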