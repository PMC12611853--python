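"""Extract the lung fields from a slice with the full preprocessing chain.

The chain standardizes intensities, denoises with a median filter and
Perona-Malik diffusion, separates dark (air/lung) from bright (tissue)
pixels by 1-D K-means, cleans the candidate mask by morphological opening,
and keeps the two largest interior connected components as the lungs.
"""

import numpy as np

from noduleseg import PhantomConfig, generate_phantom
from noduleseg.preprocessing import preprocess_slice

sample = generate_phantom(PhantomConfig(seed=3))
roi, lung_mask = preprocess_slice(sample.image)

true = sample.lung_mask.astype(bool)
got = lung_mask.astype(bool)
iou = (true & got).sum() / (true | got).sum()
print(f"recovered lung mask: {lung_mask.sum()} px "
      f"(ground truth {true.sum()} px), IoU = {iou:.3f}")
print("an IoU near 1 means the intensity-based pipeline found the same "
      "lung fields the generator drew")

print(f"ROI is zero outside the (dilated) lungs: "
      f"{np.count_nonzero(roi) / roi.size:.1%} of pixels retained")
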