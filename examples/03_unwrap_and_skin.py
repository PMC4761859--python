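"""Mirror frame → metric panorama → K-means skin mask → grasp area.

Renders an omnidirectional frame with a known finger-band layout,
calibrates the annulus from the image itself, unwraps the cylinder
surface to metric coordinates and segments skin in CIELAB chroma.
"""

import numpy as np

from graspkin import (
    MirrorModel,
    detect_annulus,
    segment_skin,
    synth_omni_frame,
    unwrap,
)
from graspkin.synth import DEFAULT_HAND_BANDS

model = MirrorModel()                      # 140 mm circumference, 70 mm band
frame, truth = synth_omni_frame(model, seed=0, pano_shape=(280, 720))

(cy, cx), r_in, r_out = detect_annulus(frame)
print(f"annulus: center ({cy:.1f}, {cx:.1f}) px, radii {r_in:.1f}–{r_out:.1f} px")

pano = unwrap(frame, model, out_w=720, out_h=280)
print(f"panorama: {pano.pixels.shape[1]}×{pano.pixels.shape[0]} px = "
      f"{pano.width_mm:.0f} × {pano.height_mm:.0f} mm "
      f"({pano.mm_per_px_x:.3f} × {pano.mm_per_px_y:.3f} mm/px)")

seg = segment_skin(pano, seed=0)
true_area = sum(w / 360.0 * model.cylinder_circumference_mm * (h1 - h0)
                for (_, w, h0, h1) in DEFAULT_HAND_BANDS)
agreement = 100.0 * np.mean(seg.mask == truth.true_skin_mask)
print(f"skin cluster centroid (L*, a*, b*): "
      f"{np.round(seg.centroids[seg.skin_cluster], 1)}")
print(f"grasp area: {seg.grasp_area_mm2:.0f} mm² "
      f"(painted: {true_area:.0f} mm²); mask agreement {agreement:.2f}%")
# The grasp area is the skin-covered part of the cylinder surface — the
# camera-side quantity the device pairs with the IMU kinematics.
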