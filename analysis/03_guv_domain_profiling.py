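#!/usr/bin/env python
"""Profile synthetic GUV micrographs and recover injected bright domains.

Renders 20 seeded vesicle images (64 nm/px, Gaussian ring membrane with one
2.5x-bright 30 degree domain at a known angle, SNR 5), runs the full
pipeline (smooth, Hough circle, radial maximum search, skeletonize,
angular profile, domain flagging) and tabulates detection accuracy.

Output: results/guv_domains.csv
"""

from pathlib import Path

import pandas as pd

from lipidphase.guv import profile_vesicle
from lipidphase.synthetic import GuvImageSpec, gen_guv_image

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rows = []
for seed in range(20):
    center_deg = (17.0 * seed + 5.0) % 360.0
    img, truth = gen_guv_image(
        GuvImageSpec(domains=((center_deg, 30.0, 2.5),), noise_sigma=40.0, seed=seed)
    )
    prof = profile_vesicle(img, r_range=(20, 80))
    best_err = None
    if prof.domains:
        best_err = min(
            abs((d.center_deg - center_deg + 180.0) % 360.0 - 180.0)
            for d in prof.domains
        )
    cx, cy = prof.circle.center_xy
    rows.append(
        {
            "seed": seed,
            "true_center_deg": center_deg,
            "n_detected": len(prof.domains),
            "center_error_deg": best_err,
            "circle_x": cx,
            "circle_y": cy,
            "radius_px": prof.circle.radius,
        }
    )

df = pd.DataFrame(rows)
df.to_csv(OUT / "guv_domains.csv", index=False)
print(df.to_string(index=False))
hits = (df["center_error_deg"] <= 5.0).sum()
print(
    f"\nDomain center recovered within 5 deg in {hits}/20 images "
    f"(worst error {df['center_error_deg'].max():.1f} deg)."
)
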