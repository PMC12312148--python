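#!/usr/bin/env python
"""Quantify lipid-phase fractions from simulated 31P powder spectra.

Emulates a temperature series in which an isotropic 0 ppm component grows
at the expense of the lamellar pattern (the signature of small inverted
micelles forming between bilayer leaflets), then decomposes each noisy
spectrum against the default three-phase basis and compares recovered to
generating weights.

Output: results/nmr_weights.csv
"""

from pathlib import Path

import pandas as pd

from lipidphase.nmr import DEFAULT_BASES, decompose_spectrum
from lipidphase.synthetic import NmrSpectrumSpec, gen_nmr_spectrum

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

series = [  # (pseudo-temperature label, lamellar, hexagonal, isotropic)
    ("4C", 0.95, 0.0, 0.05),
    ("20C", 0.80, 0.0, 0.20),
    ("37C", 0.50, 0.0, 0.50),
    ("60C", 0.30, 0.0, 0.70),
]

rows = []
for i, (label, w_lam, w_hex, w_iso) in enumerate(series):
    spec, truth = gen_nmr_spectrum(
        NmrSpectrumSpec(weights=(w_lam, w_hex, w_iso), noise_sigma=0.001, seed=i)
    )
    w, resid = decompose_spectrum(spec, DEFAULT_BASES)
    rows.append(
        {
            "temperature": label,
            "lamellar_true": w_lam, "lamellar_fit": w[0],
            "hexagonal_true": w_hex, "hexagonal_fit": w[1],
            "isotropic_true": w_iso, "isotropic_fit": w[2],
            "relative_residual": resid,
        }
    )

df = pd.DataFrame(rows)
df.to_csv(OUT / "nmr_weights.csv", index=False)
print(df.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
err = max(
    (df[f"{p}_fit"] - df[f"{p}_true"]).abs().max()
    for p in ("lamellar", "hexagonal", "isotropic")
)
print(f"\nWorst absolute weight error across the series: {err:.4f}")
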