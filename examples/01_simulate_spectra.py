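"""Generate a synthetic NIR dataset and inspect its ground truth.

The generator mimics diffuse-reflectance spectra of a dried plant powder:
three quality-marker analytes (total saponins, mannitol, naringenin) plus a
dominant, nearly constant matrix component, with baseline drift,
per-sample multiplicative scatter and white noise on top.
"""

import numpy as np

from nirquant import SyntheticConfig, generate

config = SyntheticConfig(n_samples=120, n_channels=1557, seed=7)
dataset = generate(config)

spectra = dataset.spectra
print(f"spectra: {spectra.n_samples} samples x {spectra.n_channels} channels, "
      f"{spectra.wavelengths_nm[0]:.0f}-{spectra.wavelengths_nm[-1]:.0f} nm")
print(f"absorbance range: {spectra.absorbance.min():.3f} to "
      f"{spectra.absorbance.max():.3f} AU")

print("\nreference concentrations (g/kg):")
print(dataset.references.describe().loc[["min", "mean", "max"]].round(4))

print("\ninformative channels per component (where the pure spectrum "
      "exceeds 1% of its band maximum):")
for name, idx in dataset.informative_channels.items():
    lo, hi = spectra.wavelengths_nm[idx.min()], spectra.wavelengths_nm[idx.max()]
    print(f"  {name:15s} {idx.size:4d} channels ({lo:.0f}-{hi:.0f} nm)")

print(f"\nper-sample scatter slopes m_i: "
      f"{dataset.scatter_slopes.min():.3f}-{dataset.scatter_slopes.max():.3f} "
      "(the multiplicative particle-size effect SNV/MSC remove)")
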