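# radiopeek

Photon-interaction parameters and Monte Carlo X-ray imaging simulation for
radiopaque PEEK implant composites.

Polyetheretherketone (PEEK) is a biocompatible implant polymer whose low-Z
composition (C, H, O) makes it nearly transparent on diagnostic X-ray images.
A standard remedy is to load the polymer with a high-Z filler.  This package
evaluates that trade theoretically for six materials — cortical bone, pure
PEEK, and PEEK with 20 wt% hydroxyapatite, BaSO4, Bi2O3 or Ta — over the
diagnostic energy range 20–120 keV.  It is aimed at medical-physics and
biomaterials researchers who want a scriptable, reproducible version of the
usual two-part assessment: analytic photon-interaction parameters plus a
Monte Carlo radiography experiment.

## What it computes

**Attenuation parameters** per material on an energy grid:

- mass attenuation coefficient `μ/ρ = Σᵢ wᵢ (μ/ρ)ᵢ` (cm²/g),
- linear coefficient `μ = (μ/ρ)·ρ` and transmission `I/I₀ = exp(−μx)`,
- half-value layer `HVL = ln2/μ`,
- total atomic cross-section `σ_t,a = (μ/ρ) / (N_A Σᵢ wᵢ/Aᵢ)`,
- total electronic cross-section `σ_t,el = (1/N_A) Σᵢ fᵢ (Aᵢ/Zᵢ)(μ/ρ)ᵢ`,
- effective atomic number `Z_eff = σ_t,a / σ_t,el` and effective electron
  density `N_eff = (μ/ρ) / σ_t,el`,
- percent increase over the PEEK baseline, and K-edge localization on the
  computed curves (largest upward jump on a ≤0.1 keV grid).

Composite densities follow the study inputs; the rule of mixtures
`ρ = f·ρ_filler + (1−f)·ρ_matrix` is available as a utility.

**Imaging simulation**: a 100×100 cm planar source at Z = −50 cm emits
photons along +Z with energies uniform on [20, 120] keV toward 5 cm boxes of
the six materials at Z = 0.  Photons undergo photoelectric absorption,
Klein–Nishina Compton scattering and (optionally) Rayleigh scattering; the
tallies give per-event energy deposits (mean, RMS, relative fluctuation),
interaction counts, a secondary-electron track-length proxy, a voxelized 3-D
deposition grid, projection images (XY/XZ/YZ) and per-material
`SNR = mean / standard deviation` over each footprint.

The per-element photoatomic data are generated from an embedded, approximate
two-branch power-law parameterization with exact K-edge placement (Ba at
37.4 keV, Ta at 67.4 keV, Bi at 90.5 keV); see `docs/methods.md` for its
accuracy envelope and every physics simplification.

## Worked example

```python
import numpy as np
import radiopeek as rp
from radiopeek.attenuation import compute_curve, locate_k_edge
from radiopeek.pipeline import compare_materials

mats = rp.study_materials()
curves = {n: compute_curve(m) for n, m in mats.items()}
for name in ("PEEK", "PEEK-BaSO4", "PEEK-Bi2O3"):
    c = curves[name]
    i = np.searchsorted(c.grid.energies, 50.0)
    print(f"{name:11s} mu/rho(50 keV) = {c.mu_m[i]:.4f} cm^2/g   "
          f"HVL(50 keV) = {c.hvl[i]:.3f} cm   Z_eff(50 keV) = {c.z_eff[i]:.2f}")
print("K edge PEEK-BaSO4:", locate_k_edge(curves["PEEK-BaSO4"]), "keV")
print(compare_materials(curves).round(1).to_string(index=False))
```

prints

```
PEEK        mu/rho(50 keV) = 0.2046 cm^2/g   HVL(50 keV) = 2.567 cm   Z_eff(50 keV) = 4.61
PEEK-BaSO4  mu/rho(50 keV) = 1.4569 cm^2/g   HVL(50 keV) = 0.313 cm   Z_eff(50 keV) = 24.12
PEEK-Bi2O3  mu/rho(50 keV) = 1.6096 cm^2/g   HVL(50 keV) = 0.112 cm   Z_eff(50 keV) = 30.13
K edge PEEK-BaSO4: 37.4 keV
  material  pct_30keV  pct_50keV  pct_80keV  pct_100keV  pct_grid_min  pct_grid_max
      bone      175.8       58.7       19.3        11.5           7.7         325.0
      PEEK        0.0        0.0        0.0         0.0           0.0           0.0
   PEEK-HA       62.6       20.3        6.1         3.2           1.8         116.4
PEEK-BaSO4      338.2      612.1      188.6       106.0          65.9        1191.5
PEEK-Bi2O3     1855.5      686.7      236.0       636.3         176.9        3087.8
   PEEK-Ta     1360.8      506.3      810.5       456.1         259.6        2256.7
```

Read: pure PEEK needs 2.6 cm to halve a 50 keV beam, the BaSO4 composite
3 mm and the Bi2O3 composite about 1 mm; the BaSO4 curve's discontinuity
sits exactly at the barium K edge; and 20 wt% of any heavy filler raises
μ/ρ by hundreds of percent at low-to-mid diagnostic energies, while
hydroxyapatite adds only a few percent at the high end — the quantitative
version of "HA barely improves radiopacity".

The full study (curves + Monte Carlo run + SNR tables) is one call or one
command:

```sh
radiopeek -v run --outdir study_output      # 10^6 events by default
radiopeek attenuation --material PEEK-Bi2O3 --emin 20 --emax 120
```

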