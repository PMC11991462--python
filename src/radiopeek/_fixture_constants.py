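"""Embedded photoatomic parameterization constants.

These anchor constants define the packaged photon-data fixture: for each
element, two-point power-law anchors ``[[E_keV, mu_cm2_g], ...]`` for the
photoelectric term (one branch for light elements, separate below/above-K
branches for Ba, Ta, Bi) and for the coherent (Rayleigh) term.  The
incoherent term is not tabulated here because it is computed analytically
from the free-electron Klein-Nishina cross-section.

The photoelectric branches of the K-edge elements follow a power law with
exponent 2.9 above the edge and 2.7 below, with K-jump ratios from the
empirical fit J = 125/Z + 3.5, calibrated against standard reference
attenuation values (Pb at 100 keV); light-element anchors are set directly
from reference values at 20 and 60 keV.  Coherent anchors realize
sigma = 2.747 Z^2.5 / E^1.75 barn/atom.  The parameterization is an
approximate stand-in for a full photoatomic library: accurate placement of
K-edge discontinuities and physically sensible magnitudes, with errors of
order tens of percent in individual coefficients.
"""

FIXTURE_VERSION = "1"

# Default span of the generated per-element tables (keV).  Wider than the
# 20-120 keV study range so that Compton-downscattered photons in the
# transport module remain inside the table span.
LIBRARY_EMIN = 10.0
LIBRARY_EMAX = 150.0
LIBRARY_STEP = 0.1

PHOTOELECTRIC_ANCHORS = {
    "H": {"pe": [[20.0, 1.0e-05], [60.0, 3.5e-07]]},
    "C": {"pe": [[20.0, 0.208], [60.0, 0.0068]]},
    "N": {"pe": [[20.0, 0.345], [60.0, 0.0113]]},
    "O": {"pe": [[20.0, 0.575], [60.0, 0.0189]]},
    "Na": {"pe": [[20.0, 1.04], [60.0, 0.0363]]},
    "Mg": {"pe": [[20.0, 1.38], [60.0, 0.0482]]},
    "P": {"pe": [[20.0, 2.59], [60.0, 0.0908]]},
    "S": {"pe": [[20.0, 3.21], [60.0, 0.114]]},
    "Ca": {"pe": [[20.0, 6.05], [60.0, 0.22]]},
    "Ba": {
        "pe_below": [[20.0, 22.708184], [37.4, 4.189962]],
        "pe_above": [[37.4, 24.017460], [120.0, 0.817013]],
    },
    "Ta": {
        "pe_below": [[20.0, 57.033803], [67.4, 2.145515]],
        "pe_above": [[67.4, 11.183131], [120.0, 2.099189]],
    },
    "Bi": {
        "pe_below": [[20.0, 87.497690], [90.5, 1.485342]],
        "pe_above": [[90.5, 7.435657], [120.0, 3.280761]],
    },
}

COHERENT_ANCHORS = {
    "H": [[20.0, 8.676539e-03], [120.0, 3.772088e-04]],
    "C": [[20.0, 6.421050e-02], [120.0, 2.791524e-03]],
    "N": [[20.0, 8.094817e-02], [120.0, 3.519187e-03]],
    "O": [[20.0, 9.895533e-02], [120.0, 4.302041e-03]],
    "Na": [[20.0, 1.526686e-01], [120.0, 6.637203e-03]],
    "Mg": [[20.0, 1.795000e-01], [120.0, 7.803688e-03]],
    "P": [[20.0, 2.460582e-01], [120.0, 1.069728e-02]],
    "S": [[20.0, 2.793467e-01], [120.0, 1.214448e-02]],
    "Ca": [[20.0, 3.903696e-01], [120.0, 1.697115e-02]],
    "Ba": [[20.0, 1.494587e+00], [120.0, 6.497653e-02]],
    "Ta": [[20.0, 2.200698e+00], [120.0, 9.567440e-02]],
    "Bi": [[20.0, 2.626622e+00], [120.0, 1.141913e-01]],
}
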