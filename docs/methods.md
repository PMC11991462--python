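# Methods

This note documents the physics model, the embedded data, the numerical
choices and the known limits of validity of `radiopeek`.  Units throughout:
energies keV, lengths cm (track lengths mm), mass coefficients cm²/g,
cross-sections cm² per atom or per electron, densities g/cm³.

## Materials

A material is a named set of elemental weight fractions plus a bulk
density.  The six study materials are packaged in
`src/radiopeek/data/materials.yaml`:

| material    | density | composition source |
|-------------|---------|--------------------|
| bone        | 1.85    | ICRP cortical-bone mass fractions; the 0.01 wt% Zn trace is folded into Ca because the element library covers the 12 elements that appear in the study set (H, C, N, O, Na, Mg, P, S, Ca, Ba, Ta, Bi) |
| PEEK        | 1.32    | repeat unit C19H12O3 |
| PEEK-HA     | 1.68    | 20 wt% Ca10(PO4)6(OH)2 in PEEK |
| PEEK-BaSO4  | 1.52    | 20 wt% BaSO4 in PEEK |
| PEEK-Bi2O3  | 3.84    | 20 wt% Bi2O3 in PEEK |
| PEEK-Ta     | 4.65    | 20 wt% Ta in PEEK |

Composite compositions are expanded at load time from the mixture rule
`w_e(mix) = f·w_e(filler) + (1−f)·w_e(matrix)` so they carry full floating
precision.  The composite **densities are authoritative study inputs**: they
are carried verbatim and deliberately *not* recomputed from the density rule
of mixtures (which, at 20 wt%, would give e.g. 4.386 rather than 4.65 for
the Ta composite).  `mixture_density` implements the rule as a utility and
is exact at its endpoints.

## Photoatomic model

The per-element data are generated from an embedded parameterization
(`_fixture_constants.py`), not read from an external photoatomic library.

* **Photoelectric**: per-element power law `a·E^(−p)` through two anchor
  points per branch.  Elements with a K edge inside the tabulated range
  (Ba 37.4, Ta 67.4, Bi 90.5 keV) carry separate below/above-edge branches
  with a discontinuous upward jump at the edge; jump ratios follow the
  empirical fit `J = 125/Z + 3.5` and the branch exponents are 2.7 (below)
  and 2.9 (above), calibrated against standard reference attenuation values
  at high Z.  Light-element anchors are set directly from reference values
  at 20 and 60 keV.
* **Incoherent**: free-electron Klein–Nishina total cross-section times the
  electron density `Z/A·N_A`.  No incoherent scattering function is applied;
  this is the model's main simplification and overestimates incoherent
  scattering at low energies for high-Z elements by up to ~10%.
* **Coherent (Rayleigh)**: per-element power law realizing
  `σ ≈ 2.747·Z^2.5/E^1.75` barn/atom, included by default and toggleable
  everywhere (`include_coherent`); the transport module consumes the same
  per-process coefficients, so Monte Carlo and analytic totals can never
  disagree by construction.

Accuracy envelope: individual coefficients are correct to tens of percent
(light-element photoelectric terms at high energy are worse in relative
terms but negligible in absolute terms).  K-edge *positions* are exact by
construction, which is what the package's discontinuity analysis relies on.
Totals always equal the sum of their per-process parts exactly.

Grids: the study grid is 20–120 keV in 0.1 keV steps; the generated library
tables span 10–150 keV so Compton-downscattered photons stay inside the
span.  Every in-range K edge appears as a **duplicated grid node**, the
first node holding the below-edge value and the second the above-edge
value; log-log interpolation honours the pair, and a query exactly at the
edge returns the above-edge branch by convention.

## Material-level parameters

`μ/ρ` of a mixture is the weight-fraction-weighted sum of elemental
coefficients.  The electronic cross-section uses the standard
atom-fraction form `σ_t,el = (1/N_A) Σ fᵢ (Aᵢ/Zᵢ)(μ/ρ)ᵢ` and the atomic
cross-section divides `μ/ρ` by atoms per gram, `N_A Σ wᵢ/Aᵢ`.  Both reduce
exactly to the single-element values, which forces `Z_eff = Z` and
`N_eff = N_A·Z/A` for pure elements — the package's structural check of the
formulas (asserted to 1e−9 across the whole grid).

The K-edge locator scans adjacent grid points for the largest relative
upward jump of `μ/ρ`, requires a grid step ≤ 0.1 keV, returns the energy of
the upper point (ties broken by the first maximum), and reports "no edge"
below a configurable 5% relative threshold — large enough to ignore
interpolation noise, small enough to catch a 20 wt% filler edge, whose
jumps are ≥15% here.

## Monte Carlo transport

Geometry and source defaults reproduce the study design: a 100×100 cm
planar source at Z = −50 cm, photons along +Z with energies uniform on
[20, 120] keV, and one 5×5×5 cm box per material with front faces at Z = 0,
arranged along X with 2 cm gaps, world in vacuum.  Box sizes, gaps, grid
shape and the source band are configurable; a degenerate band
(`emin == emax`) gives a monoenergetic beam for validation runs.

Tracking is surface-to-surface through axis-aligned boxes (slab method,
1 nm surface push).  Free paths are sampled from `−ln(U)/μ_total`; the
interaction type is chosen proportionally to the per-process linear
coefficients.  Physics simplifications, all deliberate:

* no electron transport — charged-particle energy deposits at the
  interaction point; the per-volume "track length" is the CSDA-style proxy
  `R(E) = 0.143·(E/100 keV)^1.67 / ρ` mm summed over secondaries, for
  relative comparisons only;
* no fluorescence or Auger relaxation after photoelectric absorption;
* Compton polar angles are rejection-sampled from the Klein–Nishina
  density (validated by a χ² goodness-of-fit test against the analytic
  form), azimuths uniform; scattered energy follows Compton kinematics with
  exact per-event energy conservation;
* Rayleigh deflects with a Thomson-shaped `1 + cos²θ` law and no energy
  loss, and can be disabled together with the coherent attenuation term;
* photons below 10 keV (beneath the tabulated span; reachable only after
  multiple large-angle scatters) deposit their remaining energy locally.

Tallies: per-event per-volume deposits (kept in full by default, streamed
into mean/RMS otherwise), interaction counts by process, the track-length
proxy, escaped energy, and a voxelized deposition grid (default 100³ over
the tight bounding box of the volumes).  Global energy balance
(deposits + escapes = emitted) holds to machine precision and is asserted
at 1e−6 in tests.

Reproducibility: one run seed; events are processed in fixed 2^16-event
batches whose RNG streams are spawned deterministically from the seed, so a
given seed and configuration give bit-identical tallies.

## Imaging metrics

`SNR = mean / sample (n−1) standard deviation` over the pixels of a
material's footprint (the projected column of its box).  In the XY and XZ
planes the six footprints are disjoint regions of shared images; in YZ all
boxes project onto the same footprint, so a restricted per-material YZ map
is built from that material's X-slab of the deposition grid.  A
zero-variance patch is reported as infinite SNR with a flag.  Per-event
deposit statistics use the population RMS about the mean; the relative
fluctuation is `F = 100·RMS/mean`, optionally scaled by `√E₀` with E₀ the
mean sampled source energy of the run (the natural choice for a uniform
energy band, where no single "initial energy" exists).

## Synthetic data

The synthetic module generates everything the tests need at run time: the
photon-data fixture (deterministic, versioned, bit-identical per spec),
truncated-normal test images with known mean/std (chosen over Poisson so
the SNR check has a closed-form target; a Poisson mode exists), and
Beer–Lambert recovery experiments.  Recovery fits `ln(I/I₀)` against
thickness by least squares with an intercept and builds a t-based
confidence interval on the slope; zero-count points are dropped with a
warning.  The end-to-end variant feeds transport-generated uncollided
counts back into the fit, closing the loop between the package's two
halves: the recovered μ agrees with the attenuation module's μ within its
99% CI.

What the generators do *not* emulate: polychromatic tube spectra, detector
response, anatomical phantoms, particle-size or dispersion effects in the
composite.  Passing tests therefore demonstrate internal consistency and
correct mathematics, not clinical image quality.

## Problem sizes

The default study runs 10⁶ source events; the test suite and the
statistical acceptance checks use 10⁵ events (and 10⁵ photons per
transmission point), sizes at which every binomial/χ² criterion in the
suite has comfortable power while the whole suite runs in well under a
minute of Monte Carlo time.  The pipeline manifest flags runs below 10⁶
events as `scaled_down`.

## Known limitations

* The photoatomic parameterization is approximate (see the accuracy
  envelope above).  Conclusions that depend on coefficient *ratios between
  materials at the same energy* are robust; absolute HVLs carry the
  coefficient error.
* Between the Ta and Bi K edges (67.4–90.5 keV) the Ta composite's μ/ρ
  exceeds the Bi2O3 composite's: Ta is then above its edge while Bi is
  below its own.  This is a genuine feature of photoelectric physics, so
  the blanket expectation "the Bi2O3 composite attenuates most at *every*
  energy" — encoded verbatim in one ordering acceptance test — cannot be
  satisfied by any self-consistent photoatomic data, and that sub-check is
  intentionally left failing rather than weakened.
* The same acceptance test encodes an expected mean-deposit chain in which
  the BaSO4 composite outranks the Ta composite.  Because
  μ(PEEK-Ta) > μ(PEEK-BaSO4) at every energy, no slab geometry can produce
  that inversion: with the default geometry the simulated ordering is
  Ta ≈ Bi2O3 > BaSO4 > bone > HA > PEEK (the two optically thick composites
  absorb essentially everything that enters and differ only through
  backscatter albedo, i.e. within noise at 10⁵ events).  The tally/μ
  consistency that the pipeline *can* guarantee — PEEK lowest in both
  orderings, every heavy composite above it — is asserted in the regular
  suite.
* Rayleigh angular shapes ignore atomic form factors; small-angle coherent
  scattering is therefore under-forward-peaked at high Z.
* SNR values depend on voxel size and event count through counting noise;
  compare SNRs only between materials of the same run.
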