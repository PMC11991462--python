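# The six study materials.
#
# Densities and elastic moduli are the authoritative study inputs (composite
# densities are carried verbatim; they are not derived from the rule of
# mixtures).  Composite compositions are expressed as mixtures and expanded
# at load time: 20 wt% filler in a PEEK matrix (repeat unit C19H12O3).
#
# Bone is the ICRP cortical-bone composition at 1.85 g/cm3; its 0.01 wt% Zn
# trace is folded into Ca because the photon-data library covers 12 elements.
materials:
  - name: bone
    density_g_cm3: 1.85
    weight_fractions:
      H: 0.047234
      C: 0.144330
      N: 0.041990
      O: 0.446096
      Mg: 0.002200
      P: 0.104970
      S: 0.003150
      Ca: 0.210030
  - name: PEEK
    density_g_cm3: 1.32
    elastic_modulus_GPa: 4.0
    formula: C19H12O3
  - name: PEEK-HA
    density_g_cm3: 1.68
    elastic_modulus_GPa: 5.2
    mixture:
      matrix: PEEK
      filler_name: hydroxyapatite
      filler_formula: Ca10(PO4)6(OH)2
      filler_density_g_cm3: 3.16
      filler_weight_fraction: 0.2
  - name: PEEK-BaSO4
    density_g_cm3: 1.52
    elastic_modulus_GPa: 5.0
    mixture:
      matrix: PEEK
      filler_name: barium sulfate
      filler_formula: BaSO4
      filler_density_g_cm3: 4.5
      filler_weight_fraction: 0.2
  - name: PEEK-Bi2O3
    density_g_cm3: 3.84
    elastic_modulus_GPa: 10.5
    mixture:
      matrix: PEEK
      filler_name: bismuth oxide
      filler_formula: Bi2O3
      filler_density_g_cm3: 8.9
      filler_weight_fraction: 0.2
  - name: PEEK-Ta
    density_g_cm3: 4.65
    elastic_modulus_GPa: 11.0
    mixture:
      matrix: PEEK
      filler_name: tantalum
      filler_formula: Ta
      filler_density_g_cm3: 16.65
      filler_weight_fraction: 0.2
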