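# Named TEVC bench solutions, salts expanded to fully dissociated ions (mM).
# Buffers/chelators/polymers are neutral components and do not enter the
# ionic strength.  k_selectivity is the Na-selectivity recipe with KCl
# substituted mole-for-mole (the bi-ionic K+ recipe is conventional, not a
# published composition).
solutions:
  - label: bath_ph7.4
    species:
      - {ion: Na+, z: 1, mM: 140.0}
      - {ion: Ca2+, z: 2, mM: 1.8}
      - {ion: Mg2+, z: 2, mM: 1.0}
      - {ion: Cl-, z: -1, mM: 145.6}
    neutral: [HEPES]
    pH: 7.4
  - label: bath_mes_ph6.0
    species:
      - {ion: Na+, z: 1, mM: 140.0}
      - {ion: Ca2+, z: 2, mM: 1.8}
      - {ion: Mg2+, z: 2, mM: 1.0}
      - {ion: Cl-, z: -1, mM: 145.6}
    neutral: [MES]
    pH: 6.0
  - label: bath_mes_ph4.0
    species:
      - {ion: Na+, z: 1, mM: 140.0}
      - {ion: Ca2+, z: 2, mM: 1.8}
      - {ion: Mg2+, z: 2, mM: 1.0}
      - {ion: Cl-, z: -1, mM: 145.6}
    neutral: [MES]
    pH: 4.0
  - label: na_selectivity
    species:
      - {ion: Na+, z: 1, mM: 140.0}
      - {ion: Ca2+, z: 2, mM: 1.0}
      - {ion: Cl-, z: -1, mM: 142.0}
    neutral: [HEPES]
    pH: 7.4
  - label: k_selectivity
    species:
      - {ion: K+, z: 1, mM: 140.0}
      - {ion: Ca2+, z: 2, mM: 1.0}
      - {ion: Cl-, z: -1, mM: 142.0}
    neutral: [HEPES]
    pH: 7.4
  - label: ca_selectivity
    species:
      - {ion: NMDG+, z: 1, mM: 126.5}
      - {ion: Ca2+, z: 2, mM: 10.0}
      - {ion: Cl-, z: -1, mM: 146.5}
    neutral: [HEPES]
    pH: 7.4
  - label: or2
    species:
      - {ion: Na+, z: 1, mM: 84.5}
      - {ion: K+, z: 1, mM: 2.5}
      - {ion: Ca2+, z: 2, mM: 1.0}
      - {ion: Mg2+, z: 2, mM: 1.0}
      - {ion: HPO4^2-, z: -2, mM: 1.0}
      - {ion: Cl-, z: -1, mM: 89.0}
    neutral: [HEPES, PVP]
    pH: 7.3
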