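# Default Cu-64 decay scheme.
# Branching ratios: beta-minus 40% (endpoint 0.573 MeV, daughter Zn),
# beta-plus 19% (endpoint 0.656 MeV, daughter Ni), electron capture 41%.
# EC relaxation: K-vacancy probability per EC 0.88; Ni K fluorescence
# yield 0.41 (otherwise the vacancy relaxes by Auger emission).
# X-ray lines: per-decay fractions as printed in standard compilations;
# sampling uses their relative weights.
# Auger spectrum: discrete representative cascade spectrum, mean ~2 keV.
name: Cu-64
beta_minus:
  probability: 0.40
  endpoint_mev: 0.573
  daughter_z: 30
beta_plus:
  probability: 0.19
  endpoint_mev: 0.656
  daughter_z: 28
ec:
  probability: 0.41
  p_k_vacancy: 0.88
  k_fluorescence_yield: 0.41
xray_lines:
  - {label: l,    energy_kev: 0.85, per_decay_fraction: 0.005}
  - {label: ka1,  energy_kev: 7.48, per_decay_fraction: 0.094}
  - {label: ka2,  energy_kev: 7.46, per_decay_fraction: 0.048}
  - {label: kb1,  energy_kev: 8.27, per_decay_fraction: 0.011}
  - {label: kb3,  energy_kev: 8.27, per_decay_fraction: 0.0058}
auger_spectrum:
  energies_kev: [0.11, 0.74, 0.84, 6.25, 7.46]
  weights:      [0.2966, 0.25, 0.20, 0.2284, 0.025]
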