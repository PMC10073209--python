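standoff_mm: 0.0
layers:
  - tissue: scalp
    thickness_um: 500.0
    permittivity: 3056.0
    conductivity_S_per_m: 0.0009
  - tissue: skull
    thickness_um: 1000.0
    permittivity: 1246.0
    conductivity_S_per_m: 0.0203
  - tissue: dura
    thickness_um: 300.0
    permittivity: 2360.0
    conductivity_S_per_m: 0.5010
  - tissue: arachnoid
    thickness_um: 75.0
    permittivity: 3013.0
    conductivity_S_per_m: 0.0650
  - tissue: brain
    thickness_um: 890.0
    permittivity: 6683.0
    conductivity_S_per_m: 0.1056
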