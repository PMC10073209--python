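topology: circular
inner_diameter_mm: 20.0
outer_diameter_mm: 65.0
turns: 7
wire_width_mm: 3.0
wire_height_mm: 2.0
turn_gap_mm: 0.2
current_A: 1000.0
voltage_V: 500.0
frequency_Hz: 20.0
label: mouse_coil
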