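# Generic stand-in for a clinical figure-8 device (two 70 mm lobes).
topology: figure8
inner_diameter_mm: 50.0
turns: 10
wire_width_mm: 1.0
wire_height_mm: 2.0
turn_gap_mm: 0.0
current_A: 5000.0
voltage_V: 2000.0
frequency_Hz: 20.0
label: human_coil_generic
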