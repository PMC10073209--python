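# minitms

Desk-scale design and dosimetry toolkit for miniaturized rodent TMS coils.

It covers the full workflow of sizing and validating a small flat-spiral
stimulation coil:

- **Coil design** — flat-spiral (Wheeler) inductance, mean-radius parameter
  and centre flux-density estimate from a compact coil spec.
- **Field solver** — exact Biot–Savart fields of filamentary loop windings
  (complete elliptic integrals), |B| maps on observation planes, peak-field
  distance sweeps, focality metrics (persistent-peak count and FWHM area),
  and a Neumann partial-inductance cross-check.
- **Head phantom** — layered murine tissue stack (scalp, skull, dura,
  arachnoid, brain) with quasi-static induced E-field via the azimuthal
  vector potential, plus drive calibration to a target cortical E value.
- **Thermal estimate** — lumped Joule-heating model (orderings and scaling
  laws only; not an FEM replacement).
- **Synthetic measurements + statistics** — seeded gaussmeter-style
  replicate readings per device and distance, and a one-way ANOVA panel
  comparing human-coil, mouse-coil, simulation and measurement groups.

Units everywhere: lengths mm, currents A, flux density T, E-field V/m.

## CLI

All stages are exposed as `minitms` subcommands; with no `--coil` argument
the bundled reference design (7-turn, 20 mm bore, 1 kA) is used. Example
configs live in `configs/`.

```bash
minitms design                                    # L, A, peak B as JSON
minitms simulate-field --distance 5 --spacing 1   # |B| map CSV + focality
minitms sweep --distances 0,2,5,8,10              # peak B vs distance
minitms compare-coils                             # circular vs figure-8
minitms induce-efield --calibrate-to 136.1452     # E-field profile CSV
minitms thermal --current 500 --duty 0.01         # lumped heating report
minitms synth-measure --n 5 --seed 42 --out meas.csv
minitms compare-stats --measurements meas.csv
minitms run-all --out bundle --seed 1             # everything + summary.json
```

`minitms run-all` writes design.json, field-map/sweep/E-field CSVs (each
with a metadata header: version, config hash, seed), the synthetic
measurement panel, the ANOVA panel and a summary JSON with the headline
numbers. Reruns with the same seed are byte-identical.

## Notes on modelling choices

- Each turn is idealized as a filamentary loop at its centreline radius;
  the rectangular conductor cross-section enters via the geometric-mean-
  distance equivalent wire radius (inductance) and a near-wire evaluation
  clamp (fields).
- The figure-8 comparison defaults to voltage-matched drive: the figure-8
  winding has roughly twice the inductance, so it carries half the current
  when driven from the same stimulator. Pass `--equal-current` to
  `compare-coils` for the equal-lobe-current variant.
- The induced E-field uses the quasi-static approximation (tissue does not
  perturb B; E = ω·A_φ for axisymmetric coils, no charge-accumulation
  term). Layer permittivities are carried in the data model but do not
  enter this computation.
- The effective angular frequency standing in for the stimulator pulse
  spectrum is recovered by calibration against a target cortical E-field,
  not assumed.
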