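# nanopierce

Analysis and simulation toolbox for AFM cell-membrane penetration
experiments: force–distance curve analysis (Hertz stiffness fitting,
penetration force-drop detection, curve staging), per-condition insertion
statistics, and a quasi-static finite-element model of a conical tip
indenting a prestressed membrane supported by a cross-linked filament
network.

Because no instrument data accompany this kind of experiment, the package
includes a first-class synthetic-curve generator (`nanopierce.synth`) that
produces seeded approach traces with the four-stage morphology
(baseline → elastic rise → force drop(s) → substrate stiffening) and full
ground-truth labels, so every downstream stage is testable end to end.

## Modules

| module                  | purpose |
|-------------------------|---------|
| `nanopierce.synth`      | seeded synthetic force–distance curves with ground truth |
| `nanopierce.analysis`   | contact-point detection, Hertz fitting, force-drop detection, A–B slope |
| `nanopierce.stats`      | condition summaries (insertion rate, force/displacement/time), histograms, strain |
| `nanopierce.mechanics`  | prestressed beam-network + membrane FE indentation, tensioned-beam closed form |
| `nanopierce.io`         | curve CSV format (`#` key=value header + two columns) |
| `nanopierce.pipeline`   | generate → analyze → summarize → simulate report bundle |
| `nanopierce.cli`        | `nanopierce` command-line interface |

Units at every interface: piezo position and depth in nm, force in nN,
spring constant in N/m, speed in µm/s, stress/modulus in Pa.

## CLI

```sh
# generate a seeded batch of synthetic curves with ground truth
nanopierce simulate-curves --n 60 --seed 1 --penetration-probability 0.6 --out curves/

# analyze them (contact point, events, slope, Hertz fit for spherical tips)
nanopierce analyze curves/curve_*.csv --out analysis.json

# one condition-summary row
nanopierce summarize analysis.json --strain 20 --out summary.csv

# indentation mechanics midline profile (with / without prestress)
nanopierce fem-indent --travel 100 --out profile.csv
nanopierce fem-indent --no-prestress --travel 100 --out profile_nopre.csv

# full pipeline (5 default conditions, 60 curves each, plus FE stage)
nanopierce report --seed 1 --out report/
```

`nanopierce report --config cfg.yaml --out report/` accepts a YAML/JSON
configuration (per-condition generator parameters, analysis thresholds,
FE mesh/prestress). Outputs are plain CSV/JSON, carry the configuration
hash and seed, and are bit-identical across reruns.

## Notes

- The FE solver replaces the original explicit-dynamics scheme with
  quasi-static linearised increments (material + geometric stiffness);
  published absolute stress values are therefore matched qualitatively,
  not numerically.
- Tip–membrane contact is a growing Winkler-type coupling between the
  blunted-cone surface and the nodes in its footprint, which is
  mesh-convergent and keeps the prestressed/unprestressed comparison
  meaningful at the contact centre.
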