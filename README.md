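# morphoswitch

Computational framework for a two-signal, mutual-inhibition ("exclusive
receiver") gene circuit that interprets diffusible signal gradients:

- **`circuit_model`** — ODE model of the circuit variants (receiver,
  exclusive receiver, relay), Hill regulatory functions, inducer
  derepression, stiff-capable single-cell integration and a vectorised
  many-cell integrator.
- **`bistability`** — multi-start Newton equilibrium finding with
  Jacobian-eigenvalue classification, pseudo-arclength continuation with
  saddle-node (fold) detection and polish, bistable-region maps in
  (C6, C12) space, and the in-silico conditioning/exposure hysteresis
  protocol.
- **`spatial`** — 1D reaction-diffusion simulation (Crank–Nicolson
  diffusion with no-flux boundaries and exact discrete mass conservation,
  operator-split intracellular reactions) of antiparallel transient
  gradients and of relay circuits that self-organise a secondary gradient.
- **`boundary`** — kymograph normalization, equal-fluorescence boundary
  tracking, and the static / moving / not-present (S/M/N) classification
  with the 10%-of-domain displacement rule.
- **`inference`** — ratiometric promoter-activity extraction (F/RFP in the
  exponential OD window) and staged parameter inference: sensing/synthesis
  parameters on receiver data first, repression parameters second with the
  shared subset frozen.
- **`synthetic_data`** — ground-truthed generators for plate-fluorometer
  grids, conditioning/exposure flow-like samples with cell-to-cell
  variability, and analytic kymograph fixtures.

## CLI

```sh
morphoswitch simulate --c6 37 --c12 100 --t-end 10 --out traj.csv
morphoswitch bistability --grid 12x12 --c6-range 1:1000 --c12-range 1:10000 --iptg 10 --out map.csv
morphoswitch hysteresis --conditioning C6 --grid 12x12 --out hyst.csv
morphoswitch spatial --avg-c6 200 --avg-c12 2000 --t-end 24 --out fields.csv
morphoswitch relay --primary C6 --source-conc 40000 --out relay.csv
morphoswitch classify --in fields.csv --stable-fraction 0.10
morphoswitch synth plate|flow|kymo --seed 1 --out data.csv
```

Parameter files are JSON (`ParamSet.to_json` / `--params p.json`); the
default calibrated parameter set is baked in and re-derivable with
`python scripts/calibrate.py` (add `--search` to re-run the original grid
search).

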