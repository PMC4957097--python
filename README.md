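# turgorkit

Toolkit for studying how small-osmolyte mixtures (KCl, D-glucose,
L-glutamine) generate and sustain turgor in a plant-cell-inspired osmotic
actuator. It implements:

- **`turgorkit.mixtures`** — non-ideal Van 't Hoff osmotic-potential
  estimation (`Pi = sum_k gamma_k M_k R T`), the measured/estimated potential
  ratio, the osmolyte association degree derived from the osmotic deficit,
  and glucose anomer-fraction arithmetic.
- **`turgorkit.association`** — a mass-action model of a single 1:1:1:1
  K+/Cl-/D-Glc/L-Gln complex: speciation by bisection, calibration of the
  association constant against a target degree, effective osmotic potential,
  and dilution curves exhibiting the cooperative buffering effect
  (`Pi_eff(lambda) * lambda` increases with dilution when complexes are present).
- **`turgorkit.actuator_sim`** — Kedem–Katchalsky-style ODE simulation of the
  osmotic actuator in free-piston (constant pressure) and bulging-disk
  (turgor) modes, with per-solute reflection coefficients and diffusive leak,
  optional association coupling, characteristic-time estimation, and a
  fixed-step RK4 oracle integrator.
- **`turgorkit.synthetic_data`** — synthetic cryo-osmometry replicates,
  quantized/clipped pressure traces, and piston-displacement traces, plus
  least-squares recovery harnesses for the membrane water permeability and
  the association degree.
- **`turgorkit.cli` / `turgorkit.io`** — a `turgorkit` command-line pipeline
  with YAML configs and provenance-stamped CSV output.

## CLI

```sh
turgorkit table1                      # derived osmometry statistics (packaged mixtures)
turgorkit estimate --ratio 5:12:3 --total 1.0
turgorkit speciate --mixture M2 --degree 18 --dilutions 1,2,4
turgorkit simulate --mixture M2 --mode turgor --duration 4ts --nondim --out trace.csv
turgorkit simulate --mixture KCl --mode piston --duration 4h --out piston.csv
turgorkit synth --kind osmometry --mixture M1 --seed 1 --out osm.csv
turgorkit recover --kind association --seed 1
```

Mixture definitions (the model cytosols M1–M2b plus the 1.5 M KCl reference)
ship as `src/turgorkit/data/mixtures.yaml`; pass `--mixtures my.yaml` to use
your own. Model parameters can be overridden with `--set key=value`
(e.g. `--set T=293.15`).

## Notes on defaults

- Estimator defaults: T = 300.15 K, phi_KCl = 0.90, i_KCl = 2, gamma_Glc = 1,
  gamma_Gln = 1.96 (calibrated constant; a closed-form ionisation model can
  be plugged in via `OsmoticModelParams.gamma_gln_hook`).
- Actuator defaults: V0 = 3 mL, S_OM = 1 cm^2, alpha_OM = 3e-13 m/s/Pa,
  sigma = 0.6 (salt ions) / 0.99 (D-Glc) / 1.0 (L-Gln), with the bulging-disk
  stiffness back-solved so the KCl reference pressurizes on a one-minute
  characteristic time.
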