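# myoforce

Tools for estimating muscle tendon force from activation, contractile-element
(CE) length and CE velocity, and for comparing two estimator families on the
same data:

* a two-element **Hill-type muscle model** (contractile + parallel elastic
  element) whose six parameters (force-length width `W`, maximum shortening
  velocity `v_max`, force-velocity curvature `A_rel`, eccentric amplification
  `g_max`, PEE stiffness and slack length) are fitted by **CMA-ES** on the
  mean squared normalized-force error;
* **per-timepoint feed-forward neural networks** (1-3 hidden layers, 5-300
  nodes, relu/tanh/sigmoid) selected by a seeded hyperparameter search on a
  chronological 80/20 train/validation split.

The package also provides the full preprocessing chain (zero-phase 30 Hz
high-pass, rectification, 6 Hz low-pass EMG envelope; scaling to the average
peak activation of the highest-speed trials; 23.6 ms excitation-contraction
delay; force normalization by PCSA x 0.29 N/mm^2), a seven-metric evaluation
suite with bespoke peak detection/alignment and rise/fall-time procedures,
force-length / force-velocity curve extraction from trained estimators, and a
synthetic gait dataset generator so the entire pipeline is testable offline.

## Layout

| module | contents |
| --- | --- |
| `myoforce.hill` | closed-form Hill model (`force_length`, `force_velocity`, `pee_force`, `hill_force`) |
| `myoforce.fit` | `mse_objective`, `fit_cmaes`, `refit_width_only` (CMA-ES in `myoforce.cmaes`) |
| `myoforce.preprocessing` | EMG chain, activation scaling/delay, force normalization, z-scoring |
| `myoforce.nn` | train/validation split, hyperparameter search, per-timepoint prediction |
| `myoforce.metrics` | peak detection/matching, rise/fall times, R^2, per-trial reports |
| `myoforce.curves` | FL/FV curve probing with extrapolation flags, `curve_summary` |
| `myoforce.synthetic` | multi-bird/two-muscle synthetic trial generator (history effects, obstacle strides, scale errors) |
| `myoforce.experiments` | head-to-head and leave-one-bird-out studies across the four test scenarios |
| `myoforce.io` | CSV trial tables + JSON/YAML manifests; column-mapping adapter for external recordings |

## CLI

```bash
myoforce simulate --config cfg.yaml --seed 1 --out data/synthetic
myoforce fit-hill --trials data/synthetic/manifest.json --bird bird1 --muscle LG --trial 0 --seed 1 --out fit.json
myoforce train-nn --trials data/synthetic/manifest.json --muscle LG --repeats 5 --seed 1 --out models/
myoforce evaluate --measured trial.csv --estimated est.csv --f-max 8.7 --fs 1000 --out report.json
myoforce curves --hill-params fit_params.json --out curves.csv
myoforce reproduce-small --seed 1 --out small_study.csv
myoforce reproduce-loo --exclude-bird bird1 --seed 1 --out loo_study.csv
```

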