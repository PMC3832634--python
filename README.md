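# limbscale

Allometric scaling of limb inertial properties in quadrupedal mammals.

As animals get bigger, do their limbs stay geometric scale models of each
other, or do they become disproportionately "swing-heavy"? `limbscale`
provides the full analysis chain for answering that question from raw
measurements to composed biomechanical predictions:

- **Pendulum-based inertial properties** — recover limb mass, center of
  mass, moment of inertia (MOI), radius of gyration, and natural
  frequency from two-scale weighings and compound-pendulum periods,
  including mounting-bar subtraction and an optional large-amplitude
  period correction.
- **Model II (SMA/RMA) allometry** — standardized major axis regressions
  of log trait on log body mass, with exact confidence intervals, tests
  of a slope against a null value, and likelihood-ratio common-slope /
  Wald common-elevation comparisons between groups.
- **Geometric-similarity null models** — the isometric predictions as
  exact rationals (length 1/3, mass 1, MOI 5/3, frequency −1/6, ...)
  derived by dimensional composition, never typed in as decimals.
- **Exponent algebra** — compose scaling exponents through physical
  identities (MOI = mass + 2·radius; angular acceleration = force + arm
  − MOI) with worst-case confidence-limit propagation.
- **Phylogenetic comparative methods** — Pagel's λ by maximum likelihood
  with profile confidence intervals, phylogenetic signal in regression
  residuals, and λ-PGLS regression, under divergence-time or unity
  branch lengths.
- **Synthetic data** — Yule tree simulation, Brownian body masses,
  power-law traits with phylogenetically structured residuals, forward
  pendulum-trial synthesis, and a bundled deterministic 44-species
  fixture.

## Worked example

```python
import numpy as np
from limbscale import bundled_fixture, run_scaling_table, pgls_lambda_regression

table, tree = bundled_fixture()      # 44 species, real body masses,
                                     # synthetic traits, composite tree

out = run_scaling_table(table, "forelimb_moi", 5/3)
print(out.iloc[0][["slope", "slope_ci_low", "slope_ci_high", "classification"]])
# slope 1.953, CI 1.871–2.039 -> positive_allometry vs the isometric 5/3

fit = pgls_lambda_regression(
    dict(zip(table["species"], np.log10(table["forelimb_moi"]))),
    dict(zip(table["species"], np.log10(table["body_mass"]))),
    tree,
)
print(f"PGLS slope {fit.slope:.3f}, lambda {fit.lambda_estimate.lam:.3f}")
# PGLS slope 1.855, lambda 0.831
```

The `examples/` directory holds five narrative scripts, one per
capability; each runs in seconds with no arguments:

```bash
python examples/01_pendulum_inertia.py      # raw trial -> inertial properties
python examples/02_scaling_regression.py    # SMA tables vs isometry
python examples/03_phylogenetic_signal.py   # lambda, residual signal, PGLS
python examples/04_acceleration_exponents.py  # exponent composition
python examples/05_simulation_recovery.py   # ground-truth recovery
```

## Command line

```bash
limbscale accel --limb hind
# hindlimb angular-acceleration exponent -0.48 (limits -0.66, -0.30)

limbscale simulate --seed 7 --out-dir sim/          # synthetic dataset + truth
limbscale rma --data sim/species_means.csv --trait hindlimb_moi \
    --null-slope auto:moi --out rma.csv             # SMA table
limbscale compute-inertia --trials trials.csv --out props.csv
limbscale report --config analysis.yaml             # full pipeline -> CSVs
```

Exit codes: 0 success, 2 validation/schema error, 3 numerical failure.

## Layout

```
src/limbscale/       library (inertial, allometry, null_models, exponents,
                     phylo, simulate, io, report, cli, constants, data/)
tests/               unit, property-based and acceptance tests
examples/            narrative example scripts
scripts/acceptance.py  headline-result JSON generator
docs/methods.md      methods note
```
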