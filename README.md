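# fermkin

Kinetics of batch alcoholic fermentation under **byproduct inhibition**:
simulation, calibration, and model comparison for the modified Monod model
in which the secondary metabolites of yeast glucose fermentation (glycerol,
acetic acid, succinic acid) feed back on growth.

## The problem

Classical Monod kinetics describe yeast growth on a limiting sugar,

```
mu(S) = mu_max * S / (K_s + S),
```

but ignore the minor fermentation products that accumulate alongside
ethanol.  In long campaigns — and especially in continuous processes where
ethanol is selectively removed — glycerol and short-chain organic acids can
build up to levels that measurably slow and eventually stop growth.
`fermkin` implements a modified Monod model in which a lumped byproduct
pool `Z` multiplies the maximum growth rate by an inhibition factor
`f(Z) ∈ [0, 1]`:

```
mu(S, Z) = mu_max0 * S / (K_s + S) * f(Z),        f(0) = 1,  f(Z >= Z_m) = 0,
```

with three candidate inhibition families (linear `1 − Z/Z_m`, parabolic
`1 − (Z/Z_m)²`, and a Luong-type power law `(1 − Z/Z_m)^K_z`), and the
state variables coupled through constant yield coefficients:

```
dX/dt =  mu(S, Z) X          (biomass)
dS/dt = −mu(S, Z) X / Y_xs   (glucose)
dP/dt = −Y_ps dS/dt          (ethanol)
dZ/dt = −Y_zs dS/dt          (byproducts)
```

The calibrated defaults are `mu_max0 = 0.244 h⁻¹`, `K_s = 11.5 g/L`,
`Z_m = 60 g/L`, `K_z = 0.83` (power-law family), and average yields
`Y_xs = 0.28`, `Y_ps = 0.42`, `Y_zs = 0.0442 g/g`.

The package is aimed at bioprocess modellers who want to (a) simulate
batch runs with and without byproduct inhibition, (b) fit the inhibition
law and yield coefficients to their own data, and (c) score competing
kinetic models against observed time courses with the usual descriptive
statistics (MSE, RMSE, summed absolute deviation, R²).

## Worked example

```python
import numpy as np
import fermkin as fk

ref = fk.reference_dataset()                 # calibrated constants
initial = fk.BatchState(t=0, X=1.0, S=100.0, P=0.0, Z=0.0)

traj = fk.simulate_batch(initial, ref.params, ref.yields, t_end=72, dt=0.01)
print(f"final state: X={traj.final.X:.2f}  P={traj.final.P:.2f} "
      f"Z={traj.final.Z:.3f} g/L")
print(f"fermentation time (99% sugar consumed): "
      f"{fk.fermentation_time(traj):.2f} h")
print(f"extra time vs classical Monod: "
      f"{fk.model_delay(ref.params, ref.yields, initial):.2f} h")

obs = fk.generate_mu_vs_z(ref.params, np.arange(0, 56, 5))   # noise-free
sel = fk.select_inhibition_family(obs, ["linear", "parabolic", "exponential"])
print("best inhibition family:", sel.best.summary())
```

prints

```
final state: X=29.00  P=42.00 Z=4.420 g/L
fermentation time (99% sugar consumed): 17.74 h
extra time vs classical Monod: 0.36 h
best inhibition family: family=exponential  mu_max0=0.244 1/h  Z_m=60 g/L  K_z=0.83  R^2=1.0000  converged
```

The final concentrations are the stoichiometric endpoints
(`X0 + Y_xs·S0`, `Y_ps·S0`, `Y_zs·S0`); inhibition delays completion of the
100 g/L batch by about 0.36 h relative to the classical model, and the
delay grows with the initial sugar level.  The family selection recovers
the generating power law exactly on noise-free data, with the linear and
parabolic alternatives ranked below it.

## Command line

```sh
fermkin simulate --out traj.csv                  # calibrated defaults
fermkin generate --kind mu-vs-z --noise-sd 0.05 --seed 1 --out obs.csv
fermkin fit-inhibition obs.csv --out ranking.csv
fermkin estimate-yields endpoints.csv
fermkin compare observed.csv --out report.csv    # modified vs classical
```

All tabular I/O is comma-separated UTF-8 text with units in the header
(`time_h, biomass_g_L, glucose_g_L, ethanol_g_L, byproduct_g_L`; empty
cells mark missing measurements).  Run configuration is a single JSON file
(see `examples/calibrated.json` for the full schema with the calibrated
parameter set); `--seed`, `--dt`, `--family` and `--threshold` override it
per run.

## Documentation

See `docs/methods.md` for the model assumptions, parameter meanings,
numerical choices, what the synthetic-data generators do and do not
emulate, and known limitations.
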