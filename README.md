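# nosco

Complementary non-uniform sampling and refocusing analysis for serial 2D
NMR titration data.

## The problem

Quantifying how a ligand binds an isotopically labelled protein by NMR
requires a titration series of 2D heteronuclear correlation (HSQC-type)
spectra at increasing ligand-to-protein ratio `x = c_L / c_P`.  Under fast
exchange each affected signal moves along a binding isotherm,

    nu_I(x) = nu_I,0 + f(x, K_D) * delta_nu_I,
    f(x, K_D) = [K_D + (1+x) c_P - sqrt((K_D + (1+x) c_P)^2 - 4 c_P^2 x)]
                / (2 c_P),

where `f` is the bound protein fraction, `K_D` the dissociation constant
and `delta_nu_I` the saturation chemical-shift-perturbation (CSP)
amplitude in Hz for dimension `I` (15N or 1H).  Recording the full series
conventionally multiplies spectrometer time by the number of titration
points and may exceed the lifetime of an unstable protein.

This package implements a complementary-sampling shortcut: the full
indirect-dimension grid of `N1` t1 increments is partitioned into `n_x`
disjoint schedules, one per titration point (e.g. 256 increments -> 8
schedules of 32 points, a 12.5% sampling level each), so the *entire
series* costs one spectrum's worth of increments.  Co-processing the
resulting pseudo-3D matrix yields a single projected 2D spectrum in which
binding-shifted peaks appear smeared, because their frequencies change
with t1 through the schedule's x(t1) mapping.  Each smeared peak is then
refocused by searching the parameter triple {delta_nu_N, delta_nu_H, K_D}
that minimizes

    | max FT[S_NS * S_C] - max FT[S_P] |,
    S_C(t1, t2) = exp(-i 2 pi f(x(t1), K_D) (delta_nu_N t1 + delta_nu_H t2)),

i.e. the unit-modulus correction signal that collapses the smear back onto
the reference (apo) line shape `S_P`.  The search uses a particle-swarm
global optimizer (default 1000 particles, 10 iterations, 5 independent
runs) because the objective is multimodal; per-peak uncertainties come
from repeating the optimization (default 20 repeats) on identical data,
and per-residue `K_D` values are averaged into the final estimate.

A forward simulator generates ground-truth pseudo-3D datasets in two
stock regimes — `"weak"` (K_D = 9 in mM units, 8 ratios, the CSP curves
never approach their plateau) and `"moderate"` (K_D = 130 in uM units, 6
ratios, lower signal-to-noise, heavier line broadening) — and a
conventional pipeline (fully sampled spectrum per titration point, peak
tracking, least-squares isotherm fitting) provides the reference analysis
for comparison.

## Worked example

```python
import numpy as np
from nosco import core
from nosco.simulate import (make_scenario, simulate_nosco_dataset,
                            simulate_reference_fid)

scen = make_scenario("weak", seed=3, snr=np.inf)   # noiseless demo
peak = scen.peaks[0]                                # residue "G10"
data = simulate_nosco_dataset([peak], scen.acq, scen.scheme,
                              scen.schedule_set, scen.binding)
ref = simulate_reference_fid([peak], scen.acq)
problem = core.make_problem(data, ref, *scen.windows[peak.label],
                            scen.bounds, window=None)

truth = scen.binding[peak.label]
print(core.nosco_objective(truth, problem) / problem.s_p_height)
# 3.1374504735729484e-16   <- at the true parameters the correction
#                             signal cancels the smear exactly

res = core.pso_minimize(problem, core.PsoConfig(
    n_particles=100, n_iterations=10, n_runs=3, seed=1))
print(res.best_params.k_d, res.best_params.delta_nu_n, res.best_params.delta_nu_h)
# 8.535076802841099 25.35753610112996 -33.53580634548799
```

The swarm recovers the simulated truth (K_D = 9 mM, delta_nu_N = 25 Hz,
delta_nu_H = -35 Hz) to within a few percent; the residual scatter
reflects the flat K_D-amplitude trade-off valley of the height-matching
objective discussed in `docs/methods.md`.

The same analysis from the shell:

```
nosco simulate --scenario weak --seed 3 --out pseudo3d.npz
nosco coprocess pseudo3d.npz --out spectrum.npz
nosco fit --scenario weak --seed 3 --outdir run1
nosco conventional --scenario weak --seed 3 --outdir run1
nosco report run1/results_nosco.csv run1/results_conventional.csv --units mM
```

The report prints the per-method aggregate (mean +/- standard deviation
over residues) and writes log-scale K_D and CSP-amplitude plots per
residue.

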