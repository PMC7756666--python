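# Methods

## Signal model and assumptions

A well-separated 2D correlation signal is modelled as a one-sided complex
exponential in both time dimensions,

    S(t1, t2) = A exp(i 2 pi nu_N t1 + i 2 pi nu_H t2) exp(-R2_N t1 - R2_H t2),

sampled on grids t_k = n / SW_k (States-type hypercomplex detection is
collapsed to a single complex channel; synthesis uses exp(+i 2 pi nu t),
so analysis is the forward FFT).  Binding is single-site and in fast
exchange: the observed frequency is the population-weighted average
nu_0 + f(x, K_D) delta_nu with the bound fraction f from the mass-action
quadratic, evaluated in the cancellation-free form
f = 2 c_P x / (b + sqrt(b^2 - 4 c_P^2 x)), b = K_D + (1+x) c_P.
Intermediate/slow exchange, multi-site binding and exchange-induced line
broadening are out of scope; dilution is modelled as a per-titration-point
amplitude factor A(x) in (0, 1] and a matching reduction of c_P.

## Complementary sampling and co-processing

`make_complementary_schedules` partitions the N1-point t1 grid uniformly
at random (shuffle, deal round-robin) into n_x disjoint schedules bound to
the titration ratios in increasing order; the whole series then costs one
full grid of increments (per-schedule level exactly 1/n_x).  An
undersampled mode draws only a fraction per schedule (optionally biased
toward early t1 with exponential weights) as a hook for compressed-sensing
reconstruction, which is not implemented.  Uniform assignment is the
least-assumption default; nothing in the method requires a density law
because every index is measured exactly once in partition mode.

Co-processing fills each t1 row from its owning titration point, divides
out that point's dilution factor, then applies the apodization window
(default cosine-squared; rectangular for tests that need exact heights),
zero-fills 4-fold in both dimensions and FFTs.  Stationary signals
reproduce the reference spectrum identically; shifted signals smear.

## Refocusing objective

For one catalogued peak the refocusing problem compares the co-processed
non-stationary signal against the separately acquired apo reference:

    minimize over {dnN, dnH, K_D}:  | max FT[S_NS * S_C] - max FT[S_P] |,
    S_C = exp(-i 2 pi f(x(t1), K_D) (dnN t1 + dnH t2)).

Two implementation decisions that were genuinely open:

* The max is taken over the peak's rectangular frequency window (the
  window must contain the full smear trajectory), not the whole spectrum,
  so neighbouring signals cannot capture the maximum.
* The correction is applied to the assembled full-grid FID rather than to
  the inverse transform of the extracted region submatrix.  On the
  acquisition grid the x(t1) map is exact and S_C cancels the
  non-stationary phase *pointwise*, so at the true parameters the
  corrected signal equals the reference signal to machine precision; a
  band-limited region signal only achieves this approximately.  Region
  extraction (and band isolation back onto the acquisition grid) is
  available in `nosco.spectral` for crowded spectra.

Peak height is the maximum of the real part (the simulator is zero-phase
by construction); a magnitude mode exists for unphased data.

## Optimizer

Canonical constriction-coefficient particle swarm: inertia 0.729,
cognitive = social = 1.49445, velocities clamped to half the box width,
reflecting boundaries, uniform random initial positions *and* velocities
(zero initial velocities were tried and converge measurably worse within
10 iterations), K_D searched on a log10 scale.  Defaults are 1000
particles, 10 iterations, 5 independent runs (best run wins, ties to the
earliest); all randomness derives from one seed via spawned
SeedSequences, so results are reproducible.  `estimate_uncertainty`
repeats the whole minimization (default 20 times) with derived seeds on
identical data and reports per-parameter means and standard deviations;
multimodal objectives (e.g. the sign-symmetric CSP solutions of
weakly-shifted peaks) surface as inflated repeat spread rather than being
averaged silently.  A dense log-spaced grid search over the same box
serves as a brute-force oracle in tests.

### Degeneracy of the height-matching objective

The objective above is *exactly* zero on a two-dimensional manifold of
parameter triples whenever the reference peak lies off the zero-filled
frequency grid.  The discrete spectral maximum then undershoots the
continuous coherent maximum, and slightly mis-refocused parameter triples
(larger K_D with proportionally larger amplitudes, the classic
weak-binding trade-off) reproduce the same discrete height.  In practice
this limits single-peak parameter recovery to a few percent in the CSP
amplitudes even on noiseless data, and to roughly a factor-of-order-one
band in K_D at realistic noise — which is why per-residue averaging and
repeat-based errors are part of the method.  A local descent (available
as `PsoConfig(polish=True)`) converges onto an arbitrary point of this
manifold and therefore *increases* parameter scatter on noisy data; it is
off by default and intended for low-noise use only.

## Conventional comparison pipeline

One fully sampled 2D spectrum per titration point is simulated, each
catalogued peak's position is measured (grid argmax, parabolic sub-grid
interpolation, then a polish that maximizes the real part of the windowed
FID's continuous-frequency transform — parabolic interpolation alone
leaves a position bias of order half a zero-filled grid step, which the
flat weak-binding isotherm amplifies into tens of percent of K_D), and
the two-dimensional shift-vs-x curves are fitted jointly to the isotherm.
The two linear parameters per dimension (nu_0, delta_nu) are profiled out
analytically for every trial K_D, so the fit reduces to a 1-D search in
log K_D: a 256-point log-spaced scan (a dense version of multi-start)
followed by bounded scalar refinement.  A fit is flagged unidentifiable
when the signal's total excursion is below 3x the configured shift noise
floor; peaks that drop below 5x the spectral noise floor at some
titration point lose that point with a flag.

## Synthetic scenarios

The simulator is the package's ground-truth source; scenario defaults are
package choices emulating two experimentally motivated regimes:

* `weak` (mM units): K_D truth 9, c_P = 0.5 diluted linearly to 0.85x,
  x = 1...32 over n_x = 8 ratios (bound fraction stays below 0.9 — no CSP
  curve reaches its plateau), 64x64 grid, SW 600x900 Hz, four peaks with
  CSP amplitudes 12-40 Hz of both signs, R2 = 4 1/s, default time-domain
  SNR (amplitude / noise sigma) 20.
* `moderate` (uM units): K_D truth 130, c_P = 80 diluted to 0.75x,
  x = 0.5...16 over n_x = 6 ratios, 96x48 grid, SW 700x1000 Hz, three
  peaks, heavier relaxation (R2 = 12 1/s), default SNR 8.

What the simulator does *not* emulate: spectral crowding and peak overlap
beyond a handful of signals, exchange broadening that varies with x,
solvent/artifact signals, and hypercomplex phase errors.  Passing
recovery tests therefore demonstrate the estimator's behaviour under the
stated signal model, not robustness to every pathology of real spectra.

## Numerical choices

* Zero filling 4x in both dimensions; apodization cosine-squared unless a
  test requires exact height preservation.
* Frequency axes are carrier-centered Hz, ascending, fftshift convention;
  indices (including nuslist files) are 0-based; region windows are
  half-open index slices.
* Aliasing is an error by default (simulated frequencies must stay inside
  +/- SW/2), with an explicit opt-in to wrap.
* The bound-fraction discriminant is clamped at 0 with a warning if
  floating-point cancellation drives it slightly negative.
* Ties across swarm runs are broken by the earliest run index; degenerate
  zero-width search boxes return the single point with a warning.

## Problem sizes in the acceptance script

`scripts/acceptance.py` uses the stock scenario grids (64x64 weak,
96x48 moderate), 8 weak and 6 moderate recovery replicates at the reduced
swarm (100 particles, 10 iterations, 5 runs), a 32x32 grid-oracle problem
with a 20x20x20 reference grid, and the 256-point/8-schedule partition
arithmetic.  These sizes were chosen so the whole script reruns a
complete, from-scratch analysis in a few minutes on one CPU while keeping
every reported quantity a genuine recomputation.

## Known limitations

* Partition mode requires n_x to divide N1; pad or trim the grid
  otherwise.
* The refocusing estimator inherits the height-matching degeneracy
  described above; K_D from a single peak is indicative only, and the
  per-residue average with its standard deviation is the quantity to
  report.
* External data ingestion is limited to the package's .npz containers
  plus nuslist/CSV text formats; vendor format adapters are a future
  extension.
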