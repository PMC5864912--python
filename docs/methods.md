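# Methods

## The model

A fibrous-porous scaffold specimen is idealized as a long circular cylinder
(length/radius ≈ 10) of a biphasic mixture: an incompressible, linearly
elastic, transversely isotropic solid skeleton (fibres along the cylinder
axis `x3`, isotropy in the transverse plane) saturated by an incompressible
fluid that moves relative to the solid by Darcy drag. Relaxation of the
axial force after a stretch is entirely poroelastic — fluid is drawn in
through the lateral surface until the drained equilibrium is reached; the
solid itself has no intrinsic viscosity.

Under a uniform axial strain history `eps(t)` the problem reduces to a
single radial consolidation equation for the radial displacement
`u(r, t)`:

    du/dt = (k C11) d/dr[(1/r) d(r u)/dr] - (deps/dt) r/2,   0 <= r <= a,

with `u(0) = 0` and the traction-free, free-draining boundary condition
`C11 u' + C12 u/a = -C13 eps(t)` at `r = a` (pore pressure `p(a, t) = 0`).
Here `C11, C12, C13, C33` are the axisymmetric stiffness coefficients of
the skeleton (kPa) and `k` its Darcy permeability. Porosity drops out of
the reduced problem; it is carried as metadata and used only as the
interpolation coordinate of the prediction layer.

The measured quantity is the load intensity — the cross-section-averaged
axial total stress `P(t) = (2/a^2) ∫ sigma_zz^t r dr` — which evaluates to

    P(t) = (2 C13 - C11 - C12) u(a, t)/a + (C33 - C13) eps(t).

### Stiffness from engineering constants

The four engineering constants `(E1, E3, nu21, nu31)` enter through exact
numerical inversion of the transversely isotropic compliance
(`S11 = 1/E1`, `S12 = -nu21/E1`, `S13 = -nu31/E3`, `S33 = 1/E3`), not
through transcribed closed forms. Inversion guarantees the two identities
that anchor the staged estimation procedure,

    nu31 = C13/(C11 + C12),      E3 = C33 - 2 C13^2/(C11 + C12),

to rounding error; the equivalent corrected closed forms
(`C12 = E1 (nu21 + nu31^2 E1/E3) / [(1 + nu21) Delta1]`,
`C33 = E3 (1 - nu21)/Delta1`, `Delta1 = 1 - nu21 - 2 nu31^2 E1/E3`) serve
as an independent oracle in the test suite. Admissibility requires the
compliance to be positive definite, equivalently `Delta1 > 0`; violations
raise a named error.

### Analytic series

Homogeneous modes of the consolidation operator are `J1(alpha_n r/a)` with
`alpha_n` the ordered positive roots of

    alpha J0(alpha) = beta J1(alpha),     beta = 1 - C12/C11 ∈ [0, 1).

Each root is bracketed between consecutive zeros of `J0` (one root per
interval), solved by Brent's method and polished by a Newton step to a
characteristic-equation residual below 1e-12.

The step-strain relaxation function was derived twice, by independent
routes that agree to 1e-13:

* Laplace transform and residues, giving the closed form used in the code:

      G(t)/eps0 = E3 + Σ_n B_n exp(-alpha_n^2 t / t_g),
      B_n = 2K / (alpha_n^2 + beta^2 - 2 beta),
      K = (C11 + C12 - 2 C13)^2 / (2 C11);

* Sturm–Liouville expansion of the isochoric initial state
  `u = -eps0 r/2` about the drained state `u = -nu31 eps0 r` (this route
  also supplies the displacement mode amplitudes used to reconstruct the
  radial fields).

`t_g = a^2/(k C11)` is the gel diffusion time; all modal relaxation times
are `t_g/alpha_n^2`. The limits are closed forms: `G(∞) = E3` (drained)
and `G(0+) = M0 = C33 - 2 C13 + (C11 + C12)/2` (isochoric). Ramp-and-hold
loading follows by Duhamel superposition, evaluated termwise in closed
form (factored exponentials, stable for `t >> tau_n`); a step protocol is
evaluated analytically, never as a small-ramp limit. The peak of `P`
always falls at the end of the ramp, so rate sweeps use the closed-form
value there.

**Truncation.** The default series length is 20 roots. For ramp protocols
this is converged to ~1e-6 relative except within a fraction of a second
of the ramp-end kink, and the final value is stable to <1e-9 under
doubling the root count. One caveat is intrinsic, not numerical: the
isochoric initial state violates the drained boundary condition, so the
modal sum rule `Σ B_n = M0 - E3` — exact for the full series — converges
only like 1/N (1.8% at 20 terms, 0.1% at ~400). Quantities at `t = 0+`
therefore use the closed-form `M0`, never the truncated sum.

### Finite-difference oracle

An independent method-of-lines solver validates the series: conservative
second-order fluxes on a uniform grid in `r/a` (201 nodes by default), a
ghost node for the Robin condition, L'Hôpital regularization at the axis,
and stiff BDF time integration with a banded Jacobian sparsity pattern.
`P(t)` is recovered by trapezoidal quadrature of the axial stress — a
different route than the boundary formula the series uses. The two engines
agree to better than 0.001% in relative sup-norm on the reference
parameter sets (the guaranteed bound is 0.5%), and the solver shows clean
second-order spatial convergence. A step protocol is integrated as a ramp
of duration `1e-4 t_g`. The discrete mass-balance residual (boundary
influx vs dilatation rate) is limited by one-sided differentiation of the
discrete pressure across the drained boundary and decreases roughly
linearly with the mesh (0.7% / 0.3% / 0.09% at 101 / 201 / 801 nodes);
the sup-norm agreement of `P(t)` is the binding accuracy statement.

## Signal conditioning

Raw traces are sensor volts at 100 samples/s; conversion to kPa is affine
(`(signal - offset) · gain / area`). The dominant interference is the
periodic signature of the stepper motor; it is removed with a degree-1
Savitzky–Golay filter whose window covers exactly one motor period:
`frame = ramp_time · sample_rate / n_cycles`, rounded to the nearest odd
integer (ties upward — a symmetric window must be odd; this is the closest
realizable window to the exact rule, which can be fractional). A degree-1
window reproduces the linear ramp exactly, attenuates a matched-period
sinusoid by >90%, and handles the trace ends by polynomial extrapolation
of the terminal windows so the trace is not shortened.

The two independently fixed parameters come from here: `E3` as the mean of
the last 1000 stress samples divided by the total strain (the drained
equilibrium relation `E3 = P(∞)/eps0`), and `nu31 = 0.24`, a configuration
constant taken from image-based displacement analysis of the equilibrium
state rather than estimated from the force trace.

## Parameter estimation

`(E1, nu21, t_g)` are estimated by bounded trust-region-reflective least
squares (scipy `least_squares`, TRF) against the full ramp + hold trace,
with `(E3, nu31)` held fixed. Defaults:

| parameter | start | bounds | rationale |
|---|---|---|---|
| `E1` (kPa) | `E3/2` | (0.1, 100) | fibre direction ≈ twice transverse stiffness |
| `nu21` | 0.7 | (0, 0.999), `Delta1 > 0` enforced at evaluation | admissibility |
| `t_g` (s) | `5.4 · t63` | (0.1, 1000) | slowest mode is `t_g/alpha_1^2`, `alpha_1^2 ≈ 5.4`; `t63` = time for 63% of the peak-to-equilibrium drop |

The staged strategy (default) first fits `(E1, t_g)` with `nu21` held at
its start, then releases all three from that point. Points with
`Delta1 <= 0` receive a continuous penalty so the trust region backs away
rather than faulting.

**Filter-aware residuals.** When the data have been Savitzky–Golay
smoothed, the model is passed through the same window inside the residual
(`filter_frame`). The filter is linear, so this cancels its bias exactly —
without it, the window's rounding of the ramp-end kink systematically
displaces the estimates. The workbench and CLI enable this automatically
whenever they smooth.

**Identifiability — a real limitation.** On noiseless data the round trip
is essentially exact (<0.1% on all three parameters for both reference
sets). But the single-trace problem is sloppy: with `(E3, nu31)` fixed,
`(E1, nu21)` enter `P(t)` only through the amplitude factor `K` and the
boundary coefficient `beta`, and the shape information carried by `beta`
is of order 0.04% of the peak for a 1%/s ramp. Concretely, for any `E1`
between 0.5 and 30 kPa there is a `(nu21, t_g)` pair whose response
differs from the reference curve by under 6e-4 kPa RMS. Any realistic
noise therefore moves the global least-squares optimum far along this
valley (typically to a bound), even though the fitted curve remains
visually perfect (r² > 0.999). The practical consequences: estimates of
`E1` and `nu21` from a single ramp-and-hold tension trace should be
treated as start-point- and bound-conditioned rather than data-determined;
restoring identifiability requires fitting several strain rates jointly or
a near-step ramp, both outside the present per-trace estimator contract.
Passing noiseless tests demonstrates correctness of the forward model and
optimizer, not robustness of single-trace estimation on real data.

## Synthetic data

The generator emulates the bioreactor: analytic response plus a motor
sinusoid plus Gaussian sensor noise, emitted as volts with a calibration
sidecar so the full conversion pipeline is exercised. Defaults: motor
1 Hz with amplitude 5% of `E3·eps0`, sensor sigma 2% of `E3·eps0` —
a deliberately low signal-to-noise regime with the periodic component
dominant, chosen so the filter's contribution is visible. The motor phase
is drawn from the seed so recovery tests cannot be phase-tuned. The full
study is the cross of the two reference porosities (50%, 70%) with strain
rates 0.25, 0.5, 1 and 3%/s at 10% strain and a 100 s hold; one global
seed fans out to per-trace sub-seeds via `SeedSequence([seed, index])`.

What the generator does **not** emulate: sensor drift, quantization,
clamp slippage or pre-tension artefacts, non-uniform sampling, and any
inelasticity of the scaffold itself. Green recovery tests on synthetic
data therefore bound the estimation error from noise and filtering only.

## Prediction layer

Peak/equilibrium ratios increase strictly with strain rate and are capped
by the isochoric bound `M0/E3` (≈1.30 at 50% porosity, ≈1.50 at 70%);
historically reported ratios above this bound (up to 1.86 / 2.30) are
incompatible with linear poroelasticity under the same equilibrium
parameters, and the package reports its own computed ratios instead.
Between estimated porosities the parameters `(E1, E3, nu21, t_g)` are
interpolated componentwise linearly (`nu31` held fixed); every interpolant
between the two reference sets remains admissible. Outside the anchor
hull the default is to warn and clamp. The peak-load summary surface
`P_pk = m x + n + a e^{b y} + c e^{d y}` is fitted by nonlinear least
squares with porosity `x` as a fraction (percent makes the historical
coefficients give negative forces) and rate `y` in %/s; the two
exponential terms are exchange-symmetric, so the labelling is fixed by the
initial guess (one decaying, one nearly flat term).

## Numerical and design choices

* Units: stresses and moduli in kPa throughout; permeability converted at
  the boundary (`t_g k C11 = a^2` with `C11` in N/m²).
* Sign convention: tension positive, pore pressure positive in
  compression, total stress `sigma^t = sigma^E - p I`; the reduced
  equations are convention-independent.
* Bessel roots: brentq with machine-precision brackets plus Newton polish;
  at `beta = 0` the tabulated `J0` zeros are returned directly.
* Degenerate inputs raise named errors: non-positive-definite compliance,
  `beta` outside [0, 1), root sets built for a different `beta`, frames
  that are even or longer than the trace, traces shorter than the
  equilibrium tail, missing calibration sidecars.
* Reproducibility: study outputs are JSON/CSV with sorted keys; a report
  records the package version, the global seed and a hash of the
  canonical config, and reruns are byte-identical.
* Peak location: analytic (end of ramp); verified against dense scans and
  the finite-difference solver.

## Problem sizes

Defaults used by the test suite and the acceptance script: 100 Hz
sampling of a 10 s ramp + 100 s hold (11 001 samples per trace), 20-root
series, 201-node finite-difference grid, 20-seed noise ensembles. These
sizes reproduce all reported quantities comfortably on a single CPU.
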