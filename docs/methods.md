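# Methods

## Model

The package simulates a layer of tumor cells embedded in a porous matrix
inside a long microfluidic channel with slow interstitial flow. Cell
motion is modeled as a velocity-jump process: cells move ballistically at
a fixed speed and reorient at Poisson times with rate 1/T, drawing a new
orientation from an exponential kernel on the unit sphere,
F(ξ) ∝ exp[s·(ξ−η)], peaked along the local stimulus direction η with
concentration |s|. An isotropic space-jump (random-motility) process is
superimposed, contributing ordinary diffusion with Péclet number Pec.
Taking moments of the kinetic equation — and discarding the second-order
orientation moment, which is smaller by the ratio of the cells' mean free
path to the layer width — closes the macroscopic system in four fields:
volume fraction φ, flux ψ, and the downstream-minus-upstream
sub-population density φ_diff and flux ψ_diff. The sub-population split is
available precisely because the macroscopic equations derive from a
velocity-space density; a conventional mixture model would not carry it.

The stimulus closure combines, in nondimensional 1D form,

* tensotaxis: Darcy drag with Carman–Kozeny permeability g(φ)=(1−φ)³/φ²
  and mixture incompressibility (u_f = 1/(1−φ)) give the upstream-pointing
  term −K φ²/(1−φ)⁴;
* autologous chemotaxis: a chemokine secreted by cells, advected by the
  flow and consumed by cell-surface receptors, taken quasi-steady and
  advection-dominated, gives a(x) = 1 − exp(−Da·∫φ) and the
  downstream-pointing term M·Da·φ·exp(−Da·∫φ).

The chemokine's own diffusion is deliberately omitted (the purely
advective limit); including it would smooth the gradient and weaken the
chemotactic cue somewhat. Proliferation, death, volume exclusion, and
higher-dimensional geometry are out of scope; the model is meant for
sub-day time scales and low-to-moderate volume fractions.

Orientation-kernel averages supply the three source functions: the
Langevin function G(s) = coth s − 1/s (mean orientation → flux source),
tanh(s/2) (hemisphere density difference → φ_diff source) and
1 − tanh(s/2)/s (hemisphere speed difference → ψ_diff source). A
brute-force spherical quadrature of the kernel (`kinetic_moments`)
validates all three identities to ≤1e−10 and is kept independent of the
closed forms.

## Parameters

| group | meaning | default | notes |
|---|---|---|---|
| φ̄ | initial peak volume fraction | varies (0.01–0.5) | Gaussian layer φ̄·exp(−x²) |
| Da | chemokine consumption/advection ratio | varies (0.01–10) | L*β_d*/(U_f*V_c*) |
| U | cell/fluid speed ratio | 0.003 | 10 μm/h vs 1 μm/s |
| Pec | flow vs cell random motility | 300 | U_f*L*/D_c* |
| T | relaxation time / transit time | 10 (alt. 100) | τ* ≈ 17 min (resp. ≈ 3 h) |
| K | tensotactic strength | 10 | l_c*ϖ*U_f*/k_H* |
| M | chemotactic strength | 10 | l_c*χ*a_eq*/L* |

Dimensional anchors (length 100 μm, fluid speed 1 μm/s) make the time unit
L*/U_f* = 100 s, so t = 1000 is about one day. All dimensional inputs are
reduced to μm and s internally before groups are formed, because
literature values mix per-hour and per-second units; human-readable
conversions round half-up (1000 s → 17 min).

## Numerics

Space: second-order central differences on a uniform grid over [−X, X]
with X = 30 and N = 1201 by default (dx = 0.05); N is kept odd so x = 0 is
a node. No-flux far-field conditions (∂φ/∂x = 0, ψ = 0, mirrored for the
sub-population fields) are imposed at ±X; the stimulus integral treats −X
as −∞, which is checked by requiring φ at the edges to stay below 1e−8 at
every output time.

Time: the stiff Pec⁻¹ diffusion operators are advanced by backward Euler
via pre-factorized sparse tridiagonal solves; advection, sources and
relaxation by forward Euler, with the stimulus evaluated from φ at the
start of each step. The default dt = 0.01 sits far below the explicit
stability bound min(2T, dx/U) (a conservative factor of 0.2 is applied by
`stable_dt`). A fully explicit variant is retained purely for
cross-checking the splitting error; the two agree to O(dt). With the
Neumann closure the discrete diffusion operator conserves the trapezoid
mass identically; measured drift over t ∈ [0, 1000] is ~1e−12 relative.

Degenerate-input policy: φ undershoots in (−1e−10, 0) are clamped to zero
and counted (roundoff), anything more negative aborts as a blow-up; the
run also aborts if max φ ≥ 0.95, where the (1−φ)⁻⁴ tensotactic factor
makes the model stiff and physically dubious.

The source functions switch to truncated series for |s| < 0.02. The
threshold balances the cancellation error of coth(s) − 1/s (relative error
≈ 6ε/s², about 1e−11 at the switch) against the series truncation error
(≈ 3s⁶/4725, about 2e−13 there), so both branches carry at least ten
significant digits where they meet.

Kernel moments use fixed-order Gauss–Legendre quadrature in μ = cos θ
(order 256; the azimuthal integral is analytic for axisymmetric weights
and a periodic trapezoid rule otherwise). The kernel is sharply peaked at
μ = 1 for large |s|; order 256 resolves |s| ≤ 100 to better than 1e−12.

## Diagnostics and the critical condition

N_diff = ∫φ_diff dx measures the net downstream-minus-upstream cell
content. Integrating the φ_diff equation over the channel gives the exact
relaxation ODE dN_diff/dt = (R − N_diff)/T with R = ∫φ·tanh(s/2) dx — note
the 1/T applies to the source term as well, since it enters the field
equation as T⁻¹(φ tanh(s/2) − φ_diff); the reconstruction of N_diff from
R(t) agrees with the directly integrated value to well under 1% and
tightens as O(dt). Feature trajectories (peak and half-maximum positions)
use parabolic sub-grid refinement and linear interpolation respectively,
since node-resolution argmax is visibly quantized at dx.

The numeric critical density is the Brent root of φ̄ ↦ N_diff(t_eval; φ̄),
each evaluation a full PDE run. Sweeps default to a coarser grid
(N = 601, dt = 0.02; dt = 0.05 for t_eval = 1000) — the reported roots
move by under 2% on refinement, below the root tolerance of interest. The
scan assumes N_diff crosses from positive (dilute, chemotaxis-dominated)
to negative (dense, tensotaxis-dominated) once over the bracket and warns
if the sign pattern disagrees.

The small-stimulus analysis solves the same transition from the diffusive
profile φ = (φ̄/b)·exp(−x²/b²), b = √(1+4t/Pec): setting the origin
stimulus to zero yields the transcendental critical equation. The
formally subdominant quartic and exponential factors are kept exactly as
they stand, because they capture the interior maximum of φ̄_cr(Da) at
moderate Da. Root finding brackets by a monotone scan and polishes with
Brent's method (xtol = 1e−12); the result is independent of the scan
resolution to 1e−10. The inverse problem (critical time at fixed φ̄)
returns `None` when the layer is chemotaxis-dominated already at t = 0,
meaning downstream migration prevails at all times.

## What the tests show — and what they do not

All inputs are generated analytically or by the simulator itself; there is
no experimental data path. Passing tests therefore establish internal
consistency (closures vs quadrature oracle, PDE vs analytic limits, PDE vs
ODE identity, numeric vs asymptotic critical curves) and reproduction of
the model's qualitative regimes (downstream at φ̄ = 0.2; upstream→
downstream transition at φ̄ = 0.4; φ̄_cr ordering in time and relaxation
rate). They do not validate the constitutive choices against real cells:
the 1D geometry idealizes the device, chemokine diffusion is neglected,
and K, M are order-of-magnitude estimates.

Two quantitative notes from running the model at the canonical parameter
set:

* the maximum scaled average cell velocity for φ̄ = 0.2, Da = 0.5, T = 10
  over t ∈ {100, 500, 1000} converges to 10.7% of the single-cell speed
  (grid- and scheme-independent to three digits), fractionally above the
  nominal "up to 10%" figure-level description of this regime;
* at Da = 0.5 the t = 1000 transition lies beyond the physical seeding
  range (N_diff stays positive up to φ̄ = 0.7), so time-ordering of the
  critical density is demonstrated at Da = 0.1, where both roots exist.

Test problem sizes are scaled to the structure each check probes: analytic
limits and scheme comparisons run on N ≈ 150–600 grids and horizons of
t ≤ 100–1000, while the velocity-bound and regime checks use the full
production resolution (N = 1201, dt = 0.01).
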