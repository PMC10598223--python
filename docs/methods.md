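# Methods

## Physical model

Synovial fluid (SF) is modelled as a pseudo-plastic (shear-thinning)
power-law fluid in steady, laminar, incompressible two-dimensional
boundary-layer flow over a flat, porous, convectively heated surface — an
idealization of flow near an articular surface. A transverse magnetic field
of strength parameter `M` acts on the (weakly conducting) fluid, a weak
stagnation-point straining of the free stream is carried by the parameter
`ε`, and wall transpiration is carried by `f_w` (suction `f_w > 0`,
injection `f_w < 0`). The base fluid may carry a dilute dispersed phase
(volume fraction `φ`) whose effect enters only through the coefficient
ratios

    A1 = μ_bf/μ_f (Brinkman),     A2 = (ρCp)_bf/(ρCp)_f (linear),
    A3 = k_bf/k_f (Maxwell–Garnett), A4 = ρ_bf/ρ_f (linear),
    σ_bf/σ_f (Maxwell),

all equal to 1 at `φ = 0`. The heating is conjugate: a hot fluid at
temperature `T_f` with film coefficient `h_f(x) = c·x^(−1/(n+1))` warms the
wall from below, which after similarity reduction becomes the single
dimensionless convective parameter `a`.

## Similarity reduction

With `η = (U∞^(2−n)/(ν_f x))^(1/(n+1)) y`,
`ψ = (U∞^(2n−1) ν_f x)^(1/(n+1)) f(η)` and
`θ = (T − T∞)/(T_f − T∞)`, the PDEs reduce to

    (|f″|^(n−1) f″)′/(A4·A1) + f f″/(n+1) − M²(σ_bf/σ_f)(f′−1) − ε² = 0
    (A3/(Pr·A2)) (|f″|^(n−1) θ′)′ + f θ′/(n+1) = 0

with `f(0) = f_w`, `f′(0) = 0`, `f′(∞) = 1`,
`θ′(0) = −(a/A3)(1 − θ(0))`, `θ(∞) = 0`.

Three formulation switches (`FormulationFlags`) exist because the sign of
the energy equation, the sign/placement of `A3` in the wall condition, and
the `|f″|^(n−1)` weighting of the thermal diffusivity each admit a literal
alternative reading. The defaults are the *corrected* set above: they are
the only combination consistent with the dimensional wall balance
`−k_bf ∂T/∂y = h_f (T_f − T_w)` and with a temperature field that decays to
the free stream with `θ(0) ∈ (0, 1]` (for `n = 1` the alternative sign
yields `θ″ = +(Pr/2) f θ′`, which has no decaying solution). The literal
`as_printed` modes are retained for auditability only; the shooting path
and the default test matrix exercise the corrected branch.

The magnetic parameter `M` is treated purely as a dimensionless input and
never computed from a field strength: the dimensional definition available
for it is x-dependent and omits the conductivity, so no consistent
similarity-constant evaluation exists.

`ε` enters only through the non-decaying source `ε²` in the momentum
equation. Consequently no `η → ∞` limit exists for `ε > 0`; the far-field
conditions are imposed at a finite truncation only (see below). Runs with
`ε > 1` are possible but outside the validated branch: the printed
stretching-sheet narrative for large `ε` is not compatible with the no-slip
condition `f′(0) = 0`, so no stretching-wall variant is implemented.

## Numerical solution

State vector `(f, f′, g, θ, q)` with `g = |f″|^(n−1) f″` and
`q = |f″|^(n−1) θ′`, solved by adaptive collocation
(`scipy.integrate.solve_bvp`, residual tolerance `tol = 1e−8`, default
initial mesh of 101 nodes, cap 200 000).

* **Shear recovery.** `f″ = sign(g)|g|^(1/n)` is exact for `n ≤ 1` (its
  slope at `g = 0` is finite there). For dilatant fluids (`n > 1`) the
  slope diverges at the edge of the boundary layer where the shear
  vanishes, so the smooth blend `g (g² + δ^(2n))^((1−n)/(2n))` with floor
  `δ = delta_reg` is used; its relative bias away from zero is
  `O(δ^(2n)/g²)` and halving the floor moves `f″(0)` by far less than the
  collocation tolerance. The default `delta_reg = 1e−8` also floors `|f″|`
  inside the thermal diffusivity weight. Dilatant runs resolve the layer
  edge on a finite mesh only with a looser floor; the dilatant tests use
  `delta_reg = 1e−5`, where the induced bias is ~1e−8 on `f″(0)`.
* **Domain truncation by continuation.** Shear-thinning profiles approach
  the free stream algebraically (for `n = 0.5`, roughly `1 − f′ ~ η^(−3)`),
  so a fixed `η_max` cannot serve all cases. Starting from `η_max = 10`,
  the domain is doubled (re-using the previous solution as the initial
  guess, extended by its free-stream asymptote) until both `f″(0)` and
  `θ′(0)` move by less than `10·tol` between successive domains, with a
  budget of 8 doublings (`η_max ≤ 2560`); exhausting the budget raises an
  explicit `ConvergenceError` carrying the last deltas. For `ε > 0`
  continuation is skipped (no limit exists) and the run is solved at the
  configured `η_max`, recorded in the diagnostics.
* **Initial guess.** `f = f_w + η + e^(−η) − 1` satisfies every velocity
  boundary condition exactly; the temperature amplitude comes from the
  wall-condition linearization `θ(0) = μ/(1+μ)`, `μ = a/A3`. A single
  seeded randomized restart (5% perturbation) is attempted only if the
  first Newton iteration fails; in the validated parameter range it never
  triggers, so results are seed-independent and bit-reproducible.

## Independent verification (shooting)

A second route recomputes the wall values without collocation. The momentum
channel does not involve temperature, so `f″(0)` is found by a bracketed
Brent root find on the far-field velocity residual of a high-order
initial-value integration (DOP853, rtol 1e−11), with early termination once
`|f′| > 5` to keep wrong-guess integrations finite. The energy channel is
linear in `θ′`, so one superposition integration from `θ′(0) = −1` gives
`J = −∫θ′` and

    θ(0) = μJ/(1 + μJ),   θ′(0) = −μ(1 − θ(0)),   μ = a/A3.

This is algebraically the same fixed point as a two-unknown shooting Newton
iteration, but has no failure modes on the monotone branch. The two routes
share only the right-hand-side assembly; their wall values agree to better
than 1e−10 across the test grid (`n ∈ {0.5, 1}`, `M ∈ {0, 1}`,
`f_w ∈ {−0.5, 0, 1}`), which is the package's main correctness certificate.

## Post-processing conventions

* Friction and heat-transfer groups exactly as defined:
  `Cf·Re^(1/(n+1)) = −2·A1·f″(0)|f″(0)|^(n−1)` (sign preserved, no absolute
  value) and `Nu·Re^(−1/(n+1)) = −A3·θ′(0)`.
* `Re_x = U∞^(2−n) x^n / ν_f` — the combination inside the similarity
  variable — is used only for the internal dimensional/similarity
  round-trip identity, which holds to ~1e−15 relative on all fixtures. In
  the dimensional Nusselt number the driving difference `T_f − T∞` is used;
  this is the reading under which the similarity identity is exact (using
  the wall excess `T_w − T∞` instead would rescale `Nu` by `1/θ(0)`).
* `δ99` is the first `η` with `f′ = 0.99` (monotone linear interpolation);
  `δT99` the first `η` where `θ` falls to 1% of its wall value (0 for an
  adiabatic wall). The wall-normal velocity is reconstructed analytically,
  `v = −(1/(n+1)) (U∞^(2n−1)ν_f/x^n)^(1/(n+1)) (f − η f′)`, whose wall
  trace is the transpiration law `V_w(x)` and which satisfies continuity
  with `u = U∞ f′` identically (verified by grid-refined central
  differences in the tests).

## Rheology layer

The Cross model `η = η₀/(1 + (cγ̇)^d)` and its high-shear power-law limit
`η = η₀/(cγ̇)^d` map onto `(K, n) = (η₀/c^d, 1 − d)`. The power-law branch
overshoots the Cross model by exactly `1/(1 + (cγ̇)^d)` of its own value —
an identity the tests check to machine precision. Classification uses
strict thresholds (mechanical: `K > 0.03`, `n < 0.85`; inflammatory:
`K < 0.01`, `n > 0.85`); boundary values fall in the intermediate class,
matching the clinical "middle ground" category. Packaged reference tables
carry the literature ranges per patient population; the OA/RA zero-shear
rows are typographically corrupt in the source and are flagged
`reliable = false`, excluded from quantitative use. Units: Pa·s, s, 1/s;
the Mark–Houwink output `0.036·Mv^0.78` is reported as a dimensionless
intrinsic-viscosity number.

## Default conditions and problem sizes

Defaults mirror the study conditions: `Pr = 6.2`, `φ = 1%` (water carrier
with a copper dispersed phase from the standard room-temperature property
table; `Pr` is an independent input, not recomputed from the properties),
`ε = 0.01`, `a = 0.1`. The packaged sweep scenarios cover
{n, M, ε, a} × {suction `f_w = 1`, injection `f_w = −0.5`, impermeable}
with a pseudo-plastic base `n = 0.5`. Test problems run at the default
tolerances; the self-convergence report solves each fixture on
{tol, tol/10, tol/100} × {η_max, 2·η_max} and reports stabilized digits
(≥ 6 on the ε = 0 fixtures).

## What the tests do and do not show

All quantitative checks are internal: oracle equivalence, algebraic
identities, degenerate limits, qualitative monotonicities (wall temperature
rising and saturating with `a`; suction thinning both layers; velocity
rising pointwise with `M`). No patient-derived flow measurements exist in
the pipeline, and the flat-plate similarity geometry ignores curvature of
articular surfaces, cartilage porous-matrix coupling, viscoelasticity and
temperature-dependent viscosity. Passing tests therefore certify the
mathematics and numerics of the stated model, not its clinical fidelity.
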