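# synovia

Boundary-layer simulator for synovial-fluid flow and heat transfer near an
articular surface, treating the fluid as a pseudo-plastic (power-law)
medium in magnetohydrodynamic stagnation-region flow, together with a
steady-shear rheology layer (Cross model, power-law mapping, Mark–Houwink
relation, clinical fluid classification).

It is written for biofluid-mechanics researchers who want a tested,
scriptable implementation of the similarity-reduced model: the governing
ODE system

    (|f″|ⁿ⁻¹ f″)′/(A₄A₁) + f f″/(n+1) − M²(σ_bf/σ_f)(f′−1) − ε² = 0
    (A₃/(Pr A₂)) (|f″|ⁿ⁻¹ θ′)′ + f θ′/(n+1) = 0

    f(0) = f_w,  f′(0) = 0,  f′(∞) = 1
    θ′(0) = −(a/A₃)(1 − θ(0)),  θ(∞) = 0

where `n` is the power-law index (shear-thinning for n < 1), `M` the
magnetic parameter, `ε` the stagnation parameter, `f_w` wall
suction/injection, `a` the conjugate (convective heating) parameter, `Pr`
the base-fluid Prandtl number, and `A₁..A₄`, `σ_bf/σ_f` dilute-mixture
property ratios. The solver is adaptive collocation with automatic domain
continuation, cross-checked against an independent shooting route; outputs
are the wall shear `f″(0)`, wall temperature `θ(0)`, the reduced
skin-friction and Nusselt groups, boundary-layer thicknesses, and fully
dimensional (u, v, T) fields. See `docs/methods.md` for the model's
assumptions and numerical choices.

## Worked example

Shear-thinning suction case at the study's reference conditions
(n = 0.5, M = 0.5, ε = 0.01, f_w = 1, a = 0.1, Pr = 6.2, φ = 1%):

```sh
$ synovia solve --n 0.5 --m 0.5 --epsilon 0.01 --f-w 1 --a 0.1 --out out
f''(0)      = 1.712356
theta(0)    = 0.017277
theta'(0)   = -0.095395
Cf group    = -2.683731
Nu group    = 0.098272
delta99     = 4.9856
deltaT99    = 1.0698
wrote out/solution.csv and out/solution.json
```

Suction steepens the velocity profile (`f″(0) = 1.71` versus 0.332 for the
Newtonian impermeable plate), the weak conjugate heating keeps the wall
only 1.7% of the way to the hot-fluid temperature (`θ(0) = 0.017`), and the
thermal layer (`δT99 ≈ 1.07`) sits well inside the velocity layer
(`δ99 ≈ 4.99`) at Pr = 6.2. The friction group is negative by the sign
convention of its definition (leading −2). The same numbers are available
from Python:

```python
from synovia import ModelParams, build_ratios, solve, water_copper_phases

params = ModelParams(n=0.5, M=0.5, epsilon=0.01, f_w=1.0, a=0.1, Pr=6.2,
                     ratios=build_ratios(water_copper_phases(phi=0.01)))
sol = solve(params)
print(sol.wall.fpp0, sol.wall.nu_group)   # 1.712356... 0.098272...
```

The rheology layer works standalone — e.g. healthy-fluid Cross parameters
(η₀ = 20 Pa·s, c = 10 s, d = 0.75):

```sh
$ synovia rheology --eta0 20 --c 10 --d 0.75 --shear-rate 1
Cross viscosity      = 3.01959 Pa s
power-law viscosity  = 3.55656 Pa s
K = 3.55656 Pa s^n, n = 0.2500
classification       = mechanical
```

`synovia sweep` runs the packaged figure-family sweeps ({n, M, ε, a} ×
{suction, injection, impermeable}) or a YAML-configured set, writing one
tidy CSV per scenario; `synovia fixtures --check` verifies the golden
wall-value fixtures regenerate bit-identically.

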