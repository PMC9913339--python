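# Methods

## Model and assumptions

The package integrates a four-variable ODE for a heterogeneous tumor:
stem fraction `S`, differentiated fraction `D` (both relative to the total
cell count, so `S + D ≤ 1` with the remainder inert), and two chemical
activator densities `a` (stem-division outcome) and `m` (plasticity).
Assumptions inherited from the underlying biology: only stem cells divide;
stem cells are immortal; a division yields on average `2p` stem and
`2(1−p)` differentiated daughters with `p(D,a) = ηa/[(1+ηa)(1+ψD)]`;
differentiated cells die at rate `d` and de-differentiate at the rate
`q(m) = (q₀/2)[1 + tanh((m−m₀)/s_q)]`, a smooth step switching on above
the threshold `m₀`; mitosis is multiplied by the saturation factor
`Υ = tanh((1−S−D)/s_l)`, which is ≈1 away from confluence and 0 at
`S+D = 1`, confining the cell fractions to the physical simplex; the
plasticity signal is produced at rate `γ·exp(−S/S₀)`, i.e. only when the
stem fraction drops to the scale `S₀`.

The activator equation is `da/dt = a[βSa/(1+a) − α_a]`: production is
linear in `S`, quadratic in `a` at small `a` with the `a/(1+a)` factor
saturating the per-capita production for large `a`. Two structural
consequences matter: `a = 0` is invariant (a tumor without activator never
regrows it), and for `βS > α_a` the activator can grow without bound —
the model's representation of runaway stem proliferation, reported as a
`divergence` event.

A built-in identity used as a test oracle: `dS/dt + dD/dt = ΥλS − dD`
holds exactly (one net cell per division; DC death the only loss), for any
parameter values.

## Parameters

All rates are per day; `λ = 1/day` defines the time unit. Shared constants
across all scenarios: `λ = 1`, `ψ = 1`, `S₀ = 0.038`, `m₀ = 0.5`,
`s_q = 0.01`, `s_l = 0.1`. The step widths `s_q`, `s_l` are mathematical
regularizations, not biological quantities; the constructor warns above
0.5 where the step approximation degrades. The per-regime constants
(`α_a`, `α_m`, `β`, `γ`, `η`, `d`, `q₀`) are carried by the scenario
registry (`cscdyn.scenarios.MODEL_ROWS`), one row per studied regime, and
an independent transcription in the test suite guards against copy errors.

Drug reference set: clearance `α_d = 10/day` (decay time ~2.4 h), period
`T = 1 day`, administration time `τ = 0.08 day`, prescribed peak
`χ_max = 1`, action magnitude `Ω₀ = 1`, midpoint `χ₀ = 0.2`, width
`s_χ = 0.05`. The rest period `(T−τ) ≫ 1/α_d`, so carry-over across
periods is `e^{−α_d(T−τ)} ≈ 1e−4` and dose peaks are essentially
identical; a constructor warning fires for schedules that would
accumulate.

## Fixed points and stability

`F1 = (0,0,0,γ/α_m)` always exists and zeroes the field exactly. `F2`
uses the closed forms `m₂ = m₀ + s_q·artanh(2d/q₀−1)`,
`S₂ = −S₀ln(α_m m₂/γ)`, `D₂ = λS₂/d`, valid under `0 < d < q₀` and
`m₂ < γ/α_m`, checked in that order (an artanh argument outside (−1,1) is
reported as non-existence, never raised). The closed form assumes `Υ ≈ 1`;
its residual against the full field is `O(exp(−2(1−S₂−D₂)/s_l))`, below
1e−6 for every shipped regime.

`F3` (the only equilibrium with `a ≠ 0`) solves a cubic with no useful
closed form and is located by multi-start Newton root search. The search
is run on the `Υ = 1` field, because that is the field on which the
existence condition `d > ψα_a/β` and the saddle classification are
derived — and because the root's total `S₃+D₃` can exceed 1. When the
unsaturated root polishes to a genuine full-field equilibrium inside the
simplex (it does whenever it lies far enough from confluence), the
polished interior point is reported and classified with the full-field
finite-difference Jacobian; the `inside_physical_simplex` flag records
which case applies. In both cases F3 is a saddle on every shipped regime.

Stability is classified from the eigenvalues of the analytic Jacobian with
`Υ` frozen at 1 (the approximation under which the analysis is exact at
F1/F2, which sit well below confluence); a central-difference Jacobian of
the full field is the cross-check, agreeing entrywise to ~1e−4 for
`S+D ≲ 0.4`. Labels: `stable` (all real parts < 0), `saddle` (mixed
signs), `unstable` (all > 0); a real part within 1e−10 of zero raises a
non-hyperbolic error rather than guessing. Saddles are unstable; the
`is_stable` helper encodes that.

## Stochastic layer

A chosen rate parameter θ ∈ {λ, d, q₀, η, ψ, α_a, α_m} evolves as an
unbiased Wiener process `dθ = ρ dW` from its base value; `ρ` is specified
relative to the base value by default (realistic band 5–20%, warned
outside). Because the noise is independent of the state, each realization
is an ordinary non-autonomous ODE driven by a pre-drawn parameter path.
The integrator draws the path on a fixed step grid (default `dt = 1e−3 d`)
and advances the state with a Heun (2-stage Runge–Kutta) rule using the
mid-step parameter value; states are clipped to the simplex after each
step. An independent oracle — feeding the recorded path to a high-order
adaptive solver — agrees with the fixed-step route to better than 1e−3
over 10 days, and the zero-amplitude limit reproduces the deterministic
solver to 1e−6.

Bundles run N realizations (seeds `base_seed + i`, so any member can be
reproduced standalone) on a common output grid (default `Δt = 0.05 d`).
Realizations whose parameter leaves `(0, ∞)` are flagged
`nonphysical_parameter`; those whose activator exceeds the divergence
ceiling are frozen and flagged `divergence`. The default policy is
flag-and-report; flagged members are excluded from width fits but kept in
the bundle.

Bundle width: at each grid time, each variable's cross-bundle distribution
is summarized by the unbinned Gaussian maximum-likelihood fit, whose
closed form is the sample mean and the biased (1/N) standard deviation —
so no iterative fitting is involved. The activator `a` is excluded by
default (it is a numerical zero in the colony regimes where widths are
studied). `width_growth_check` fits `σ(t) = c·t + b` by least squares on
`(0, t_max]` and reports slope, R², and "super-linear breakout" times
where σ exceeds the fit by more than 5% of the fitted range — a heuristic
flag, adequate to separate linear from exponential growth, not a formal
test.

## Therapy layer

The dosing level χ(t) is evaluated analytically (piecewise exponentials
chained with exact carry-over; χ = 0 before `t_start`), matching direct
ODE integration to 1e−8 over ten periods. The administration rate can be
given directly (ζ) or derived from a prescribed first-dose peak via
`ζ = χ_max α_d/(1−e^{−α_d τ})`; with carry-over, later peaks exceed
`χ_max` by ~`χ_max·e^{−α_d(T−τ)}` (1e−4 here). The therapy integrator
restarts the adaptive solver at every dosing on/off switch so the
discontinuous forcing never sits inside a step.

Adapter conventions: cytostatic and anti-plasticity actions are clamped at
zero by default (negative mitosis or plasticity rates are nonphysical),
switchable off to study the literal model. The combined
differentiation+cytotoxic therapy replaces the plasticity term by
`q(m) − Ω_diff(χ)` *without* clamping: its negative excursion is the
induced stem differentiation/death flux, which is the point of the
therapy. It is implemented literally as a term proportional to `D`; an
alternative reading proportional to `S` (stem cells being forced to
differentiate) is arguable but not the literal substitution, and is not
implemented.

## Scenarios and initial conditions

Each studied regime is packaged as a named scenario carrying its parameter
row, drug/noise blocks where applicable, a horizon (20 d for convergence
studies, 10 d for width studies — within the relaxation time scale), and a
default initial state. Initial states are repository choices, marked as
such in each scenario's `notes`: the regimes are defined by their
attractors and parameters, and the defaults were selected (by systematic
scan, then verified robust across solver tolerances 1e−6..1e−10) to
exhibit each regime's qualitative outcome class — overshoot, colony
convergence, plasticity bump, tumor-growth paradox, cytostatic rescue and
delay. The paradox and rescue starts necessarily sit near separatrices
(those regimes *are* borderline cases), so the reproducible surface is the
outcome class, not the trajectory.

The width study (`fig3a`) starts exactly on the computed F2 so that all
spread is noise-generated.

## Numerical choices

- Deterministic solver: Dormand–Prince RK45 (`scipy.solve_ivp`), default
  `rtol 1e−8 / atol 1e−10`; end states at `rtol 1e−6` vs `1e−9` differ by
  < 1e−4 on the fixtures.
- Trial states probed by the adaptive solver may leave the simplex; the
  RHS projects them back (clip at 0; renormalize S, D if S+D > 1) instead
  of raising, and *accepted* output states are validated afterwards
  (material violations recorded as a `bound_violation` event; none occur
  on the fixtures).
- Events: `divergence` when `a` crosses a configurable ceiling (default
  1e6, terminal), `extinction` when `S+D` first crosses 1e−6 (recorded,
  non-terminal). Both thresholds are conventions, not model content.
- The multi-start root searches use scipy's Powell-hybrid method with 48–64
  random starts; converged points are projected onto the domain,
  deduplicated at 1e−5, and accepted below residual 1e−8 (1e−10 for F3).
  Stationary points on the saturation boundary `S+D = 1` are artifacts of
  the projection and are filtered out.
- All CSV output is written with 17 significant digits; exported scenario
  YAML round-trips to bit-identical runs.

## What the tests do and do not show

The synthetic scenarios reproduce the *structure* of the studied regimes —
attractors, stability classes, noise response, therapy outcome classes —
under the stated parameter sets. They do not calibrate the model to any
measured tumor data: rates are order-of-magnitude literature values, the
activators are effective one-variable summaries of signalling pathways,
and the noise model is a first-order Wiener idealization whose parameter
can leave the physical range on long horizons (flagged, not modelled).
Quantitative predictions about real tumors are outside what a passing
suite demonstrates.
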