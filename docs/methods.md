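# Methods

## The model and its assumptions

The package computes the two-dimensional flow driven by a ciliated edge in
a semi-infinite watery medium, in the envelope approximation: the cilia
tips, beating with a linear phase lag, are replaced by a continuous wavy
wall whose motion forces the fluid. The key assumptions are

- **Elliptic tip trajectories.** Each tip sweeps an ellipse with horizontal
  semi-axis *a* and vertical semi-axis *βa*; real trajectories deviate
  (forward and backward paths nearly coincide), which should be absorbed
  into an effective *β*.
- **Perfect metachrony.** The phase lag is exactly linear in position,
  giving a wave of constant speed; the computed wall velocity is therefore
  an ideal upper envelope for a real, partially disordered edge.
- **Small amplitude.** The expansion parameter is ε = a/h. Fields are
  expanded to O(ε²); the neglected terms are O(ε³). A warning (not an
  error) is raised when a/h > 0.3 — an intentionally conservative
  threshold, since there is no sharp breakdown point.
- **Stagnant fluid at height h.** Velocity and shear vanish at y\* = h.
  Experimentally h is the one fitted geometric parameter; its physical
  origin (neighbouring clusters, slide friction) is outside the model.
- **Newtonian fluid, no mucus layer.** The model reproduces the *ex vivo*
  preparation, not the in-vivo periciliary-liquid + mucus bilayer.

The flow solution proceeds in two orders. At O(ε) the stream function
satisfies the unsteady Stokes equation `Δ²ψ₁ = α²Δψ₁,t` with a Robin
condition at the wall and free-slip/no-penetration at y = 1. Keeping the
two decaying characteristic modes e^(−ky), e^(−γ₁y) (γ₁ = √(k² + iα²),
principal branch) and matching the wall conditions gives

    A₁ = i (βγ₁/k − 1) / (2 (γ₁ − k)(1 + kφ))
    B₁ = i (1 − β)     / (2 (γ₁ − k)(1 + γ₁φ))

At O(ε²) only the steady (time-averaged) part is computed. Its profile is
`u₂ˢ(y) = A₂y² + B₂y + C₂ − 4α⁴k[...]`, where the bracket holds two
exponentially decaying streaming terms and (A₂, B₂, C₂) follow from three
linear boundary conditions through the constants C = βk + β(1−β)Re γ₁ and
(G₁, G₂, G₃). A₂ is also the steady pressure gradient along the edge. The
oscillatory e^(±2iθ) second-order component is deliberately not computed:
it time-averages to zero and does not affect crossing times at the accuracy
of the rest of the model.

Sign conventions: θ = kx + t, so the metachronal wave travels towards −x
and the steady flow is towards +x for β < β_c = 1 + √2. One printed-formula
ambiguity was resolved against the model's own boundary conditions: the
vertical first-order velocity is v₁ = +2k Im{a₁(y)e^(iθ)}, which reproduces
the wall condition v₁(0) = β cos θ exactly.

## Parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| a (CBA) | beat amplitude (tip-ellipse horizontal semi-axis) | μm | — |
| β | tip-ellipse eccentricity (signed; rotation sense) | — | 0 |
| f (CBF) | beat frequency | Hz | — |
| λ | metachronal wavelength | μm | — |
| φ\* | sliding length of the partial-slip wall | μm | 0 |
| h | stagnation height | μm | 50 |
| ρ, μ | fluid density, viscosity | g/cm³, cP | 1, 1 |
| R, ρ_b | bead radius, density | μm, g/cm³ | 2.25, 1 |

The reference set (a = 8 μm, f = 10 Hz, λ = 10 μm, φ\* = 0, h = 50 μm,
water) gives ε = 0.16, k = 10π ≈ 31.4, α ≈ 0.40 and bead Stokes number
St_k ≈ 7·10⁻⁵. The experimentally relevant regime is k ≥ 10 and α ≲ 0.4,
where the steady profile is parabolic to better than 0.5%.

On amplitude naming: the experimental "CBA" is identified with *a*, the
semi-axis (the full horizontal excursion of a tip is 2a). If a data source
reports the full excursion instead, halve it before use; U₀ scales as a².

On the bead: the Stokes number uses the bead *radius* in the 6πRμ drag law
(a 4.5 μm-diameter polystyrene bead gives St_k ~ 10⁻⁴, consistent only with
the radius reading).

## Numerical choices

- **α = 0 (steady Stokes) limit.** γ₁ → k makes the generic coefficient
  formulas singular; the repeated-root basis {e^(−ky), y·e^(−ky)} is solved
  instead. At α = 0 the streaming forcing (∝ α⁴) vanishes identically, so
  the steady profile is the exact parabola with G₃ = −k − C.
- **Dropped growing exponentials.** The analytic solution keeps only
  decaying modes, so the y = 1 conditions hold up to O(e^(−k)); accuracy
  degrades below k ≈ 5. The finite-difference oracle (below) quantifies
  this: the analytic/FD gap shrinks monotonically as k grows.
- **Bead integration.** Adaptive RK45 (`scipy.integrate.solve_ivp`),
  rtol 10⁻⁸, with terminal events at the window exit x = L and at the wall
  y = 0. The drag ODE is stiff at St_k ~ 10⁻⁴; below St_k = 10⁻³ the
  massless-tracer equation dx/dt = U(x, t) is integrated instead (the two
  agree to < 0.1% at the switch point). The default window is five
  metachronal wavelengths, so crossing times average over whole wave
  periods and the release phase moves V_eff by less than the local
  oscillatory-to-steady ratio.
- **Profile fitting.** `V(y) = U₀·max(0, 1 − y/h)²` by nonlinear least
  squares, multi-started at h ∈ {1.2, 2, 4}·max(y) because (U₀, h) are
  correlated when the data stop short of the stagnation region; points
  beyond h contribute zero model velocity (stagnant fluid) rather than an
  unphysical negative branch. All-zero profiles return a flagged null fit.
  Uncertainty is the Jacobian-based covariance; h may optionally be fixed.
- **Finite-difference oracle.** The first-order amplitude ODE
  `a₁'''' − (2k² + iα²)a₁'' + (k⁴ + ik²α²)a₁ = 0` is solved on [0, 1] with
  second-order centred differences (one-sided closures at the boundaries)
  and a sparse direct solve, enforcing all four boundary conditions exactly
  at the discrete level — including the y = 1 pair the analytic form only
  satisfies asymptotically. This makes it an independent check, not a
  re-derivation; Richardson extrapolation against a half-resolution grid
  estimates the discretisation error. Observed convergence is second order;
  at 513 nodes the analytic/FD L² gap at (k = 10, α = 0.4) is ≈ 0.2%.
- **Tolerances.** Boundary/PDE residual thresholds in the tests
  (10⁻¹⁰–10⁻⁵, scaled by condition-number factors where the coefficients
  are near-degenerate) are chosen to separate algebra errors, which appear
  at O(1), from floating-point and stencil-truncation noise.

## Synthetic data

The generator emulates bead-velocimetry profiles: n equispaced distances in
a chosen fraction of [0, h], effective speeds from either the parabolic law
(`closed_form`) or full tracer integrations through the oscillatory +
steady field (`traced`), plus independent Gaussian noise — relative on
speed (σ as a fraction of U₀, default 5%) and optional absolute noise on
distance. Defaults follow the reference beating set above with n = 20
points over [0.1h, 0.9h]. A seed fixes the draw bit-for-bit, and every
profile is returned with its generating ground truth.

What it does *not* emulate: bead-detection imaging noise, heteroscedastic
tracking error, curved or disrupted edges, out-of-window flow sources, or
bead–bead and bead–wall hydrodynamic interactions. Passing recovery tests
therefore demonstrates the estimator's correctness and noise robustness
under the model's own assumptions, not robustness to those experimental
artefacts — profiles from visibly non-ideal edges must still be screened
out before fitting.

## Problem sizes

The test suite and the acceptance script run at deliberately compact sizes
chosen as the smallest that exercise each property cleanly: Monte-Carlo
recovery uses 200 replicates of 20-point profiles; the law-of-large-numbers
check uses 10⁴ draws; the FD oracle runs at up to 513 nodes; bead tracing
uses windows of 5 wavelengths. Each completes in seconds on one core.

## Known limitations

- Validity degrades for a/h ≳ 0.3 (error O(ε³)) and for k < 5 (dropped
  growing modes).
- φ\* inference assumes the measured U₀ comes from a perfect metachronal
  wave; disorder in the wave and genuine slip are observationally
  confounded in a single U₀ deficit.
- The fitted h is only as meaningful as the stagnation assumption; profiles
  that do not decay towards zero within the sampled range constrain h
  weakly (large U₀–h covariance).
- No Brownian motion, Faxén corrections, or near-wall drag corrections for
  the beads; at St_k ~ 10⁻⁴ and 4.5 μm beads these are negligible relative
  to the 5%-level measurement noise.
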