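# Methods

## Model

`stochsirs` implements a stochastic SIRS epidemic model with nonlinear
incidence and two vaccination routes.  The deterministic skeleton is

    S' = (1-q)Λ − β f(S) g(I) − (d_S + p) S + ε R
    I' = β f(S) g(I) − (d_I + γ) I
    R' = qΛ + p S + γ I − (d_R + ε) R

where Λ is recruitment, q the fraction of new members vaccinated at entry
(moved directly to R), p the vaccination rate of susceptibles, ε the
immunity-loss rate, γ the recovery rate, and d_S, d_I, d_R
compartment-specific removal rates (d_I typically includes disease-induced
mortality).  The incidence rate β f(S) g(I) generalizes the bilinear βSI:
the built-in family is

    f(S) = S / (1 + aS),        g(I) = I / (1 + ωI²),

a saturating force of infection in S and a non-monotone response in I that
captures behavioural inhibition at high prevalence.  Structural assumptions:
f(0)=0, f′≥0, f″≤0; g(0)=0, g′(0)>0, and the chain g′(I) ≤ g(I)/I ≤ g′(0).
The last chain is what the threshold analysis actually uses; it holds when
g(I)/I is non-increasing, which is true of the built-in family.  The
assumption validator checks the chain numerically on a grid (tolerance 1e−9)
and flags functions whose ratio increases, since user-supplied callables
cannot be inspected symbolically.  User-supplied incidence functions must
provide analytic first derivatives; no automatic differentiation is
attempted, because g′(0) and f′ enter the thresholds exactly.

Environmental noise perturbs the transmission coefficient and the three
removal rates through l shared Brownian channels B_j:

    dS = [...]dt − f(S)g(I) Σ_j σ₀ⱼ dB_j − S Σ_j σ₁ⱼ dB_j
    dI = [...]dt + f(S)g(I) Σ_j σ₀ⱼ dB_j − I Σ_j σ₂ⱼ dB_j
    dR = [...]dt − R Σ_j σ₃ⱼ dB_j

The 4×l matrix σ_ij ≥ 0 is the single noise input; row sums of squares
σ_i² = Σ_j σ_ij² and the cross term Σ_j σ₀ⱼσ₂ⱼ are the only combinations the
theory needs.

## Thresholds

With S₀ = Λ[(1−q)d_R+ε]/(d_S(d_R+ε)+p·d_R) the disease-free susceptible
level, and S̄ = Λ/μ, μ = min(d_S,d_I,d_R), the package computes

* R₀ = β f(S₀) g′(0)/(d_I+γ) — deterministic reproduction number;
* R̃₀ = [f(S₀)g′(0)(β+Σσ₀ⱼσ₂ⱼ) − ½f(S₀)²g′(0)²σ₀² − ½σ₂²]/(d_I+γ) —
  noise-corrected threshold: two sufficient conditions for almost-sure
  exponential extinction are (a) R̃₀<1 with σ₀²f(S₀)g′(0) ≤ β+Σσ₀ⱼσ₂ⱼ, and
  (b) σ₀>0 with (β+Σσ₀ⱼσ₂ⱼ)²/(2σ₀²) < d_I+γ+½σ₂²;
* R̄₀ — identical except the quadratic incidence-noise penalty is evaluated
  at f(S̄) instead of f(S₀); since f is nondecreasing, R̄₀ ≤ R̃₀, and both
  collapse to R₀ when σ ≡ 0 (the implementation makes that reduction exact
  in floating point by ordering the products identically).

The persistence/permanence lower bounds on lim inf ⟨I⟩ are implemented for
the special cases in which they are available (f(S)=S with, respectively,
incidence noise off, removal noise off, or equal removal rates d_S=d_R,
d_I=d_S+α).  They take the solution bound (M₀ or S̄) as an explicit argument
where the theory leaves it trajectory-dependent, keeping the operations
deterministic.  The auxiliary function G(I)=I/g(I) and its derivative are
evaluated from the analytic g, g′ on a 4001-point grid including the
endpoint; for the built-in family this reproduces the closed forms
G = 1+ωI², G′ = 2ωI exactly at the grid points.

## Deterministic equilibria

Eliminating R from the stationarity system and adding the S and I balances
yields the exact linear relation S = S₀ − S₁·I with
S₁ = [d_I(d_R+ε)+d_Rγ]/(d_S(d_R+ε)+p·d_R) — the same relation that governs
long-run time averages of the stochastic system.  The endemic equilibrium is
the root of β f(S₀−S₁I) g(I) = (d_I+γ)I on (0, S₀/S₁), found by Brent's
method at xtol 1e−15; the residual of the full vector field at the
reconstructed state is reported and required < 1e−10.  For R₀ ≤ 1 the
operation returns the disease-free state flagged as a fallback.  The ODE
reference integrator is adaptive RK45 at rtol 1e−10 / atol 1e−12.

## Stochastic integration

The integrator is the Milstein-type discretization in which each compartment
receives, per channel, the increment σ_ij ξ_j √Δt + ½σ_ij²(ξ_j²−1)Δt
multiplied by its diffusion factor, with the same N(0,1) draw ξ_j shared by
the three equations within a step (one draw per channel per step, reflecting
the shared Brownian channels).  Numerical notes:

* **Positivity.**  The discrete map can produce negative excursions the
  exact process almost surely never has; by default every component is
  floored at zero after the step and the number of clamp events is recorded
  (`clamp=False` for scheme-fidelity studies).  The I=0 face is absorbing
  (g(0)=0 kills every I term), so a clamped-out epidemic stays out.
* **Strong order.**  The per-channel correction enters with the sign printed
  in the scheme's source, which for the linear-noise channels is opposite to
  the textbook ½bb′(ΔB²−Δt) term; consequently the scheme's strong order in
  the noise is ½, not 1 (step-halving self-convergence factor √2 at the
  endemic example's noise level).  The correction has zero mean, so weak
  behaviour is unaffected at leading order.  The convergence test therefore
  uses the package's declared smooth test configuration — the endemic-regime
  drift with noise an order of magnitude below the endemic example — in
  which the O(Δt) drift error dominates and the measured halving factor is
  ≈ 2.  On noise-dominated configurations users should expect factor ≈ √2.
* **Reproducibility.**  Replicate r of an ensemble draws its normals from
  `numpy.random.default_rng(SeedSequence(master_seed, spawn_key=(r,)))`,
  fully determined by (seed, config, parameters) across machines.
* **Defaults.**  Δt = 0.01; recording is strided so at most 1e5 points are
  stored per trajectory.

## Long-run diagnostics

⟨h⟩ is the left-Riemann time average.  Regime classification discards a
burn-in (default 25% of the horizon, since the theory's statements are
asymptotic) and labels a run *extinct* when the fitted slope of ln I over
the window is below −1e−3 **and** terminal I is below 1e−2 — two conditions
because either alone mislabels slow transients.  The slope is fitted on the
strictly positive part of the window; a window that is exactly zero for more
than half its length (absorption by the clamp) with small terminal I counts
as extinct, because a floored logarithm would otherwise flatten the slope of
a run that has plainly died out.  *Persistent* requires the windowed mean
and terminal I both above the level threshold.  Runs where the clamp fired
in more than 1% of steps are *indeterminate*.  The theory gives no
operational finite-time definition of persistence, so both tolerances are
exposed as parameters (and CLI flags).

The classifier also reports the long-run linear-relation residual
|⟨S⟩ − (S₀ − S₁⟨I⟩)| on full-horizon averages, which converges to zero for
any positive solution under the theory's boundedness assumptions.

## Stationary distribution check

For f(S)=S the checker evaluates the Lyapunov sufficient condition for a
unique stationary distribution: rate preconditions γ>p, d_I>d_S,
γ(d_S+d_R)>p(d_I+d_R), R₀>1, uniform ellipticity of the diffusion diagonal
a_ii, and a quadratic-form inequality at the endemic equilibrium with
constants C₁–C₃ quadratic in σ (so the condition always holds for small
enough noise — asserted as a property test).  The typeset source of the
constants is ambiguous in one grouping (I* versus I*² in C₁'s first term and
in the right-hand side); the implemented parse is the one that reproduces
the published aggregate value 0.0147 for the endemic noise example, and the
verdicts for both endemic examples (satisfied / not satisfied) are locked as
tests.  Global ellipticity on the whole open octant is impossible (a_ii → 0
at the origin), so the infimum is probed on a bounded box, by default
[0.1x*, 3x*] per component around the endemic equilibrium; the report notes
the distinction.  Failure of the condition does not imply non-existence —
it is sufficient only.

## Synthetic study conditions and what tests show

The five built-in fixtures are the published worked examples for this model
family and define the study conditions: Example 1 (R̃₀=0.8939, strong noise,
extinction), Example 2 (R̃₀=1.3554, persistence), Example 3 (R̄₀=0.8687 <
1 < R̃₀=1.2931, permanence beyond the sufficient condition), Example 4
(weak noise, R₀=2.5279, stationary condition satisfied), Example 5
(R₀=1.6484, preconditions fail).  Regime tests use I(0)=0.5-type interior
starts, horizons T=400–2000, Δt=0.01, and 5–10 replicates — sizes chosen so
the whole suite runs on a desktop in well under a minute of simulation time
while leaving the asymptotic behaviour visible.

Two caveats the simulations expose, worth knowing when interpreting green
and red checks:

* Under Example 1's printed noise, σ₃² = 1.0858 > 2(d_R+ε) = 1.0, so the
  disease-free R process has a Pareto-tailed quasi-stationary law with tail
  index ≈ 0.92: its stationary mean is infinite, and through the εR inflow
  so is S's.  Finite-horizon time averages of S and R then fluctuate widely
  (dt-stable excursions reaching many multiples of the typical level), and
  per-run "within 10% of the disease-free level" checks hold only with
  probability ≈ 0.75 at T=600.  The asymptotic limits quoted for the
  extinct regime implicitly require moment conditions this noise level
  violates.
* The long-run linear-relation residual for Example 2 decays like T^(−1/2)
  (measured RMS 0.068 → 0.051 → 0.026 of S₀ at T = 500 → 2000 → 8000) but at
  T=2000 its scale equals a 5% band, so per-run 5% checks at that horizon
  pass only ≈ half the time.

The generator emulates demographic structure and environmental noise only;
it has no contact network, seasonality, reporting noise, or demographic
(individual-level) stochasticity, so passing tests speak to the SDE model,
not to surveillance data.

## Known limitations

* Thresholds are sharp only as sufficient conditions; the gap between R̄₀
  and R̃₀ regimes is explorable by simulation but not asserted.
* The persistence bounds depend on a caller-supplied solution bound and are
  typically far below observed means (conservative).
* The integrator omits cross-channel Milstein terms (no Lévy areas); see the
  strong-order note above.
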