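# Methods

This note records the models implemented in `rheowave`, the numerical
choices behind them, and the limits of what the test suite demonstrates.

## Models and conventions

All constitutive behaviour is one-dimensional linear viscoelasticity for
the shear channel: a dynamic modulus `E(ω)` (stress/strain ratio at angular
frequency ω), a relaxation modulus `G(t)` (stress response to a strain
step) and a creep compliance `J(t)` (strain response to a stress step).
The Fourier convention is `exp(+iωt)`; passivity then reads
`Re E(ω) > 0`, `Im E(ω) ≥ 0` for ω > 0. Shear-wave dispersion follows
`(k/ω)² = ρ/E(ω)` with the principal square root and `Re k > 0`; phase
velocity is `ω/Re k` (continued to `√(E(0)/ρ)` at ω = 0) and attenuation
`|Im k|` [Np/m]. Units are strictly SI internally; frequencies cross the
CLI/file boundary in Hz and are multiplied by 2π on read.

### Spring–damper networks

`SpringDamperNetwork` holds non-negative element values in one of two
conjugate topologies. Maxwell–Wiechert: an equilibrium spring `E_e` in
parallel with Maxwell branches (spring `E_n` in series with damper `η_n`),
modulus `E(ω) = E_e + Σ iωη_n E_n/(E_n + iωη_n)`; a branch with `E_n = 0`
is a direct dashpot and contributes `iωη_n` plus the impulsive relaxation
term `G_-δ(t)`, which is carried as a separate scalar of the relaxation
result and never sampled. Kelvin chain: series-connected Kelvin–Voigt
units (spring ∥ damper), with a lone series spring (unit with `η = 0`) or
damper (unit with `E = 0`); compliances add and are inverted. Pairs with
both elements zero carry no response and are dropped with a log message;
an empty Kelvin chain is a degenerate-network error. Relaxation of a chain
is computed through its Maxwell conjugate.

Conjugation (same modulus, opposite topology) is implemented for the
canonical forms up to four elements — single elements, Kelvin–Voigt, Zener
and the four-parameter model — by converting to the closed-form parameter
set and re-realizing. General N-element synthesis from an arbitrary
rational modulus is out of scope; `rational_from_network` provides the
network → rational direction for any finite network.

### Classical and fractional models

Zener: `E(ω) = E_e(1 + iωτ_ε)/(1 + iωτ_σ)`, `0 ≤ τ_σ ≤ τ_ε`; physical
elements `η = E_e(τ_ε − τ_σ)`, `E = η/τ_σ`. `τ_σ = 0` is Kelvin–Voigt
(the branch spring stiffens away and is replaced by a lone damper);
`τ_σ = τ_ε` is purely elastic and rejected as degenerate. The rendered
high-frequency velocity relation is implemented as
`c_∞ = c_0 √(ω_σ/ω_ε)`, which is forced by `E(∞) = E_e τ_ε/τ_σ`.

Fractional Zener: `E(ω) = E_e(1 + (iωτ_ε)^α)/(1 + (iωτ_σ)^α)` with
`(iωτ)^α = (ωτ)^α e^{iαπ/2}` on the principal branch and ω ≥ 0 only
(negative frequencies by conjugate symmetry, never evaluated). The
constitutive fractional derivative carries the same order α on the stress
and strain sides; the modulus fixes this. α = 1 reduces to the classical
forms to machine precision (tested at 1e-12).

### Spectral decomposition

The creep time-spectral density of the fractional models is

    R_ε(τ) = (1/πτ) · sin απ / ((τ/τ_ε)^α + (τ/τ_ε)^{−α} + 2 cos απ),

a unit-mass density (the integral evaluates to 1 analytically for every
α < 1; verified numerically to 1e-6) with log-log tail slopes `α − 1`
below the knee and `−α − 1` above. Its frequency counterpart is
`S_ε(Ω) = a·R_ε(1/Ω)/Ω²` with the normalizing compliance
`a = (1/E_e)(1 − (τ_σ/τ_ε)^α)`; the constant is the transient creep
amplitude `J(∞) − J(0⁺)`, which identifies the modulus constant appearing
in the closed form. Both densities are evaluated in closed form and the
identity between them holds to floating-point roundoff (tested at 1e-14).
At α = 1 both densities degenerate to a delta function (single relaxation
process) and are returned as a flagged atom, never sampled.

Tail-slope fits use ordinary least squares on log-log samples. The
sub-leading denominator term decays only as `(τ/τ_ε)^α`, so a window a
fixed few decades from the knee is not in the asymptotic regime for small
α (at α = 0.2 the local slope is still 0.03 off six decades out). Fit
windows are therefore placed 10–12 decades from the knee, where the bias
is below the 0.01 tolerance for all orders tested; for α = 0.01 both tails
are within 0.02 of −1, the structural-hysteresis limit.

### Creep quadrature and the Mittag–Leffler oracle

The transient creep is the superposition
`J(t) = ∫ S_ε(Ω)(1 − e^{−Ωt}) dΩ`, evaluated by adaptive quadrature on
`u = ln Ω`: the region below `Ω = 10⁻¹⁰/t` is dropped (its contribution is
O((Ωt)) against a vanishing density), the exponential factor is dropped
above `Ω = 40/t` (error < e⁻⁴⁰), the remaining power-law tail is
integrated until it has decayed by e⁻³⁵ and closed with the analytic
remainder `S(Ω_cap)·Ω_cap/α`. Breakpoints at `Ω = 1/τ_ε` and `Ω = 1/t`
guide the subdivision; tolerances are 1e-18 absolute / 1e-11 relative per
panel. Against the closed form `J(t) = a(1 − E_α(−(t/τ_ε)^α))` the
quadrature agrees to ~1e-13 relative over six decades of time (the test
threshold is 1e-6). Densities supplied only as samples are integrated by
the trapezoidal rule on their own grid and must cover at least 12 decades,
otherwise an accuracy error is raised.

The Mittag–Leffler function `E_α(z)` is needed only on the completely
monotone branch (α ∈ (0,1], z ≤ 0). For |z| ≤ 1 the Taylor series
`Σ zⁿ/Γ(αn+1)` converges without cancellation; for z < −1 the spectral
representation

    E_α(−x) = ∫₀^∞ e^{−rX} K_α(r) dr,  X = x^{1/α},
    K_α(r) = (1/π) r^{α−1} sin απ / (r^{2α} + 2r^α cos απ + 1)

is integrated on `v = ln r` with the scale shifted so the exponential cut
sits at `v = −ln X` (the integrand is positive, so relative quadrature
tolerances are meaningful). Accuracy is ~1e-15 against the exact identity
`E_{1/2}(−x) = e^{x²} erfc(x)` (via `erfcx`) across 1e-3 ≤ x ≤ 1e4, and
against 80-digit series summation for other orders. When cross-checking
against a high-precision series, the order must be passed as an exact
rational: a double-precision α perturbs the Γ arguments enough to leave a
~1e10 residue in the cancellation of terms of size 1e23.

### Finite-chain (Prony-type) discretization

`discretize_spectrum` lumps `S_ε` into a Kelvin chain: log-uniform cells
at `n_per_decade` across the requested band, each unit carrying its cell's
spectral mass `∫_cell S_ε dΩ` at the cell's geometric center, plus a lone
series spring holding the residual static compliance so the chain's
equilibrium compliance is exactly `1/E_e`. Two choices matter:

* **Cell masses, not midpoint values.** Midpoint weights
  `S(Ω_m)·ΔΩ_m` systematically overshoot the continuum mass at coarse
  spacing (at 4 units/decade the overshoot exceeds the out-of-band tail
  and drives the residual spring negative, i.e. non-realizable).
  Integrated masses are bounded by the continuum mass, so the residual
  stays positive and the chain passive for any density.
* **α-adaptive padding.** The out-of-band spectral mass decays as
  `Ω^{−α}`, so the band is padded by `max(3, 3/α)` decades per side; this
  keeps the tail contribution to the on-band error near 1e-3 even at
  α = 0.2, where a fixed 3-decade pad would leave ~17%.

With the defaults, 8 units/decade reproduce the fractional Kelvin–Voigt
modulus to ~0.07% over the central two decades of a four-decade band
(tested against the 1% bound), and the band error is non-increasing in
`n_per_decade`.

### Hysteresis

Structural damping `E = K + iH` is frequency independent and non-causal;
the fractional Kelvin–Voigt model with α → 0⁺ is its causal regularization
(loss ∝ ω^α). `hysteresis_limit_check` reports the max/min ratio of
`Im E` over a band: `(band ratio)^α`, e.g. 1.047 for α = 0.01 over two
decades, → 1 as α → 0.

### Biot shear dispersion

Two independent routes are implemented. The Stoll/Hovem
relative-displacement form is the rational function

    (k/ω)² = (ρ/μ_r) · (1 + iωτ₂)/(1 + iωτ₁),
    τ₁ = ρ_c B/η_f,  τ₂ = (ρ_c − ρ_f²/ρ) B/η_f,

with `ρ_c = tortuosity·ρ_f/φ`. The original two-density route eliminates
the fluid rotation from the coupled equations of motion,

    μ_r (k/ω)² = ρ₁₁ − iβ + (ρ₁₂ + iβ)²/(iβ − ρ₂₂),  β = b/ω,
    b = η_f φ²/B,

using the closure `ρ₂₂ = tortuosity·φ·ρ_f`, `ρ₁₂ + ρ₂₂ = φρ_f`,
`ρ₁₁ + ρ₁₂ = (1−φ)ρ_s` (the individual `ρ₁₁, ρ₁₂` are not stated by the
theory's summary tables; this closure is the unique one consistent with
the stated identities). Under that closure the two routes are the same
rational function — the elimination collapses algebraically onto the Stoll
form — so their numerical agreement (~1e-13 relative over 200 random
media and six decades of frequency) validates the transcription. The
elimination form has a removable `β → ∞` cancellation at very low
frequency; on grids centered on ω_ε (as used throughout) the float error
stays below 1e-12. Compressional (fast/slow) waves and the
high-frequency, non-laminar flow regime are out of scope.

The exact Zener map (`E_e = μ_r`, `ω_ε = 1/τ₁`, `ω_σ = 1/τ₂`, density ρ)
follows by inspection; `1 − ρ_f²/(ρρ_c) ∈ (0,1)` for every physical
medium since `ρ ≥ φρ_f` and `ρ_c ≥ ρ_f/φ`, so `ω_σ ≥ ω_ε` always, and the
effective characteristic frequency `f_c' = η_f φ/(2πB·tortuosity·ρ_f)`
equals `ω_ε/2π` identically.

### Sensitivity and identifiability

`shear_sensitivity` perturbs each of the ten parameters by 10% (step and
the 1e-8 flag threshold are arguments) and records the maximum relative
wavenumber change: exactly seven parameters move the shear wave (porosity,
both densities, viscosity, permeability, tortuosity, frame shear); the
three bulk moduli never enter the shear branch and report exactly zero.

`identifiability_rank` builds the Jacobian of the stacked Re/Im parts of
`k(ω)` over the seven shear parameters by relative central differences
(step 1e-5 — small enough that the O(h²) truncation bias, which does not
respect the model's low-rank structure, stays far below the 1e-6 singular
value cutoff) and counts singular values above 1e-6 of the leading one.
Because the entire curve is a function of exactly three parameter
combinations — `ρ/μ_r`, `τ₁` and `τ₂` — the rank is 3; freezing the
`τ₂/τ₁` ratio at its baseline (the "frame-dominated" approximation) drops
it to 2. This is deliberately distinct from the *parameter count* of the
reduced model: five quantities (`μ_r`, `ρ`, `ρ_c`, `η_f/B`, `ρ_f`)
specify the exact shear response, but they map onto only three observable
degrees of freedom of `k(ω)`, so no Jacobian of the dispersion alone can
resolve five directions. Scaling `η_f` and `B` together leaves the curve
unchanged to 1e-13, since only their ratio enters.

### Four-parameter (poroviscoelastic) model

Letting the frame shear modulus relax, `μ' = μ/(1 + iω/ω_μ)` in the
denominator sense used here, multiplies the Zener modulus by
`(1 + iω/ω_μ)`:
`E(ω) = μ(1 + iω/ω_μ)(1 + iω/ω_ε)/(1 + iω/ω_σ)`, with `E(0) = μ` and
`|E| ∝ ω` at high frequency. Its compliance splits into partial fractions
over the retardation poles ω_μ and ω_ε, giving two Kelvin units in series
(weights `A = (1 − ω_μ/ω_σ)/(μ(1 − ω_μ/ω_ε))` and symmetrically `B`); the
realization matches the closed form to ~1e-15 and degenerates to the Zener
Kelvin form as ω_μ → ∞. Negative partial-fraction weights (e.g. orderings
with ω_μ between ω_ε and ω_σ) are not passively realizable in this
topology and raise with the offending coefficient; the coincident-pole
case ω_μ = ω_ε would need a repeated-pole form and is rejected. Only this
(conjugate, two-Kelvin-unit) realization is synthesized; an equivalent
Maxwell-side form (equilibrium spring + direct damper + one Maxwell
branch) is produced by `conjugate_network`. The sand-coupling extension
with Bessel-function frame/fluid coupling is out of scope.

## Parameters that matter

| Parameter | Units | Default | Why |
|---|---|---|---|
| `n_per_decade` (Prony) | 1/decade | 8 | ~0.1% band error; error halves-ish per doubling |
| `pad_decades` (Prony) | decades | `max(3, 3/α)` | out-of-band mass ∝ Ω^{−α} |
| `rel_step` (sensitivity) | – | 0.1 | large enough that discretization noise cannot flag a bulk modulus |
| sensitivity threshold | – | 1e-8 | separates exact zeros from rounding |
| `rel_step` (rank) | – | 1e-5 | balances O(h²) truncation vs eps/h roundoff |
| `sv_tol` (rank) | – | 1e-6 | separates genuinely-zero directions from noise |
| quadrature tolerances | – | 1e-18 abs / 1e-11 rel | creep agreement ≪ the 1e-6 test bound |

## Test materials

The fixture generator writes physically plausible placeholder materials
(unit Zener 1 Pa/2 s/1 s; fractional models with α = 0.3 and α = 0.8 with
a 1000:1 time-constant ratio; the porous baseline above; a four-parameter
set). They exercise every code path — exact maps, long-tailed spectra,
random-media sweeps — but they are analytic constructions, not tissue
measurements: passing tests demonstrates the mathematical identities and
numerical accuracy of the implementations, not that any particular tissue
follows these models, and no fitting of measured elastography data is
provided or implied. Problem sizes in the acceptance script (200 random
media, 61–181 frequency points, 31 time points) were chosen as the
smallest sweeps that exercise the full parameter ranges; all computations
are closed-form or one-dimensional quadratures and complete in about a
second.

## Known limitations

* Conjugation and relaxation-modulus evaluation of Kelvin chains are
  limited to the canonical ≤ 4-element forms; arbitrary chains evaluate
  their modulus but are not re-realized.
* The relaxation-side spectral densities of the fractional models are not
  provided in closed form (only the creep side is); the generic
  superposition transforms accept user-supplied sampled densities instead.
* The Mittag–Leffler evaluator covers only the completely monotone branch
  (real z ≤ 0, α ∈ (0,1]) needed for creep/relaxation.
* Reports omit wall-clock timestamps by default so identical inputs give
  byte-identical outputs; `--timestamp` opts in.
* The CLI writes no plots; CSV output is intended for downstream tooling.
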