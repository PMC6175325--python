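# rheowave

Spring–damper equivalents of viscoelastic, fractional-viscoelastic and
poroelastic shear-wave models, for elastography.

## The problem

MR and ultrasound elastography infer tissue stiffness from shear-wave
propagation. The measured dispersion — phase velocity `c_p(ω) = ω/Re k` and
attenuation `|Im k|` of the complex wavenumber `k = ω √(ρ/E(ω))` — is
interpreted through a material model for the complex dynamic shear modulus
`E(ω)`. Several model families are in routine use and look unrelated:

* **Classical viscoelastic**: Kelvin–Voigt `E(ω) = E_e(1 + iωτ_ε)` and the
  Zener (standard linear solid)
  `E(ω) = E_e (1 + iωτ_ε)/(1 + iωτ_σ)`, `0 ≤ τ_σ ≤ τ_ε`;
* **Fractional viscoelastic**:
  `E(ω) = E_e (1 + (iωτ_ε)^α)/(1 + (iωτ_σ)^α)` with order `α ∈ (0, 1]`,
  the parsimonious description of power-law dispersion/attenuation
  (a spring-pot `E ∝ (iωη)^α` in the high-frequency limit);
* **Biot poroelastic**: a two-phase solid-frame + pore-fluid medium with
  ten material parameters (porosity φ, densities ρ_s, ρ_f, bulk moduli,
  fluid viscosity η_f, permeability B, tortuosity, frame moduli K_r, μ_r)
  and Darcy (laminar) loss from relative fluid flow;
* **Poroviscoelastic (squirt-flow / viscous-drag extension)**: Biot with a
  relaxing frame shear modulus `μ' = μ(1 + iω/ω_μ)`.

`rheowave` implements all of these and, crucially, the *bridges* between
them:

* any Zener/Kelvin–Voigt model is realized exactly as a three-element
  spring–damper network, in either conjugate topology (Maxwell–Wiechert
  parallel branches or a Kelvin chain of series units);
* the fractional models are superpositions of elementary relaxation
  processes weighted by the long-tailed creep spectral density
  `R_ε(τ) = (1/πτ) sin απ / ((τ/τ_ε)^α + (τ/τ_ε)^{-α} + 2 cos απ)`
  (log-log tail slopes `α−1` and `−α−1`); sampling its frequency-domain
  form on a log grid yields a finite, passive Kelvin chain (a Prony-type
  approximation) with controllable band error;
* the shear branch of the Biot model **is** a Zener solid, exactly:
  `E_e = μ_r`, `ω_ε = η_f/(ρ_c B)`,
  `ω_σ = ω_ε / (1 − ρ_f²/(ρ ρ_c))`, `c_0² = μ_r/ρ`, with the
  mass-coupling density `ρ_c = tortuosity·ρ_f/φ` and aggregate density
  `ρ = φρ_f + (1−φ)ρ_s`;
* the poroviscoelastic shear modulus is the non-standard four-parameter
  model `E(ω) = μ(1 + iω/ω_μ)(1 + iω/ω_ε)/(1 + iω/ω_σ)`, realizable as
  two Kelvin–Voigt units in series.

Sensitivity and identifiability tools quantify which of the ten Biot
parameters the shear wave feels (seven) and how many independent
directions the dispersion curve can actually resolve.

Convention: time dependence `exp(+iωt)`, so passive loss means
`Im E(ω) ≥ 0`; wavenumbers use the principal root with `Re k > 0` and
attenuation is reported as `|Im k|` in Np/m. SI units internally; plain Hz
at every file/CLI boundary.

## Worked example

A soft water-saturated porous frame (porosity 0.5, solid grains
2650 kg/m³, water 1000 kg/m³, viscosity 1 mPa·s, permeability 10⁻¹¹ m²,
tortuosity 1.25, frame shear modulus 5 kPa):

```sh
rheowave fixtures --out-dir materials
rheowave biot2zener --params materials/biot_baseline.yaml
```

prints (abridged):

```json
{
  "derived": {
    "equilibrium_modulus_pa": 5000.0,
    "omega_eps_rad_s": 40000.0,
    "omega_sig_rad_s": 51228.0701754386,
    "aggregate_density_kg_m3": 1825.0,
    "mass_coupling_density_kg_m3": 2500.0,
    "f_c_prime_hz": 6366.197723675815,
    "c0_m_s": 1.655211777204736,
    "c_inf_m_s": 1.8731716231633881
  }
}
```

Reading: this porous medium is *exactly* a Zener solid with equilibrium
modulus 5 kPa and relaxation corner at `ω_ε = η_f/(ρ_c B) = 4×10⁴` rad/s
(`ρ_c = 1.25·1000/0.5 = 2500` kg/m³); the stress corner sits a factor
`1/(1 − 1000²/(1825·2500)) = 1.2807` higher. The shear wave travels at
`c_0 = √(μ_r/ρ) = 1.66` m/s at low frequency and approaches
`c_∞ = c_0 √(ω_σ/ω_ε) = 1.87` m/s beyond the corner, which coincides with
the effective pore-pressure relaxation frequency
`f_c' = ω_ε/2π ≈ 6.4` kHz.

Other subcommands: `dispersion` (CSV curves for any model),
`spectrum`/`prony` (fractional spectral density and its finite Kelvin
chain), `sensitivity` and `rank` (which Biot parameters matter),
`fixtures`. See `rheowave --help`.

Library use mirrors the CLI:

```python
import numpy as np
from rheowave import FractionalParams, discretize_spectrum, frac_modulus, network_modulus

p = FractionalParams(modulus=2e3, tau_eps=0.01, alpha=0.3)  # fractional KV
chain = discretize_spectrum(p, n_per_decade=8, band=(1.0, 1e4))
w = np.geomspace(10.0, 1e3, 5)
print(np.max(np.abs(network_modulus(chain, w) - frac_modulus(p, w))
             / np.abs(frac_modulus(p, w))))   # ~7e-4
```

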