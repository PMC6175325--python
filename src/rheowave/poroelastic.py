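"""Biot poroelastic shear dispersion and its viscoelastic equivalents.

A fluid-saturated porous medium (solid frame plus pore fluid, laminar
Darcy flow) supports one shear wave whose dispersion is governed by the
relative solid/fluid motion.  Two classical formulations are implemented:

* the original two-density formulation, in which the fluid rotation is
  eliminated from the coupled equations of motion written with the
  effective densities ``rho_11, rho_12, rho_22`` and the friction
  coefficient ``b = eta_f phi^2 / B``; and
* the Stoll/Hovem relative-displacement form

      (k/omega)^2 = (rho/mu_r)
          (1 + i omega (rho_c - rho_f^2/rho) B/eta_f)
          / (1 + i omega rho_c B/eta_f),

  with the mass-coupling density ``rho_c = tortuosity rho_f / phi``.

Both are the same degree-(1,1) rational function of ``i omega``: the shear
branch of the poroelastic model *is* a three-element Zener solid with

    E_e = mu_r,   omega_eps = eta_f/(rho_c B),
    omega_sig = omega_eps / (1 - rho_f^2/(rho rho_c)) >= omega_eps,
    c_0^2 = mu_r / rho,

which this module exposes as an exact parameter map.  Allowing the frame
shear modulus itself to relax (squirt-flow / viscous-drag extension) turns
the equivalent into the non-standard four-parameter model

    E(omega) = mu (1 + i w/w_mu)(1 + i w/w_eps) / (1 + i w/w_sig),

realizable as two Kelvin-Voigt units in series.  Sensitivity and
identifiability helpers quantify which of the ten material parameters the
shear wave actually feels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .viscoelastic import (
    DispersionCurve,
    SpringDamperNetwork,
    SpringDamperUnit,
    Topology,
    ZenerParams,
    _check_omega,
    dispersion,
)

__all__ = [
    "BiotParams",
    "BiotDensities",
    "FourParamModel",
    "SHEAR_PARAMETERS",
    "derive_densities",
    "biot_shear_original",
    "biot_shear_stoll",
    "biot_to_zener",
    "bicsqs_modulus",
    "bicsqs_from_biot",
    "fourparam_to_network",
    "shear_sensitivity",
    "affected_parameters",
    "identifiability_rank",
]


@dataclass(frozen=True)
class BiotParams:
    """The ten low-frequency Biot-Stoll material parameters (SI units).

    ``porosity`` in (0, 1); ``tortuosity >= 1``; densities [kg/m^3], moduli
    [Pa], fluid viscosity [Pa s], permeability [m^2].  The bulk moduli
    (solid grain, pore fluid, drained frame) do not enter the shear wave;
    they are carried for completeness of the material description.
    """

    porosity: float
    solid_density: float
    fluid_density: float
    solid_bulk: float
    fluid_bulk: float
    fluid_viscosity: float
    permeability: float
    tortuosity: float
    frame_bulk: float
    frame_shear: float

    def __post_init__(self) -> None:
        if not (0.0 < self.porosity < 1.0):
            raise ValueError("porosity must lie in (0, 1)")
        if not (self.tortuosity >= 1.0):
            raise ValueError("tortuosity must be >= 1")
        for name in (
            "solid_density",
            "fluid_density",
            "solid_bulk",
            "fluid_bulk",
            "fluid_viscosity",
            "permeability",
            "frame_bulk",
            "frame_shear",
        ):
            if not (getattr(self, name) > 0.0):
                raise ValueError(f"{name} must be positive")

    def replace(self, **kw) -> "BiotParams":
        from dataclasses import replace

        return replace(self, **kw)


#: The seven Table-style parameters the shear wave depends on.
SHEAR_PARAMETERS = (
    "porosity",
    "solid_density",
    "fluid_density",
    "fluid_viscosity",
    "permeability",
    "tortuosity",
    "frame_shear",
)


@dataclass(frozen=True)
class BiotDensities:
    """Derived densities, coupling terms and characteristic frequencies."""

    rho: float
    rho_11: float
    rho_12: float
    rho_22: float
    gamma_11: float
    gamma_12: float
    gamma_22: float
    rho_c: float
    b_fric: float
    f_c: float
    f_c_prime: float


def derive_densities(p: BiotParams) -> BiotDensities:
    """Effective densities and characteristic frequencies of a Biot medium.

    Uses the aggregate density ``rho = phi rho_f + (1-phi) rho_s``, the
    fluid effective mass ``rho_22 = tortuosity phi rho_f`` and the standard
    closure ``rho_12 + rho_22 = phi rho_f``, ``rho_11 + rho_12 =
    (1-phi) rho_s`` (so the mass-coupling density ``rho_12 <= 0``).  The
    friction coefficient is ``b = eta_f phi^2 / B``; the characteristic
    frequency ``f_c = b / (2 pi (rho_12 + rho_22))`` and the (lower)
    effective one ``f_c' = f_c (gamma_12+gamma_22)/gamma_22 =
    eta_f phi / (2 pi B tortuosity rho_f)``, which coincides with
    ``omega_eps / (2 pi)`` of the equivalent Zener model.
    """
    phi = p.porosity
    rho = phi * p.fluid_density + (1.0 - phi) * p.solid_density
    rho_22 = p.tortuosity * phi * p.fluid_density
    rho_12 = phi * p.fluid_density - rho_22
    rho_11 = (1.0 - phi) * p.solid_density - rho_12
    rho_c = p.tortuosity * p.fluid_density / phi
    b_fric = p.fluid_viscosity * phi**2 / p.permeability
    f_c = b_fric / (2.0 * np.pi * (rho_12 + rho_22))
    f_c_prime = f_c * (rho_12 + rho_22) / rho_22
    return BiotDensities(
        rho=rho,
        rho_11=rho_11,
        rho_12=rho_12,
        rho_22=rho_22,
        gamma_11=rho_11 / rho,
        gamma_12=rho_12 / rho,
        gamma_22=rho_22 / rho,
        rho_c=rho_c,
        b_fric=b_fric,
        f_c=f_c,
        f_c_prime=f_c_prime,
    )


# ---------------------------------------------------------------------------
# dispersion, two routes


def biot_shear_original(p: BiotParams, omega) -> DispersionCurve:
    """Shear dispersion from the original two-density formulation.

    Eliminating the fluid rotation from the coupled shear equations of
    motion gives, with ``beta = b/omega`` (normalized here by ``rho``),

        mu_r (k/omega)^2 =
            rho_11 - i beta + (rho_12 + i beta)^2 / (i beta - rho_22).

    The low-frequency limit (``beta -> inf``, locked fluid) is the lossless
    elastic wave ``k = omega sqrt(rho/mu_r)``; the high-frequency limit has
    the reduced inertia ``rho_11 - rho_12^2/rho_22``.
    """
    w = _check_omega(omega)
    d = derive_densities(p)
    kk = np.empty(w.shape, dtype=complex)  # (k/omega)^2 * mu / rho
    nz = w > 0.0
    with np.errstate(divide="ignore"):
        bt = np.where(nz, d.b_fric / np.where(nz, w, 1.0) / d.rho, np.inf)
    bt = bt[nz]
    kk[nz] = (
        d.gamma_11
        - 1j * bt
        + (d.gamma_12 + 1j * bt) ** 2 / (1j * bt - d.gamma_22)
    )
    kk[~nz] = 1.0  # locked-fluid limit: aggregate density
    # kk is (k/omega)^2 mu/rho, so the dynamic modulus is mu/kk
    return dispersion(p.frame_shear / kk, d.rho, w)


def biot_shear_stoll(p: BiotParams, omega) -> DispersionCurve:
    """Shear dispersion in the Stoll/Hovem relative-displacement form.

    ``(k/omega)^2 = (rho/mu_r)(1 + i w tau_2)/(1 + i w tau_1)`` with
    ``tau_1 = rho_c B / eta_f`` and
    ``tau_2 = (rho_c - rho_f^2/rho) B / eta_f``.
    """
    w = _check_omega(omega)
    d = derive_densities(p)
    tau1 = d.rho_c * p.permeability / p.fluid_viscosity
    tau2 = (d.rho_c - p.fluid_density**2 / d.rho) * p.permeability / p.fluid_viscosity
    kk = (1.0 + 1j * w * tau2) / (1.0 + 1j * w * tau1)  # (k/omega)^2 mu/rho
    return dispersion(p.frame_shear / kk, d.rho, w)


def biot_to_zener(p: BiotParams) -> tuple[ZenerParams, float]:
    """Exact Zener equivalent ``(E_e, tau_eps, tau_sig)`` and density.

    ``E_e = mu_r``, ``omega_eps = eta_f/(rho_c B)``,
    ``omega_sig = omega_eps / (1 - rho_f^2/(rho rho_c))``; the aggregate
    density completes the four-parameter Zener medium.  The denominator
    lies in (0, 1) for every physical medium (``tortuosity >= 1``,
    ``porosity < 1``) so ``omega_sig >= omega_eps`` always.
    """
    d = derive_densities(p)
    denom = 1.0 - p.fluid_density**2 / (d.rho * d.rho_c)
    if not (0.0 < denom < 1.0):
        raise ValueError(
            "invalid medium: 1 - rho_f^2/(rho rho_c) must lie in (0, 1), "
            f"got {denom}"
        )
    tau_eps = d.rho_c * p.permeability / p.fluid_viscosity
    tau_sig = tau_eps * denom
    return ZenerParams(p.frame_shear, tau_eps, tau_sig), d.rho


# ---------------------------------------------------------------------------
# poroviscoelastic (squirt-flow / viscous-drag) extension


@dataclass(frozen=True)
class FourParamModel:
    """Non-standard four-parameter shear model ``(mu, w_mu, w_eps, w_sig)``.

    ``E(omega) = mu (1 + i w/w_mu)(1 + i w/w_eps)/(1 + i w/w_sig)`` — a
    Zener solid whose frame shear modulus itself relaxes with
    characteristic rate ``w_mu``.  ``E(0) = mu``; ``|E| ~ omega`` as
    ``omega -> inf``.  Ordering ``w_sig >= w_eps`` is inherited from the
    Zener part.
    """

    shear_modulus: float
    omega_mu: float
    omega_eps: float
    omega_sig: float

    def __post_init__(self) -> None:
        for name in ("shear_modulus", "omega_mu", "omega_eps", "omega_sig"):
            if not (getattr(self, name) > 0.0):
                raise ValueError(f"{name} must be positive")
        if self.omega_sig < self.omega_eps:
            raise ValueError("need omega_sig >= omega_eps (Zener ordering)")


def bicsqs_modulus(m: FourParamModel, omega) -> np.ndarray:
    """Dynamic modulus of the four-parameter (relaxing-frame) shear model."""
    w = _check_omega(omega)
    return (
        m.shear_modulus
        * (1.0 + 1j * w / m.omega_mu)
        * (1.0 + 1j * w / m.omega_eps)
        / (1.0 + 1j * w / m.omega_sig)
    )


def bicsqs_from_biot(p: BiotParams, omega_mu: float) -> FourParamModel:
    """Four-parameter model of a Biot medium with a relaxing frame modulus."""
    z, _rho = biot_to_zener(p)
    return FourParamModel(z.modulus, omega_mu, z.omega_eps, z.omega_sig)


def fourparam_to_network(m: FourParamModel) -> SpringDamperNetwork:
    """Realize the four-parameter model as two Kelvin units in series.

    The compliance ``1/E(omega)`` splits into partial fractions over the
    retardation poles ``w_mu`` and ``w_eps``:

        J = A/(1 + i w/w_mu) + B/(1 + i w/w_eps),
        A = (1 - w_mu/w_sig)/(mu (1 - w_mu/w_eps)),
        B = (1 - w_eps/w_sig)/(mu (1 - w_eps/w_mu)),

    each term a Kelvin unit ``(E = 1/A, eta = 1/(A w_mu))``.  Negative
    weights mean the parameter set is not passively realizable and raise.
    """
    mu, wm, we, ws = m.shear_modulus, m.omega_mu, m.omega_eps, m.omega_sig
    if wm == we:
        raise ValueError(
            "coincident retardation rates (omega_mu == omega_eps) need a "
            "repeated-pole realization, which is not supported"
        )
    A = (1.0 - wm / ws) / (mu * (1.0 - wm / we))
    B = (1.0 - we / ws) / (mu * (1.0 - we / wm))
    for name, coeff in (("A (omega_mu pole)", A), ("B (omega_eps pole)", B)):
        if coeff < 0.0:
            raise ValueError(
                f"non-realizable parameters: partial-fraction weight {name} "
                f"= {coeff} is negative"
            )
    units = (
        SpringDamperUnit(1.0 / A, 1.0 / (A * wm)),
        SpringDamperUnit(1.0 / B, 1.0 / (B * we)),
    )
    return SpringDamperNetwork(Topology.KELVIN_CHAIN, units)


# ---------------------------------------------------------------------------
# sensitivity / identifiability


def shear_sensitivity(
    p: BiotParams,
    omega,
    rel_step: float = 0.1,
    threshold: float = 1e-8,
) -> dict[str, float]:
    """Which material parameters move the shear dispersion.

    Perturbs each of the ten parameters by ``rel_step`` (one at a time,
    multiplicatively), recomputes the Stoll-form wavenumber and reports the
    maximum relative ``|dk|`` per parameter.  A parameter "affects" the
    shear wave when that exceeds ``threshold``; the three bulk moduli never
    do.
    """
    if not (0.0 < rel_step <= 0.2):
        raise ValueError("rel_step must lie in (0, 0.2]")
    w = _check_omega(omega)
    k0 = biot_shear_stoll(p, w).wavenumber
    out: dict[str, float] = {}
    for name in (
        "porosity",
        "solid_density",
        "fluid_density",
        "solid_bulk",
        "fluid_bulk",
        "fluid_viscosity",
        "permeability",
        "tortuosity",
        "frame_bulk",
        "frame_shear",
    ):
        q = p.replace(**{name: getattr(p, name) * (1.0 + rel_step)})
        k1 = biot_shear_stoll(q, w).wavenumber
        out[name] = float(np.max(np.abs(k1 - k0) / np.abs(k0)))
    return out


def affected_parameters(report: dict[str, float], threshold: float = 1e-8):
    """Names whose dispersion change exceeds the threshold."""
    return tuple(name for name, d in report.items() if d > threshold)


def _stacked_k(p: BiotParams, w: np.ndarray, freeze_ratio: float | None) -> np.ndarray:
    if freeze_ratio is None:
        k = biot_shear_stoll(p, w).wavenumber
    else:
        # approximate model: the tau_sig/tau_eps ratio is held at its
        # baseline value instead of tracking rho_f^2/(rho rho_c)
        d = derive_densities(p)
        tau1 = d.rho_c * p.permeability / p.fluid_viscosity
        tau2 = tau1 * freeze_ratio
        kk = (1.0 + 1j * w * tau2) / (1.0 + 1j * w * tau1)
        k = dispersion(p.frame_shear / kk, d.rho, w).wavenumber
    return np.concatenate([k.real, k.imag])


def identifiability_rank(
    p: BiotParams,
    omega,
    rel_step: float = 1e-5,
    sv_tol: float = 1e-6,
    approx: bool = False,
) -> int:
    """Numerical rank of the dispersion Jacobian over the shear parameters.

    Builds the Jacobian of the stacked real/imaginary parts of the
    Stoll-form ``k(omega)`` with respect to the seven shear-affecting
    parameters by relative central differences (each column is the
    derivative against the *logarithm* of its parameter, which scales
    columns by parameter magnitude), then counts singular values above
    ``sv_tol`` times the leading one.

    The returned rank is the number of independent directions the
    dispersion curve can actually distinguish.  Because the curve is a
    function of exactly three parameter combinations (``rho/mu_r``,
    ``tau_eps`` and ``tau_sig``), the rank is 3 however many parameters are
    perturbed; with ``approx=True`` the ``tau_sig/tau_eps`` ratio is frozen
    at its baseline value and the rank drops to 2.
    """
    w = _check_omega(omega)
    if w.size < 10 or w[w > 0].max() / w[w > 0].min() < 1e3:
        raise ValueError("need >= 10 frequencies spanning >= 3 decades")
    freeze = None
    if approx:
        z, _ = biot_to_zener(p)
        freeze = z.tau_sig / z.tau_eps
    cols = []
    for name in SHEAR_PARAMETERS:
        x0 = getattr(p, name)
        hi = p.replace(**{name: x0 * (1.0 + rel_step)})
        lo = p.replace(**{name: x0 * (1.0 - rel_step)})
        col = (_stacked_k(hi, w, freeze) - _stacked_k(lo, w, freeze)) / (2.0 * rel_step)
        cols.append(col)
    J = np.column_stack(cols)
    sv = np.linalg.svd(J, compute_uv=False)
    if sv[0] == 0.0:
        raise ValueError("ill-conditioned baseline: Jacobian is identically zero")
    return int(np.sum(sv > sv_tol * sv[0]))
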