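"""Spring-damper network algebra and classical viscoelastic shear models.

Linear viscoelastic media are described here in three interchangeable ways:

* a finite network of springs (stiffness ``E_n`` [Pa]) and dampers
  (viscosity ``eta_n`` [Pa s]) in one of two conjugate topologies
  (Maxwell-Wiechert: spring+damper pairs in series, pairs in parallel;
  Kelvin chain: spring||damper units in series),
* a rational dynamic modulus ``E(omega)`` (ratio of two polynomials in
  ``i*omega``), and
* closed-form two/three-element models: Kelvin-Voigt
  ``E(omega) = E_e (1 + i omega tau_eps)`` and the Zener standard linear
  solid ``E(omega) = E_e (1 + i omega tau_eps) / (1 + i omega tau_sig)``.

Throughout the package the Fourier convention is a time dependence
``exp(+i omega t)``, so every passive loss term carries ``+i`` and
``Im E(omega) >= 0``.  The dispersion relation for a shear wave in a
homogeneous medium of density ``rho`` is ``(k/omega)^2 = rho / E(omega)``;
the principal square root is taken and ``Re k > 0`` enforced, with the
attenuation reported as ``|Im k|`` in Np/m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Topology",
    "SpringDamperUnit",
    "SpringDamperNetwork",
    "ZenerParams",
    "RationalModulus",
    "RelaxationResult",
    "DispersionCurve",
    "DegenerateNetworkError",
    "network_modulus",
    "zener_modulus",
    "kelvin_voigt_modulus",
    "zener_to_network",
    "network_to_zener",
    "conjugate_network",
    "relaxation_modulus",
    "dispersion",
    "rational_from_network",
]


class DegenerateNetworkError(ValueError):
    """Raised for networks with no mechanical response (e.g. an empty chain)."""


class Topology(str, Enum):
    """Network topology tag.

    ``maxwell_wiechert``: each unit is a spring and damper in series
    (a Maxwell branch) and the units are connected in parallel, together
    with an optional equilibrium spring.  A unit with zero stiffness is a
    direct dashpot across the terminals and contributes the impulsive
    relaxation term.

    ``kelvin_chain``: each unit is a spring and damper in parallel
    (a Kelvin-Voigt unit) and the units are connected in series.  A unit
    with zero viscosity is a lone series spring; a unit with zero
    stiffness is a lone series damper.
    """

    MAXWELL_WIECHERT = "maxwell_wiechert"
    KELVIN_CHAIN = "kelvin_chain"


@dataclass(frozen=True)
class SpringDamperUnit:
    """One spring/damper pair: stiffness [Pa] and viscosity [Pa s]."""

    stiffness: float
    viscosity: float

    def __post_init__(self) -> None:
        if not (self.stiffness >= 0.0) or not (self.viscosity >= 0.0):
            raise ValueError(
                "spring stiffness and damper viscosity must be non-negative, "
                f"got (E={self.stiffness}, eta={self.viscosity})"
            )

    @property
    def relaxation_time(self) -> float:
        """``tau = eta / E`` [s]; ``inf`` for a pure damper."""
        if self.stiffness == 0.0:
            return np.inf
        return self.viscosity / self.stiffness


@dataclass(frozen=True)
class SpringDamperNetwork:
    """A physically realizable finite spring-damper network.

    Parameters
    ----------
    topology
        Connection pattern, see :class:`Topology`.
    units
        Ordered ``(stiffness, viscosity)`` pairs.  Units with both elements
        zero carry no response and are dropped (with a log message).
    equilibrium_spring
        The lone parallel spring ``E_e`` [Pa] of the Maxwell-Wiechert form;
        must be zero for a Kelvin chain (a lone series spring is encoded as
        a unit with zero viscosity instead).
    """

    topology: Topology
    units: tuple[SpringDamperUnit, ...]
    equilibrium_spring: float = 0.0

    def __post_init__(self) -> None:
        topo = Topology(self.topology)
        object.__setattr__(self, "topology", topo)
        units = tuple(
            u if isinstance(u, SpringDamperUnit) else SpringDamperUnit(*u)
            for u in self.units
        )
        kept = tuple(u for u in units if u.stiffness > 0.0 or u.viscosity > 0.0)
        if len(kept) < len(units):
            logger.info(
                "dropped %d degenerate (E=0, eta=0) unit(s)", len(units) - len(kept)
            )
        object.__setattr__(self, "units", kept)
        if not (self.equilibrium_spring >= 0.0):
            raise ValueError("equilibrium spring must be non-negative")
        if topo is Topology.KELVIN_CHAIN:
            if self.equilibrium_spring != 0.0:
                raise ValueError(
                    "a Kelvin chain has no parallel equilibrium spring; encode a "
                    "lone series spring as a unit with zero viscosity"
                )
            if not self.units:
                raise DegenerateNetworkError("empty Kelvin chain has no compliance")
        else:
            if not self.units and self.equilibrium_spring == 0.0:
                raise DegenerateNetworkError("network has no elements")

    @property
    def n_elements(self) -> int:
        """Number of physical one-parameter elements (springs + dampers)."""
        n = sum(
            (1 if u.stiffness > 0 else 0) + (1 if u.viscosity > 0 else 0)
            for u in self.units
        )
        if self.topology is Topology.MAXWELL_WIECHERT and self.equilibrium_spring > 0:
            n += 1
        return n

    @property
    def impulse_weight(self) -> float:
        """Weight ``G_-`` of the instantaneous (delta) relaxation term [Pa s].

        Non-zero only for a Maxwell-Wiechert net with a direct dashpot
        (a unit with zero stiffness).
        """
        if self.topology is not Topology.MAXWELL_WIECHERT:
            return 0.0
        return sum(u.viscosity for u in self.units if u.stiffness == 0.0)


@dataclass(frozen=True)
class ZenerParams:
    """Standard-linear-solid parameters.

    ``modulus`` is the equilibrium (relaxed) modulus ``E_e`` [Pa];
    ``tau_eps`` and ``tau_sig`` are the strain and stress relaxation times
    [s] with ``0 <= tau_sig <= tau_eps``.  ``tau_sig = 0`` degenerates to
    the Kelvin-Voigt model.
    """

    modulus: float
    tau_eps: float
    tau_sig: float

    def __post_init__(self) -> None:
        if not (self.modulus > 0.0):
            raise ValueError("equilibrium modulus must be positive")
        if not (0.0 <= self.tau_sig <= self.tau_eps):
            raise ValueError(
                f"need 0 <= tau_sig <= tau_eps, got tau_sig={self.tau_sig}, "
                f"tau_eps={self.tau_eps}"
            )
        if self.tau_eps <= 0.0:
            raise ValueError("tau_eps must be positive")

    @property
    def glass_modulus(self) -> float:
        """High-frequency limit ``E_e tau_eps / tau_sig`` [Pa] (inf for KV)."""
        if self.tau_sig == 0.0:
            return np.inf
        return self.modulus * self.tau_eps / self.tau_sig

    @property
    def omega_eps(self) -> float:
        return 1.0 / self.tau_eps

    @property
    def omega_sig(self) -> float:
        return np.inf if self.tau_sig == 0.0 else 1.0 / self.tau_sig


@dataclass(frozen=True)
class RationalModulus:
    """Dynamic modulus as a rational function of ``i*omega``.

    ``E(omega) = sum_k b[k] (i w)^k / (1 + sum_{k>=1} a[k-1] (i w)^k)`` with
    ``b[0]`` the equilibrium modulus.  Coefficients are real; the
    denominator's leading 1 is implicit.
    """

    b_coeffs: tuple[float, ...]
    a_coeffs: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "b_coeffs", tuple(float(x) for x in self.b_coeffs))
        object.__setattr__(self, "a_coeffs", tuple(float(x) for x in self.a_coeffs))
        if not self.b_coeffs:
            raise ValueError("numerator needs at least the constant coefficient")

    def __call__(self, omega: Sequence[float] | float) -> np.ndarray:
        s = 1j * np.atleast_1d(np.asarray(omega, dtype=float))
        num = np.polynomial.polynomial.polyval(s, np.asarray(self.b_coeffs))
        den = np.polynomial.polynomial.polyval(s, np.asarray((1.0,) + self.a_coeffs))
        return num / den


@dataclass(frozen=True)
class RelaxationResult:
    """Sampled relaxation modulus ``G(t)`` plus its non-sampled parts.

    ``impulse_weight`` is the coefficient ``G_-`` of the delta function at
    ``t = 0`` (the direct-dashpot contribution), carried separately and
    never added to the samples.  ``equilibrium`` is ``G(inf) = E_e``.
    """

    t: np.ndarray
    values: np.ndarray
    equilibrium: float
    impulse_weight: float


@dataclass(frozen=True)
class DispersionCurve:
    """Per-frequency complex modulus and shear wavenumber.

    Fields: angular frequency ``omega`` [rad/s] (ascending), complex dynamic
    modulus ``modulus`` [Pa], complex wavenumber ``wavenumber`` [1/m], phase
    velocity ``omega / Re k`` [m/s], attenuation ``|Im k|`` [Np/m], and the
    density used [kg/m^3].
    """

    omega: np.ndarray
    modulus: np.ndarray
    wavenumber: np.ndarray
    phase_velocity: np.ndarray
    attenuation: np.ndarray
    density: float


# ---------------------------------------------------------------------------
# moduli


def _check_omega(omega) -> np.ndarray:
    w = np.atleast_1d(np.asarray(omega, dtype=float))
    if np.any(w < 0.0):
        raise ValueError("angular frequencies must be >= 0 (use conjugate symmetry)")
    return w


def network_modulus(net: SpringDamperNetwork, omega) -> np.ndarray:
    """Complex dynamic modulus of a spring-damper network.

    For the Maxwell-Wiechert topology
    ``E(w) = E_e + sum_n i w eta_n E_n / (E_n + i w eta_n)`` (a unit with
    ``E_n = 0`` contributing the direct-dashpot term ``i w eta_n``); for a
    Kelvin chain the unit compliances ``1 / (E_n + i w eta_n)`` are summed
    and inverted.
    """
    w = _check_omega(omega)
    if net.topology is Topology.MAXWELL_WIECHERT:
        E = np.full(w.shape, net.equilibrium_spring, dtype=complex)
        for u in net.units:
            if u.stiffness == 0.0:
                E += 1j * w * u.viscosity
            elif u.viscosity == 0.0:
                # a rigid-damper branch transmits no stress
                continue
            else:
                E += (1j * w * u.viscosity * u.stiffness) / (
                    u.stiffness + 1j * w * u.viscosity
                )
        return E
    # Kelvin chain: series compliances
    J = np.zeros(w.shape, dtype=complex)
    free = np.zeros(w.shape, dtype=bool)  # infinite compliance (free damper at w=0)
    for u in net.units:
        denom = u.stiffness + 1j * w * u.viscosity
        zero = denom == 0.0
        free |= zero
        with np.errstate(divide="ignore", invalid="ignore"):
            J += np.where(zero, 0.0, 1.0 / np.where(zero, 1.0, denom))
    E = np.empty(w.shape, dtype=complex)
    E[free] = 0.0
    E[~free] = 1.0 / J[~free]
    return E


def zener_modulus(p: ZenerParams, omega) -> np.ndarray:
    """Zener dynamic modulus ``E_e (1 + i w tau_eps) / (1 + i w tau_sig)``.

    With ``tau_sig = 0`` this is the Kelvin-Voigt modulus
    ``E_e (1 + i w tau_eps) = E_e + i w eta``.
    """
    w = _check_omega(omega)
    return p.modulus * (1.0 + 1j * w * p.tau_eps) / (1.0 + 1j * w * p.tau_sig)


def kelvin_voigt_modulus(modulus: float, viscosity: float, omega) -> np.ndarray:
    """Kelvin-Voigt dynamic modulus ``E_e + i w eta``."""
    w = _check_omega(omega)
    return modulus + 1j * w * viscosity


# ---------------------------------------------------------------------------
# Zener <-> network


def zener_to_network(p: ZenerParams) -> SpringDamperNetwork:
    """Realize Zener parameters as a 3-element Maxwell-Wiechert network.

    The physical elements are ``eta = E_e (tau_eps - tau_sig)`` and
    ``E = eta / tau_sig`` in a Maxwell branch parallel to the equilibrium
    spring ``E_e``.  In the Kelvin-Voigt limit ``tau_sig = 0`` the branch
    spring stiffens to infinity and is replaced by a lone damper.
    """
    if p.tau_eps == p.tau_sig:
        raise ValueError(
            "tau_eps == tau_sig is a purely elastic degenerate (zero damper)"
        )
    eta = p.modulus * (p.tau_eps - p.tau_sig)
    if p.tau_sig == 0.0:
        units = (SpringDamperUnit(0.0, eta),)
    else:
        units = (SpringDamperUnit(eta / p.tau_sig, eta),)
    return SpringDamperNetwork(
        Topology.MAXWELL_WIECHERT, units, equilibrium_spring=p.modulus
    )


def _classify_units(net: SpringDamperNetwork):
    springs = [u for u in net.units if u.viscosity == 0.0]
    dampers = [u for u in net.units if u.stiffness == 0.0]
    full = [u for u in net.units if u.stiffness > 0.0 and u.viscosity > 0.0]
    return springs, dampers, full


def network_to_zener(net: SpringDamperNetwork) -> ZenerParams:
    """Read Zener parameters off a 3-element network (either topology).

    Maxwell-Wiechert form: equilibrium spring ``E_e`` plus one Maxwell
    branch ``(E, eta)`` gives ``tau_sig = eta / E``,
    ``1/E' = 1/E_e + 1/E``, ``tau_eps = eta / E'``; the branch with
    ``E = 0`` (direct dashpot) is the Kelvin-Voigt case ``tau_sig = 0``.
    Kelvin-chain form: lone series spring ``E_0`` plus one Kelvin unit.
    """
    springs, dampers, full = _classify_units(net)
    if net.topology is Topology.MAXWELL_WIECHERT:
        if springs or net.equilibrium_spring <= 0.0:
            raise ValueError("not a Zener/Kelvin-Voigt topology")
        Ee = net.equilibrium_spring
        if len(full) == 1 and not dampers:
            E, eta = full[0].stiffness, full[0].viscosity
            tau_sig = eta / E
            E_prime = 1.0 / (1.0 / Ee + 1.0 / E)
            return ZenerParams(Ee, eta / E_prime, tau_sig)
        if len(dampers) == 1 and not full:
            return ZenerParams(Ee, dampers[0].viscosity / Ee, 0.0)
        raise ValueError("not a Zener/Kelvin-Voigt topology")
    # Kelvin chain
    if dampers:
        raise ValueError("a lone series damper has no equilibrium stiffness")
    if len(full) == 1 and not springs:
        # single Kelvin unit == Kelvin-Voigt model
        u = full[0]
        return ZenerParams(u.stiffness, u.viscosity / u.stiffness, 0.0)
    if len(full) == 1 and len(springs) == 1:
        E0 = springs[0].stiffness
        E1, eta1 = full[0].stiffness, full[0].viscosity
        Ee = 1.0 / (1.0 / E0 + 1.0 / E1)
        tau_eps = eta1 / E1  # retardation time
        tau_sig = tau_eps * Ee / E0
        return ZenerParams(Ee, tau_eps, tau_sig)
    raise ValueError("not a Zener/Kelvin-Voigt topology")


# ---------------------------------------------------------------------------
# conjugation


def _zener_to_kelvin_chain(p: ZenerParams) -> SpringDamperNetwork:
    """Kelvin (series) realization of a Zener/Kelvin-Voigt model."""
    if p.tau_sig == 0.0:
        # Kelvin-Voigt: a single Kelvin unit
        units = (SpringDamperUnit(p.modulus, p.modulus * p.tau_eps),)
        return SpringDamperNetwork(Topology.KELVIN_CHAIN, units)
    E0 = p.glass_modulus  # series spring carries the glass compliance
    E1 = 1.0 / (1.0 / p.modulus - 1.0 / E0)
    eta1 = p.tau_eps * E1
    units = (SpringDamperUnit(E0, 0.0), SpringDamperUnit(E1, eta1))
    return SpringDamperNetwork(Topology.KELVIN_CHAIN, units)


def _fourparam_maxwell_to_kelvin(
    Ee: float, eta_d: float, E1: float, eta1: float
) -> SpringDamperNetwork:
    """Conjugate of {E_e || damper eta_d || Maxwell branch (E1, eta1)}.

    The modulus is a degree-(2,1) rational in ``i w`` with pole
    ``omega_sig = E1/eta1`` and zeros ``-omega_mu, -omega_eps``; its
    compliance splits into two partial fractions, i.e. two Kelvin units in
    series.
    """
    omega_sig = E1 / eta1
    # numerator polynomial of E(s)*(E1 + eta1 s) in s = i*omega
    c0 = Ee * E1
    c1 = Ee * eta1 + eta_d * E1 + E1 * eta1
    c2 = eta_d * eta1
    roots = np.roots([c2, c1, c0])  # both real negative for passive elements
    if np.any(np.abs(roots.imag) > 1e-9 * np.abs(roots.real)) or np.any(
        roots.real >= 0.0
    ):
        raise ValueError("modulus zeros are not negative real; not realizable")
    om_a, om_b = sorted(-roots.real)  # retardation rates omega_eps < omega_mu
    from .poroelastic import FourParamModel, fourparam_to_network

    return fourparam_to_network(FourParamModel(Ee, om_b, om_a, omega_sig))


def _two_kelvin_units_to_maxwell(units) -> SpringDamperNetwork:
    """Conjugate of two Kelvin units in series (four-parameter model)."""
    (Ea, eta_a), (Eb, eta_b) = (
        (u.stiffness, u.viscosity) for u in units
    )
    A, B = 1.0 / Ea, 1.0 / Eb  # partial-fraction compliance weights
    om_a, om_b = Ea / eta_a, Eb / eta_b  # retardation rates
    mu = 1.0 / (A + B)
    omega_sig = (A + B) / (A / om_b + B / om_a)  # zero of the compliance
    eta_d = mu * omega_sig / (om_a * om_b)
    eta1 = mu * (1.0 / om_a + 1.0 / om_b - 1.0 / omega_sig) - eta_d
    if eta1 < 0.0:
        raise ValueError("negative Maxwell-branch viscosity; not realizable")
    E1 = eta1 * omega_sig
    return SpringDamperNetwork(
        Topology.MAXWELL_WIECHERT,
        (SpringDamperUnit(0.0, eta_d), SpringDamperUnit(E1, eta1)),
        equilibrium_spring=mu,
    )


def conjugate_network(net: SpringDamperNetwork) -> SpringDamperNetwork:
    """Opposite-topology network with the identical dynamic modulus.

    Supported: single elements, Kelvin-Voigt, the 3-element Zener model and
    the 4-element four-parameter model.  General N-element conjugation is
    not implemented.
    """
    springs, dampers, full = _classify_units(net)
    if net.topology is Topology.MAXWELL_WIECHERT:
        Ee = net.equilibrium_spring
        if not net.units and Ee > 0.0:  # single spring
            return SpringDamperNetwork(
                Topology.KELVIN_CHAIN, (SpringDamperUnit(Ee, 0.0),)
            )
        if Ee == 0.0 and len(dampers) == 1 and not full and not springs:
            return SpringDamperNetwork(
                Topology.KELVIN_CHAIN, (SpringDamperUnit(0.0, dampers[0].viscosity),)
            )
        if Ee > 0.0 and not springs:
            if len(full) == 1 and not dampers:  # Zener
                return _zener_to_kelvin_chain(network_to_zener(net))
            if len(dampers) == 1 and not full:  # Kelvin-Voigt
                return _zener_to_kelvin_chain(network_to_zener(net))
            if len(dampers) == 1 and len(full) == 1:  # four-parameter
                return _fourparam_maxwell_to_kelvin(
                    Ee,
                    dampers[0].viscosity,
                    full[0].stiffness,
                    full[0].viscosity,
                )
        raise NotImplementedError(
            "conjugation implemented only for <= 4-element canonical forms"
        )
    # Kelvin chain side
    if len(net.units) == 1:
        (u,) = net.units
        if u.viscosity == 0.0:  # single spring
            return SpringDamperNetwork(
                Topology.MAXWELL_WIECHERT, (), equilibrium_spring=u.stiffness
            )
        if u.stiffness == 0.0:  # single damper
            return SpringDamperNetwork(
                Topology.MAXWELL_WIECHERT, (SpringDamperUnit(0.0, u.viscosity),)
            )
        # Kelvin-Voigt unit
        return zener_to_network(network_to_zener(net))
    if len(springs) == 1 and len(full) == 1 and not dampers:  # Zener (Kelvin form)
        return zener_to_network(network_to_zener(net))
    if len(full) == 2 and not springs and not dampers:  # four-parameter
        return _two_kelvin_units_to_maxwell(full)
    raise NotImplementedError(
        "conjugation implemented only for <= 4-element canonical forms"
    )


# ---------------------------------------------------------------------------
# time domain


def relaxation_modulus(net: SpringDamperNetwork, t) -> RelaxationResult:
    """Relaxation modulus ``G(t) = E_e + sum_n E_n exp(-t/tau_n)``.

    The direct-dashpot impulse ``G_- delta(t)`` is returned as the separate
    scalar ``impulse_weight`` and never sampled; ``t = 0`` is therefore
    allowed only when that weight vanishes.  Kelvin chains of supported size
    are first converted to their Maxwell-Wiechert conjugate.
    """
    if net.topology is Topology.KELVIN_CHAIN:
        net = conjugate_network(net)
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(ts < 0.0):
        raise ValueError("relaxation modulus is causal; t must be >= 0")
    g_minus = net.impulse_weight
    if g_minus > 0.0 and np.any(ts == 0.0):
        raise ValueError(
            "t = 0 sample requested but the network carries an impulse term "
            f"G_- = {g_minus}; sample t > 0 instead"
        )
    G = np.full(ts.shape, net.equilibrium_spring, dtype=float)
    for u in net.units:
        if u.stiffness > 0.0 and u.viscosity > 0.0:
            G += u.stiffness * np.exp(-ts / u.relaxation_time)
    return RelaxationResult(
        t=ts, values=G, equilibrium=net.equilibrium_spring, impulse_weight=g_minus
    )


# ---------------------------------------------------------------------------
# dispersion


def dispersion(modulus, density: float, omega) -> DispersionCurve:
    """Shear dispersion curve from a dynamic modulus sequence.

    ``k = omega sqrt(rho / E(omega))`` on the principal branch with
    ``Re k > 0``; phase velocity ``omega / Re k`` (continued to
    ``sqrt(E(0)/rho)`` at ``omega = 0``) and attenuation ``|Im k|``.
    """
    w = _check_omega(omega)
    E = np.atleast_1d(np.asarray(modulus, dtype=complex))
    if E.shape != w.shape:
        raise ValueError("modulus and omega must have matching shapes")
    if density <= 0.0:
        raise ValueError("density must be positive")
    if np.any(E.real <= 0.0):
        raise ValueError("dynamic modulus must have positive real part")
    k = w * np.sqrt(density / E)
    k = np.where(k.real < 0.0, -k, k)
    cp = np.empty(w.shape, dtype=float)
    still = w == 0.0
    cp[~still] = w[~still] / k[~still].real
    cp[still] = np.sqrt(E[still].real / density)
    return DispersionCurve(
        omega=w,
        modulus=E,
        wavenumber=k,
        phase_velocity=cp,
        attenuation=np.abs(k.imag),
        density=float(density),
    )


# ---------------------------------------------------------------------------
# rational form


def rational_from_network(net: SpringDamperNetwork) -> RationalModulus:
    """Expand a network's modulus into its rational coefficients.

    Sums the branch moduli (Maxwell-Wiechert) or unit compliances (Kelvin
    chain) as polynomial fractions in ``s = i*omega`` and normalizes the
    denominator's constant term to 1.
    """
    P = np.polynomial.polynomial

    def add(fr1, fr2):
        (n1, d1), (n2, d2) = fr1, fr2
        return P.polyadd(P.polymul(n1, d2), P.polymul(n2, d1)), P.polymul(d1, d2)

    if net.topology is Topology.MAXWELL_WIECHERT:
        frac = (np.array([net.equilibrium_spring]), np.array([1.0]))
        for u in net.units:
            if u.stiffness == 0.0:
                branch = (np.array([0.0, u.viscosity]), np.array([1.0]))
            elif u.viscosity == 0.0:
                continue
            else:
                branch = (
                    np.array([0.0, u.stiffness * u.viscosity]),
                    np.array([u.stiffness, u.viscosity]),
                )
            frac = add(frac, branch)
    else:
        frac = (np.array([0.0]), np.array([1.0]))
        for u in net.units:
            frac = add(frac, (np.array([1.0]), np.array([u.stiffness, u.viscosity])))
        frac = (frac[1], frac[0])  # invert compliance
    num, den = frac
    num, den = np.trim_zeros(num, "b"), np.trim_zeros(den, "b")
    if den.size == 0 or den[0] == 0.0:
        raise DegenerateNetworkError("modulus has a pole at omega = 0")
    num = num / den[0]
    den = den / den[0]
    return RationalModulus(tuple(num), tuple(den[1:]))
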