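"""Fractional Kelvin-Voigt/Zener rheology and its spring-damper content.

The fractional Zener model replaces the first-order stress/strain rates of
the standard linear solid by derivatives of non-integer order
``alpha in (0, 1]``; its dynamic modulus is

    E(omega) = E_e (1 + (i omega tau_eps)^alpha) / (1 + (i omega tau_sig)^alpha)

with ``tau_sig = 0`` giving the fractional Kelvin-Voigt model
``E_e (1 + (i omega tau_eps)^alpha)`` (a spring in parallel with a
spring-pot).  ``(i omega tau)^alpha`` is evaluated on the principal branch,
``(omega tau)^alpha exp(i alpha pi / 2)`` for ``omega >= 0``.

The central structural result implemented here is that these power-law
models are superpositions of ordinary spring-damper (Kelvin) units weighted
by a long-tailed spectral density.  The creep time-spectral density is

    R_eps(tau) = (1/(pi tau)) sin(alpha pi)
                 / ((tau/tau_eps)^alpha + (tau/tau_eps)^{-alpha}
                    + 2 cos(alpha pi)),

a unit-mass density with log-log asymptote slopes ``alpha - 1`` below and
``-alpha - 1`` above the knee at ``tau_eps``.  Its frequency-domain
counterpart ``S_eps(Omega) = a R_eps(1/Omega) / Omega^2`` (normalizing
compliance ``a = (1/E_e)(1 - (tau_sig/tau_eps)^alpha)``) feeds the creep
integral ``J(t) = int S_eps(Omega) (1 - exp(-Omega t)) dOmega``, whose
closed form is the Mittag-Leffler creep
``a (1 - E_alpha(-(t/tau_eps)^alpha))``.  Sampling ``S_eps`` on a log grid
turns the fractional model into a finite Kelvin chain (Prony-type
approximation); in the limit ``alpha -> 0`` the loss becomes frequency
independent and the model degenerates to structural hysteresis
``E = K + iH``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import quad
from scipy.special import rgamma

from .viscoelastic import (
    SpringDamperNetwork,
    SpringDamperUnit,
    Topology,
    ZenerParams,
    _check_omega,
    conjugate_network,
    zener_to_network,
)

__all__ = [
    "FractionalParams",
    "SpectralDensity",
    "HysteresisModulus",
    "SpectralCoverageError",
    "frac_modulus",
    "time_spectral",
    "freq_spectral",
    "creep_from_spectrum",
    "relaxation_from_spectrum",
    "mittag_leffler",
    "ml_creep",
    "discretize_spectrum",
    "hysteresis_modulus",
    "hysteresis_limit_check",
    "fit_loglog_slope",
]


class SpectralCoverageError(ValueError):
    """Raised when a sampled density is too narrow for accurate quadrature."""


@dataclass(frozen=True)
class FractionalParams:
    """Fractional Zener parameters ``(E_e, tau_eps, tau_sig, alpha)``.

    ``0 <= tau_sig < tau_eps``; ``alpha in (0, 1]``.  ``alpha = 1`` reduces
    exactly to :class:`~rheowave.viscoelastic.ZenerParams`, ``tau_sig = 0``
    to the (fractional) Kelvin-Voigt model.
    """

    modulus: float
    tau_eps: float
    tau_sig: float = 0.0
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not (self.modulus > 0.0):
            raise ValueError("equilibrium modulus must be positive")
        if not (0.0 <= self.tau_sig < self.tau_eps):
            raise ValueError("need 0 <= tau_sig < tau_eps")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("fractional order must lie in (0, 1]")

    @property
    def norm_compliance(self) -> float:
        """Transient creep amplitude ``a = (1/E_e)(1 - (tau_sig/tau_eps)^alpha)``."""
        return (1.0 - (self.tau_sig / self.tau_eps) ** self.alpha) / self.modulus

    def as_zener(self) -> ZenerParams:
        if self.alpha != 1.0:
            raise ValueError("only alpha = 1 maps onto the classical Zener model")
        return ZenerParams(self.modulus, self.tau_eps, self.tau_sig)


@dataclass(frozen=True)
class SpectralDensity:
    """A sampled (and, when analytic, evaluable) relaxation-process density.

    ``kind`` is ``"time"`` for ``R_eps(tau)`` against relaxation times or
    ``"frequency"`` for ``S_eps(Omega)`` against relaxation rates;
    ``norm_compliance`` is the constant ``a`` [1/Pa] linking the two
    (``S_eps(Omega) = a R_eps(1/Omega)/Omega^2``).  ``atom`` marks the
    degenerate single-relaxation case ``alpha = 1``, where the density is a
    delta function at ``tau_eps`` (or ``1/tau_eps``) rather than a sampled
    curve.
    """

    kind: str
    grid: np.ndarray
    values: np.ndarray
    norm_compliance: float
    atom: float | None = None
    params: FractionalParams | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("time", "frequency"):
            raise ValueError("kind must be 'time' or 'frequency'")
        if np.any(np.asarray(self.values) < 0.0):
            raise ValueError("spectral densities are non-negative")

    def evaluate(self, x) -> np.ndarray:
        """Closed-form density at ``x`` (requires analytic parameters)."""
        if self.params is None:
            raise ValueError("density carries no analytic parameters")
        if self.atom is not None:
            raise ValueError("atom (delta) densities cannot be point-evaluated")
        if self.kind == "time":
            return _r_eps(self.params, np.asarray(x, dtype=float))
        return _s_eps(self.params, np.asarray(x, dtype=float))


@dataclass(frozen=True)
class HysteresisModulus:
    """Structural (frequency-independent) damping ``E = K + iH``."""

    storage: float
    loss: float

    def __post_init__(self) -> None:
        if not (self.storage > 0.0):
            raise ValueError("storage constant K must be positive")
        if not (self.loss >= 0.0):
            raise ValueError("loss constant H must be non-negative")


# ---------------------------------------------------------------------------
# moduli


def frac_modulus(p: FractionalParams, omega) -> np.ndarray:
    """Fractional Zener/Kelvin-Voigt dynamic modulus (principal branch)."""
    w = _check_omega(omega)
    rot = np.exp(1j * p.alpha * np.pi / 2.0)
    num = 1.0 + (w * p.tau_eps) ** p.alpha * rot
    den = 1.0 + (w * p.tau_sig) ** p.alpha * rot
    return p.modulus * num / den


def hysteresis_modulus(h: HysteresisModulus, omega) -> np.ndarray:
    """Constant complex modulus ``K + iH`` at every frequency."""
    w = _check_omega(omega)
    return np.full(w.shape, h.storage + 1j * h.loss, dtype=complex)


def hysteresis_limit_check(
    modulus: float, tau_eps: float, eps_order: float, band: tuple[float, float]
) -> float:
    """Loss-flatness ratio of a fractional Kelvin-Voigt model.

    Evaluates ``Im E(omega)`` for the fractional KV model with
    ``alpha = eps_order`` across ``band`` (angular frequencies) and returns
    ``max/min``.  Since the loss varies as ``omega^alpha``, the ratio is
    ``(band_hi/band_lo)^alpha`` and tends to 1 as ``eps_order -> 0``: in
    that limit the model is indistinguishable from hysteresis on any fixed
    band.
    """
    if not (0.0 < eps_order <= 0.05):
        raise ValueError("eps_order must lie in (0, 0.05]")
    lo, hi = band
    if not (0.0 < lo < hi) or hi / lo < 100.0:
        raise ValueError("band must be ascending and span at least 2 decades")
    w = np.geomspace(lo, hi, 241)
    E = frac_modulus(FractionalParams(modulus, tau_eps, 0.0, eps_order), w)
    return float(E.imag.max() / E.imag.min())


# ---------------------------------------------------------------------------
# spectral densities


def _r_eps(p: FractionalParams, tau: np.ndarray) -> np.ndarray:
    x = tau / p.tau_eps
    a = p.alpha
    den = x**a + x**-a + 2.0 * np.cos(a * np.pi)
    return np.sin(a * np.pi) / (np.pi * tau * den)


def _s_eps(p: FractionalParams, om: np.ndarray) -> np.ndarray:
    a = p.alpha
    xe = om * p.tau_eps
    den = xe ** (2.0 * a) + 1.0 + 2.0 * xe**a * np.cos(a * np.pi)
    pref = (p.tau_eps**a - p.tau_sig**a) / (np.pi * p.modulus)
    return pref * om ** (a - 1.0) * np.sin(a * np.pi) / den


def time_spectral(p: FractionalParams, tau) -> SpectralDensity:
    """Creep time-spectral density ``R_eps(tau)`` of the fractional model.

    Unit-mass, long-tailed in both directions (slopes ``alpha - 1`` and
    ``-alpha - 1`` on a log-log plot).  For ``alpha = 1`` the density
    degenerates to a delta function at ``tau = tau_eps`` and is returned as
    a flagged atom, not a sampled curve.
    """
    t = np.atleast_1d(np.asarray(tau, dtype=float))
    if np.any(t <= 0.0):
        raise ValueError("relaxation times must be positive")
    if p.alpha == 1.0:
        return SpectralDensity(
            "time", t, np.zeros_like(t), p.norm_compliance, atom=p.tau_eps, params=p
        )
    return SpectralDensity("time", t, _r_eps(p, t), p.norm_compliance, params=p)


def freq_spectral(p: FractionalParams, omega_relax) -> SpectralDensity:
    """Creep frequency-spectral density ``S_eps(Omega)``.

    Pointwise equal to ``a R_eps(1/Omega)/Omega^2`` (an algebraic identity
    of the two closed forms); asymptote slopes ``alpha - 1`` (low) and
    ``-alpha - 1`` (high).  ``alpha = 1`` returns the single-relaxation
    atom at ``Omega = 1/tau_eps``.
    """
    om = np.atleast_1d(np.asarray(omega_relax, dtype=float))
    if np.any(om <= 0.0):
        raise ValueError("relaxation rates must be positive")
    if p.alpha == 1.0:
        return SpectralDensity(
            "frequency",
            om,
            np.zeros_like(om),
            p.norm_compliance,
            atom=1.0 / p.tau_eps,
            params=p,
        )
    return SpectralDensity("frequency", om, _s_eps(p, om), p.norm_compliance, params=p)


def fit_loglog_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Ordinary least-squares slope of ``log y`` against ``log x``."""
    lx, ly = np.log(np.asarray(x, float)), np.log(np.asarray(y, float))
    return float(np.polyfit(lx, ly, 1)[0])


# ---------------------------------------------------------------------------
# creep / relaxation superposition integrals


def _creep_analytic(p: FractionalParams, ts: np.ndarray) -> np.ndarray:
    """Adaptive log-substituted quadrature of the creep superposition.

    ``J(t) = int_0^inf S_eps(Omega) (1 - exp(-Omega t)) dOmega`` with the
    substitution ``u = ln Omega``.  The integrand is smooth and positive in
    ``u``; below ``Omega = 1e-10/t`` the contribution is negligible and
    above ``Omega = 40/t`` the exponential factor is dropped (error
    ``< e^-40``) so the power-law tail can be integrated to infinity.
    """

    out = np.empty(ts.shape, dtype=float)

    def body(u, t):
        om = np.exp(u)
        return _s_eps(p, om) * -np.expm1(-om * t) * om

    def tail(u):
        om = np.exp(u)
        with np.errstate(over="ignore"):
            return _s_eps(p, om) * om

    for i, t in enumerate(ts):
        u_lo = np.log(1e-10 / t)
        u_mid = np.log(40.0 / t)
        pts = [x for x in (np.log(1.0 / p.tau_eps), np.log(1.0 / t)) if u_lo < x < u_mid]
        main, _ = quad(
            body, u_lo, u_mid, args=(t,), points=sorted(pts) or None, limit=400,
            epsabs=1e-18, epsrel=1e-11,
        )
        # power-law tail: integrate until it has decayed by e^{-35} and close
        # with the asymptotic remainder int_cap^inf K Om^{-a-1} = S(cap) cap/a
        u_cap = min(700.0, max(u_mid, np.log(1.0 / p.tau_eps)) + 35.0 / p.alpha)
        rest, _ = quad(tail, u_mid, u_cap, limit=400, epsabs=1e-18, epsrel=1e-11)
        rest += tail(u_cap) / p.alpha
        out[i] = main + rest
    return out


def creep_from_spectrum(S: SpectralDensity, t) -> np.ndarray:
    """Transient creep compliance ``J(t)`` from a spectral density.

    For an analytic density the integral is evaluated by adaptive
    quadrature on ``u = ln Omega`` (absolute tolerance well below 1e-9 on
    the compliance); a purely sampled density is integrated by the
    trapezoidal rule on its own grid and must cover at least 12 decades.
    ``J(0+) = 0`` and ``J(inf) = a``, the normalizing compliance.
    """
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(ts <= 0.0):
        raise ValueError("creep times must be positive")
    if S.atom is not None:
        # single relaxation process: J(t) = a (1 - exp(-Omega_0 t))
        om0 = S.atom if S.kind == "frequency" else 1.0 / S.atom
        return S.norm_compliance * -np.expm1(-om0 * ts)
    if S.params is not None:
        p = S.params
        if S.kind == "time":
            # Eq. (time) form: J(t) = a int R(tau)(1 - e^{-t/tau}) dtau; same
            # integral after tau -> 1/Omega.
            pass
        return _creep_analytic(p, ts)
    if S.kind != "frequency":
        raise ValueError("sampled creep quadrature expects a frequency density")
    grid = np.asarray(S.grid, dtype=float)
    if grid[-1] / grid[0] < 1e12:
        raise SpectralCoverageError(
            "sampled density must cover at least 12 decades of relaxation rates"
        )
    om = grid[None, :]
    integrand = S.values[None, :] * -np.expm1(-om * ts[:, None])
    return np.trapezoid(integrand * om, np.log(grid), axis=1)


def relaxation_from_spectrum(S: SpectralDensity, t, amplitude: float = 1.0) -> np.ndarray:
    """Generic relaxation superposition on a user-supplied density.

    Evaluates ``G_tau(t) = b int R(tau) e^{-t/tau} dtau`` (time kind) or
    ``int S(Omega) e^{-Omega t} dOmega`` (frequency kind) by trapezoidal
    quadrature on the sampled grid; ``amplitude`` is the constant ``b``.
    """
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    grid = np.asarray(S.grid, dtype=float)
    vals = np.asarray(S.values, dtype=float)
    if S.kind == "time":
        kern = np.exp(-ts[:, None] / grid[None, :])
        return amplitude * np.trapezoid(vals[None, :] * kern * grid, np.log(grid), axis=1)
    kern = np.exp(-grid[None, :] * ts[:, None])
    return amplitude * np.trapezoid(vals[None, :] * kern * grid, np.log(grid), axis=1)


# ---------------------------------------------------------------------------
# Mittag-Leffler


def _ml_series(alpha: float, z: float) -> float:
    acc = 1.0
    term = 1.0
    for n in range(1, 220):
        term *= z
        contrib = term * rgamma(alpha * n + 1.0)
        acc += contrib
        if abs(contrib) < 1e-17 * abs(acc):
            break
    return acc


def _ml_integral(alpha: float, x: float) -> float:
    """Spectral representation of ``E_alpha(-x)`` for ``x > 0``.

    ``E_alpha(-x) = int_0^inf exp(-r X) K_alpha(r) dr`` with
    ``X = x^(1/alpha)`` and the completely monotone kernel
    ``K_alpha(r) = (1/pi) r^(alpha-1) sin(alpha pi)
    / (r^(2 alpha) + 2 r^alpha cos(alpha pi) + 1)``; integrated on
    ``v = ln r`` with the scale shifted so the exponential cut sits at
    ``v = -ln X``.
    """
    X = x ** (1.0 / alpha)
    lnX = np.log(X)
    s, c = np.sin(alpha * np.pi), np.cos(alpha * np.pi)

    def f(v):
        r = np.exp(v)
        ra = r**alpha
        return np.exp(-r * X) * (s / np.pi) * ra / (ra * ra + 2.0 * ra * c + 1.0)

    v_lo = -lnX - 40.0 / alpha
    v_hi = -lnX + np.log(45.0)
    pts = [v for v in (0.0, -lnX) if v_lo < v < v_hi]
    val, _ = quad(f, v_lo, v_hi, points=sorted(pts) or None, limit=400,
                  epsabs=0.0, epsrel=1e-13)
    return val


def mittag_leffler(alpha: float, z) -> np.ndarray | float:
    """Mittag-Leffler function ``E_alpha(z)`` on the completely monotone branch.

    Supports ``alpha in (0, 1]`` and real ``z <= 0`` to a relative accuracy
    of about 1e-10, switching between the Taylor series
    ``sum z^n / Gamma(alpha n + 1)`` for ``|z| <= 1`` and the spectral
    integral representation for larger arguments.  ``alpha = 1`` is the
    exponential.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("order must lie in (0, 1]")
    zs = np.atleast_1d(np.asarray(z, dtype=float))
    if np.any(zs > 0.0):
        raise ValueError("only the z <= 0 branch is supported")
    if alpha == 1.0:
        out = np.exp(zs)
    else:
        out = np.empty(zs.shape, dtype=float)
        for i, zi in enumerate(zs.ravel()):
            if zi >= -1.0:
                out.ravel()[i] = _ml_series(alpha, zi)
            else:
                out.ravel()[i] = _ml_integral(alpha, -zi)
    return out if np.ndim(z) else float(out[0])


def ml_creep(p: FractionalParams, t) -> np.ndarray:
    """Closed-form transient creep ``a (1 - E_alpha(-(t/tau_eps)^alpha))``.

    The independent oracle for :func:`creep_from_spectrum`.
    """
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    arg = -((ts / p.tau_eps) ** p.alpha)
    return p.norm_compliance * (1.0 - np.asarray(mittag_leffler(p.alpha, arg)))


# ---------------------------------------------------------------------------
# finite-chain (Prony-type) discretization


def discretize_spectrum(
    p: FractionalParams,
    n_per_decade: int = 8,
    band: tuple[float, float] | None = None,
    pad_decades: float | None = None,
) -> SpringDamperNetwork:
    """Approximate a fractional model by a finite Kelvin chain.

    Kelvin units are placed at log-uniform relaxation rates ``Omega_m``
    across ``band`` (angular rates, padded on each side so the spectral
    mass left outside is negligible; the default padding
    ``max(3, 3/alpha)`` decades tracks the slow ``Omega^{-alpha}`` tail
    decay).  Each unit carries the spectral mass of its own log cell,
    ``int_cell S_eps(Omega) dOmega`` (Simpson-integrated, so the lumped
    compliances never exceed the continuum mass), and a lone series spring
    carries the residual static compliance, which makes the chain's
    equilibrium compliance exactly ``1/E_e`` and its glass compliance the
    out-of-band remainder.  The chain is passive by construction
    (``S_eps >= 0``) and its on-band modulus error is non-increasing in
    ``n_per_decade``.

    For ``alpha = 1`` the density is an atom and a single Kelvin unit (plus
    series spring for the Zener case) reproduces the model exactly.
    """
    if n_per_decade < 1:
        raise ValueError("need at least one unit per decade")
    if band is None:
        band = (0.01 / p.tau_eps, 100.0 / p.tau_eps)
    lo, hi = band
    if not (0.0 < lo < hi) or np.log10(hi / lo) < 2.0:
        raise ValueError("band must be ascending and span at least 2 decades")
    if p.alpha == 1.0:
        # single relaxation atom: the exact Kelvin realization
        return conjugate_network(zener_to_network(p.as_zener()))
    if pad_decades is None:
        pad_decades = max(3.0, 3.0 / p.alpha)
    lg_lo = np.log10(lo) - pad_decades
    lg_hi = np.log10(hi) + pad_decades
    n = int(np.ceil((lg_hi - lg_lo) * n_per_decade))
    edges = np.logspace(lg_lo, lg_hi, n + 1)
    centers = np.sqrt(edges[:-1] * edges[1:])
    # per-cell spectral mass by composite Simpson on u = ln Omega
    nsub = 8
    u_edges = np.log(edges)
    offsets = np.linspace(0.0, 1.0, nsub + 1)
    u_s = u_edges[:-1, None] + np.diff(u_edges)[:, None] * offsets[None, :]
    om_s = np.exp(u_s)
    f = _s_eps(p, om_s.ravel()).reshape(om_s.shape) * om_s
    simp = np.array([1, 4, 2, 4, 2, 4, 2, 4, 1], dtype=float)
    weights = (np.diff(u_edges) / nsub / 3.0) * (f @ simp)
    units = [
        SpringDamperUnit(1.0 / Jm, 1.0 / (Jm * om))
        for Jm, om in zip(weights, centers)
        if Jm > 0.0
    ]
    residual = 1.0 / p.modulus - float(np.sum(weights))
    if residual <= 0.0:
        raise ValueError(
            "discrete weights exceed the static compliance; widen the band "
            "or reduce n_per_decade"
        )
    units.append(SpringDamperUnit(1.0 / residual, 0.0))
    return SpringDamperNetwork(Topology.KELVIN_CHAIN, tuple(units))
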