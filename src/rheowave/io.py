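"""Material files, dispersion CSV output, run reports and canonical fixtures.

Material descriptions are YAML or JSON mappings with a ``model`` tag, a
``parameters`` mapping in strict SI units and an optional
``frequency_grid``.  Frequencies are plain Hz at every user boundary and
converted to angular frequency internally.  Unknown keys are validation
errors, never warnings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .fractional import FractionalParams, HysteresisModulus
from .poroelastic import BiotParams, FourParamModel
from .viscoelastic import (
    DispersionCurve,
    SpringDamperNetwork,
    SpringDamperUnit,
    Topology,
    ZenerParams,
)

__all__ = [
    "MaterialFile",
    "MaterialValidationError",
    "FrequencyGrid",
    "load_material",
    "parse_material",
    "material_to_mapping",
    "write_dispersion_csv",
    "read_dispersion_csv",
    "write_spectrum_csv",
    "network_to_mapping",
    "build_report",
    "generate_fixtures",
]

DISPERSION_HEADER = (
    "freq_hz,re_E_pa,im_E_pa,re_k_per_m,im_k_per_m,"
    "phase_velocity_m_s,attenuation_np_m"
)

MODEL_NAMES = (
    "network",
    "kelvin_voigt",
    "zener",
    "fractional_kv",
    "fractional_zener",
    "biot",
    "bicsqs",
    "hysteresis",
)


class MaterialValidationError(ValueError):
    """A material file failed validation; the message names the failing key."""


@dataclass(frozen=True)
class FrequencyGrid:
    """User-facing frequency grid: Hz boundaries, log or linear spacing."""

    min_hz: float
    max_hz: float
    n: int = 200
    spacing: str = "log"

    def __post_init__(self) -> None:
        if not (0.0 < self.min_hz <= self.max_hz):
            raise MaterialValidationError("frequency_grid: need 0 < min_hz <= max_hz")
        if self.n < 1:
            raise MaterialValidationError("frequency_grid: n must be >= 1")
        if self.spacing not in ("log", "linear"):
            raise MaterialValidationError("frequency_grid: spacing must be log|linear")

    def hz(self) -> np.ndarray:
        if self.n == 1:
            return np.array([self.min_hz])
        if self.spacing == "log":
            return np.geomspace(self.min_hz, self.max_hz, self.n)
        return np.linspace(self.min_hz, self.max_hz, self.n)

    def omega(self) -> np.ndarray:
        return 2.0 * np.pi * self.hz()


@dataclass(frozen=True)
class MaterialFile:
    """A validated material description.

    ``model`` is one of the supported model tags; ``material`` the typed
    parameter object of the owning module; ``density`` [kg/m^3] the medium
    density where the model does not define one itself (the Biot model
    derives its aggregate density).
    """

    model: str
    material: Any
    density: float | None = None
    frequency_grid: FrequencyGrid | None = None


def _require_keys(mapping: dict, required: set[str], optional: set[str], where: str):
    unknown = set(mapping) - required - optional
    if unknown:
        raise MaterialValidationError(
            f"{where}: unknown key(s) {sorted(unknown)}"
        )
    missing = required - set(mapping)
    if missing:
        raise MaterialValidationError(f"{where}: missing key(s) {sorted(missing)}")


def _pos(mapping: dict, key: str, where: str) -> float:
    try:
        v = float(mapping[key])
    except (TypeError, ValueError) as exc:
        raise MaterialValidationError(f"{where}: key '{key}' is not a number") from exc
    return v


_BIOT_KEYS = {
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
}


def parse_material(doc: dict) -> MaterialFile:
    """Validate a decoded material mapping into typed parameters."""
    if not isinstance(doc, dict):
        raise MaterialValidationError("material file must be a mapping")
    _require_keys(
        doc, {"model", "parameters"}, {"frequency_grid"}, "material file"
    )
    model = doc["model"]
    if model not in MODEL_NAMES:
        raise MaterialValidationError(
            f"model: unknown model '{model}' (expected one of {MODEL_NAMES})"
        )
    pars = doc["parameters"]
    if not isinstance(pars, dict):
        raise MaterialValidationError("parameters: must be a mapping")
    grid = None
    if "frequency_grid" in doc:
        g = doc["frequency_grid"]
        _require_keys(g, {"min_hz", "max_hz"}, {"n", "spacing"}, "frequency_grid")
        grid = FrequencyGrid(
            _pos(g, "min_hz", "frequency_grid"),
            _pos(g, "max_hz", "frequency_grid"),
            int(g.get("n", 200)),
            str(g.get("spacing", "log")),
        )

    density = None
    try:
        if model == "network":
            _require_keys(
                pars,
                {"topology", "units"},
                {"equilibrium_spring", "density"},
                "parameters",
            )
            units = tuple(
                SpringDamperUnit(float(e), float(eta)) for e, eta in pars["units"]
            )
            material = SpringDamperNetwork(
                Topology(pars["topology"]),
                units,
                equilibrium_spring=float(pars.get("equilibrium_spring", 0.0)),
            )
        elif model == "kelvin_voigt":
            _require_keys(pars, {"modulus", "viscosity"}, {"density"}, "parameters")
            Ee = _pos(pars, "modulus", "parameters")
            eta = _pos(pars, "viscosity", "parameters")
            material = ZenerParams(Ee, eta / Ee, 0.0)
        elif model == "zener":
            _require_keys(
                pars, {"modulus", "tau_eps", "tau_sig"}, {"density"}, "parameters"
            )
            material = ZenerParams(
                _pos(pars, "modulus", "parameters"),
                _pos(pars, "tau_eps", "parameters"),
                _pos(pars, "tau_sig", "parameters"),
            )
        elif model in ("fractional_kv", "fractional_zener"):
            req = {"modulus", "tau_eps", "alpha"}
            if model == "fractional_zener":
                req = req | {"tau_sig"}
            _require_keys(pars, req, {"density"}, "parameters")
            material = FractionalParams(
                _pos(pars, "modulus", "parameters"),
                _pos(pars, "tau_eps", "parameters"),
                _pos(pars, "tau_sig", "parameters") if model == "fractional_zener" else 0.0,
                _pos(pars, "alpha", "parameters"),
            )
        elif model == "biot":
            _require_keys(pars, _BIOT_KEYS, set(), "parameters")
            material = BiotParams(**{k: _pos(pars, k, "parameters") for k in _BIOT_KEYS})
        elif model == "bicsqs":
            _require_keys(
                pars,
                {"shear_modulus", "omega_mu", "omega_eps", "omega_sig"},
                {"density"},
                "parameters",
            )
            material = FourParamModel(
                _pos(pars, "shear_modulus", "parameters"),
                _pos(pars, "omega_mu", "parameters"),
                _pos(pars, "omega_eps", "parameters"),
                _pos(pars, "omega_sig", "parameters"),
            )
        else:  # hysteresis
            _require_keys(pars, {"storage", "loss"}, {"density"}, "parameters")
            material = HysteresisModulus(
                _pos(pars, "storage", "parameters"), _pos(pars, "loss", "parameters")
            )
    except MaterialValidationError:
        raise
    except (ValueError, TypeError) as exc:
        raise MaterialValidationError(f"parameters: {exc}") from exc
    if isinstance(pars, dict) and "density" in pars:
        density = _pos(pars, "density", "parameters")
        if density <= 0.0:
            raise MaterialValidationError("parameters: density must be positive")
    return MaterialFile(model, material, density=density, frequency_grid=grid)


def load_material(path: str | Path) -> MaterialFile:
    """Read and validate a YAML or JSON material file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    return parse_material(doc)


# ---------------------------------------------------------------------------
# serialization helpers


def network_to_mapping(net: SpringDamperNetwork) -> dict:
    """JSON-ready mapping of a network in the material-file layout."""
    return {
        "model": "network",
        "parameters": {
            "topology": net.topology.value,
            "equilibrium_spring": net.equilibrium_spring,
            "units": [[u.stiffness, u.viscosity] for u in net.units],
        },
    }


def material_to_mapping(mat: MaterialFile) -> dict:
    """Echo a validated material back into a plain mapping."""
    m = mat.material
    if mat.model == "network":
        doc = network_to_mapping(m)
    elif mat.model == "kelvin_voigt":
        doc = {
            "model": "kelvin_voigt",
            "parameters": {"modulus": m.modulus, "viscosity": m.modulus * m.tau_eps},
        }
    elif mat.model == "zener":
        doc = {
            "model": "zener",
            "parameters": {
                "modulus": m.modulus,
                "tau_eps": m.tau_eps,
                "tau_sig": m.tau_sig,
            },
        }
    elif mat.model in ("fractional_kv", "fractional_zener"):
        pars = {"modulus": m.modulus, "tau_eps": m.tau_eps, "alpha": m.alpha}
        if mat.model == "fractional_zener":
            pars["tau_sig"] = m.tau_sig
        doc = {"model": mat.model, "parameters": pars}
    elif mat.model == "biot":
        doc = {
            "model": "biot",
            "parameters": {k: getattr(m, k) for k in sorted(_BIOT_KEYS)},
        }
    elif mat.model == "bicsqs":
        doc = {
            "model": "bicsqs",
            "parameters": {
                "shear_modulus": m.shear_modulus,
                "omega_mu": m.omega_mu,
                "omega_eps": m.omega_eps,
                "omega_sig": m.omega_sig,
            },
        }
    else:
        doc = {
            "model": "hysteresis",
            "parameters": {"storage": m.storage, "loss": m.loss},
        }
    if mat.density is not None:
        doc["parameters"]["density"] = mat.density
    if mat.frequency_grid is not None:
        g = mat.frequency_grid
        doc["frequency_grid"] = {
            "min_hz": g.min_hz,
            "max_hz": g.max_hz,
            "n": g.n,
            "spacing": g.spacing,
        }
    return doc


# ---------------------------------------------------------------------------
# CSV


def write_dispersion_csv(path: str | Path, curve: DispersionCurve) -> None:
    """Full-precision (%.17g) dispersion CSV; frequencies in Hz."""
    rows = np.column_stack(
        [
            curve.omega / (2.0 * np.pi),
            curve.modulus.real,
            curve.modulus.imag,
            curve.wavenumber.real,
            curve.wavenumber.imag,
            curve.phase_velocity,
            curve.attenuation,
        ]
    )
    with open(path, "w", newline="") as fh:
        fh.write(DISPERSION_HEADER + "\n")
        for row in rows:
            fh.write(",".join("%.17g" % v for v in row) + "\n")


def read_dispersion_csv(path: str | Path, density: float = 0.0) -> DispersionCurve:
    """Read a dispersion CSV back into a curve (inverse of the writer)."""
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return DispersionCurve(
        omega=2.0 * np.pi * data[:, 0],
        modulus=data[:, 1] + 1j * data[:, 2],
        wavenumber=data[:, 3] + 1j * data[:, 4],
        phase_velocity=data[:, 5],
        attenuation=data[:, 6],
        density=density,
    )


def write_spectrum_csv(path: str | Path, grid: np.ndarray, values: np.ndarray) -> None:
    """Two-column ``x,value`` CSV at full precision."""
    with open(path, "w", newline="") as fh:
        fh.write("x,value\n")
        for x, v in zip(grid, values):
            fh.write("%.17g,%.17g\n" % (x, v))


# ---------------------------------------------------------------------------
# run report


def build_report(
    material: MaterialFile,
    derived: dict[str, float],
    outputs: list[str],
    timestamp: str | None = None,
) -> dict:
    """Assemble a run report: input echo, derived quantities, output paths.

    Every derived quantity is recomputable from the echoed input.  The
    timestamp is omitted by default so identical inputs give byte-identical
    reports.
    """
    report = {
        "tool": "rheowave",
        "version": __version__,
        "input": material_to_mapping(material),
        "derived": derived,
        "outputs": list(outputs),
    }
    if timestamp is not None:
        report["timestamp"] = timestamp
    return report


# ---------------------------------------------------------------------------
# fixtures


_FIXTURES: dict[str, dict] = {
    "zener_unit.yaml": {
        "model": "zener",
        "parameters": {"modulus": 1.0, "tau_eps": 2.0, "tau_sig": 1.0, "density": 1.0},
        "frequency_grid": {"min_hz": 1e-3, "max_hz": 1e3, "n": 121, "spacing": "log"},
    },
    "frac_kv.yaml": {
        "model": "fractional_kv",
        "parameters": {
            "modulus": 2.0e3,
            "tau_eps": 0.01,
            "alpha": 0.3,
            "density": 1000.0,
        },
        "frequency_grid": {"min_hz": 1.0, "max_hz": 1e4, "n": 121, "spacing": "log"},
    },
    "frac_zener.yaml": {
        # time-constant ratio 1000 between tau_eps and tau_sig
        "model": "fractional_zener",
        "parameters": {
            "modulus": 2.0e3,
            "tau_eps": 1.0,
            "tau_sig": 1.0e-3,
            "alpha": 0.8,
            "density": 1000.0,
        },
        "frequency_grid": {"min_hz": 1e-3, "max_hz": 1e4, "n": 141, "spacing": "log"},
    },
    "biot_baseline.yaml": {
        "model": "biot",
        "parameters": {
            "porosity": 0.5,
            "solid_density": 2650.0,
            "fluid_density": 1000.0,
            "solid_bulk": 3.6e10,
            "fluid_bulk": 2.2e9,
            "fluid_viscosity": 1.0e-3,
            "permeability": 1.0e-11,
            "tortuosity": 1.25,
            "frame_bulk": 1.0e5,
            "frame_shear": 5.0e3,
        },
        "frequency_grid": {"min_hz": 1.0, "max_hz": 1e6, "n": 121, "spacing": "log"},
    },
    "bicsqs.yaml": {
        "model": "bicsqs",
        "parameters": {
            "shear_modulus": 5.0e3,
            "omega_mu": 1.0e6,
            "omega_eps": 4.0e4,
            "omega_sig": 5.123e4,
            "density": 1825.0,
        },
        "frequency_grid": {"min_hz": 10.0, "max_hz": 1e6, "n": 121, "spacing": "log"},
    },
}


def generate_fixtures(out_dir: str | Path) -> list[Path]:
    """Write the canonical test materials; each round-trips its validator."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, doc in _FIXTURES.items():
        parse_material(doc)  # must validate before writing
        path = out / name
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
        written.append(path)
    return written
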