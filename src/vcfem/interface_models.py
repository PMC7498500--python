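"""Electrode-electrolyte interface physics.

The metal/electrolyte boundary carries a mix of non-faradaic (capacitive
double layer) and faradaic (charge transfer) currents.  The double layer is
modeled as a constant-phase-angle (CPA) pseudocapacitance

    Z_CPA = K (j w)^(-beta)        [Ohm m^2]

and the faradaic path as a per-area charge transfer resistance

    R_CT = R T / (n F j0)          [Ohm m^2]

with gas constant R, temperature T, electrons per molecule n, Faraday
constant F and exchange current density j0.  The two in parallel give the
per-area surface admittance ``y = g + jb`` used by the Robin boundary
condition in the FEM assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GAS_CONSTANT = 8.314        # J/(mol K)
FARADAY_CONSTANT = 96485.0  # C/mol

__all__ = [
    "CPAParams",
    "ChargeTransferParams",
    "InterfaceModel",
    "cpa_impedance_area",
    "charge_transfer_resistance_area",
    "surface_admittance",
    "electrode_impedance",
    "cone_lateral_area",
]


@dataclass(frozen=True)
class CPAParams:
    """Constant-phase-angle pseudocapacitance, ``Z = K (jw)^-beta``.

    K in Ohm m^2 s^-beta; beta dimensionless in (0, 1].  beta = 1 reduces to
    an ideal capacitor with C = 1/K per unit area.
    """

    K: float = 1.57
    beta: float = 0.91

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be positive")
        if not (0.0 < self.beta <= 1.0):
            raise ValueError("beta must be in (0, 1]")


@dataclass(frozen=True)
class ChargeTransferParams:
    """Per-area charge transfer resistance parameters, ``RT/(n F j0)``.

    Defaults: body temperature, two electrons per molecule and a
    platinum-order exchange current density of 0.1 A/m^2.
    """

    T: float = 310.0
    n: int = 2
    j0: float = 0.1
    R: float = GAS_CONSTANT
    F: float = FARADAY_CONSTANT

    def __post_init__(self) -> None:
        for name in ("T", "n", "j0", "R", "F"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class InterfaceModel:
    """Electrode interface: faradaic, non-faradaic, or the two in parallel.

    ``fixed_frequency`` selects the equivalent-RC variant: the parallel
    network is collapsed to an R and C evaluated at that frequency, after
    which the admittance of that RC network is still evaluated at the
    requested frequency (the capacitive reactance remains
    frequency-dependent).
    """

    mode: str = "parallel"
    cpa: CPAParams = field(default_factory=CPAParams)
    ct: ChargeTransferParams = field(default_factory=ChargeTransferParams)
    fixed_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("faradaic", "nonfaradaic", "parallel"):
            raise ValueError(f"unknown interface mode {self.mode!r}")
        if self.fixed_frequency is not None and self.fixed_frequency <= 0:
            raise ValueError("fixed_frequency must be positive")


def cpa_impedance_area(cpa: CPAParams, f: float) -> complex:
    """CPA impedance per unit area at frequency ``f`` (Ohm m^2).

    Magnitude ``K w^-beta``, phase ``-beta pi/2``.  Diverges at DC: ``f = 0``
    raises; callers must use the faradaic path for the DC component.
    """
    if f <= 0:
        raise ValueError("CPA impedance diverges at f <= 0; use the DC/faradaic path")
    w = 2.0 * np.pi * f
    return complex(cpa.K * (1j * w) ** (-cpa.beta))


def charge_transfer_resistance_area(ct: ChargeTransferParams) -> float:
    """Charge transfer resistance per unit area (Ohm m^2)."""
    return ct.R * ct.T / (ct.n * ct.F * ct.j0)


def _raw_admittance(model: InterfaceModel, f: float) -> complex:
    if model.mode == "faradaic":
        return complex(1.0 / charge_transfer_resistance_area(model.ct))
    if f <= 0:
        raise ValueError(
            f"{model.mode} interface admittance is undefined at f <= 0; "
            "use a faradaic model for the DC component"
        )
    y = 1.0 / cpa_impedance_area(model.cpa, f)
    if model.mode == "parallel":
        y += 1.0 / charge_transfer_resistance_area(model.ct)
    return complex(y)


def surface_admittance(model: InterfaceModel, f: float) -> complex:
    """Per-area surface admittance ``y = g + jb`` (S/m^2) at frequency ``f``.

    Parallel mode adds the CPA and charge-transfer admittances; nonfaradaic
    is the CPA alone (infinite transfer resistance); faradaic is the real
    charge-transfer conductance alone.  With ``fixed_frequency`` set, the
    equivalent parallel R and C are computed at that frequency and the RC
    network is then evaluated at ``f``.
    """
    if model.fixed_frequency is None:
        return _raw_admittance(model, f)
    y0 = _raw_admittance(model, model.fixed_frequency)
    g = y0.real
    c = y0.imag / (2.0 * np.pi * model.fixed_frequency)  # F/m^2
    return complex(g + 1j * 2.0 * np.pi * f * c)


def electrode_impedance(model: InterfaceModel, area: float, f: float) -> complex:
    """Lumped interface impedance (Ohm) of an electrode of given area."""
    if area <= 0:
        raise ValueError("area must be positive")
    return 1.0 / (area * surface_admittance(model, f))


def cone_lateral_area(base_diameter: float, height: float) -> float:
    """Lateral (slant) surface area of a cone, ``pi r sqrt(r^2 + h^2)``.

    The base is excluded: for a conical electrode bonded to its substrate
    only the slant surface contacts the electrolyte.  ``height = 0`` reduces
    to the disc area ``pi r^2``.
    """
    if base_diameter < 0 or height < 0:
        raise ValueError("dimensions must be non-negative")
    r = base_diameter / 2.0
    return float(np.pi * r * np.hypot(r, height))
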