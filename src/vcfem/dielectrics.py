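"""Dielectric dispersion models and admittivity construction.

Tissue conductivity and relative permittivity are frequency dependent.  The
four-term Cole-Cole dispersion model expresses the complex relative
permittivity as

    eps_hat(w) = eps_inf + sum_n  delta_eps_n / (1 + (j w tau_n)^(1-alpha_n))
                 + sigma_ionic / (j w eps0)

from which ``eps_r = Re(eps_hat)`` and ``sigma = -w eps0 Im(eps_hat)``.
The complex admittivity combining conduction and displacement currents is

    y = sigma + j w eps0 eps_r .

The packaged tissue constants are the Gabriel et al. (1996) four-term
Cole-Cole parameter sets for grey matter, white matter, cerebrospinal fluid,
cortical bone and dry skin, plus an approximate saline entry for Ringer's
solution.  They can be overridden from YAML/JSON config files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

EPS0 = 8.85e-12  # vacuum permittivity, F/m

__all__ = [
    "EPS0",
    "ColeColeParams",
    "Admittivity",
    "TissueTable",
    "cole_cole_eval",
    "admittivity_of",
    "anisotropic_tensor",
    "load_tissue_table",
    "TISSUES",
]


@dataclass(frozen=True)
class ColeColeParams:
    """Four-term Cole-Cole dispersion parameters.

    Parameters
    ----------
    eps_inf : float
        High-frequency relative permittivity (dimensionless).
    delta_eps : tuple of 4 floats
        Dispersion magnitudes (dimensionless).
    tau : tuple of 4 floats
        Relaxation time constants (seconds).
    alpha : tuple of 4 floats
        Broadening exponents, each in ``[0, 1)``.
    sigma_ionic : float
        Static ionic conductivity (S/m).
    """

    eps_inf: float
    delta_eps: tuple[float, float, float, float]
    tau: tuple[float, float, float, float]
    alpha: tuple[float, float, float, float]
    sigma_ionic: float

    def __post_init__(self) -> None:
        if self.eps_inf < 0:
            raise ValueError("eps_inf must be non-negative")
        if len(self.delta_eps) != len(self.tau) or len(self.tau) != len(self.alpha):
            raise ValueError("delta_eps, tau and alpha must have equal length")
        if any(t <= 0 for t in self.tau):
            raise ValueError("all tau must be positive")
        if any(not (0.0 <= a < 1.0) for a in self.alpha):
            raise ValueError("all alpha must lie in [0, 1)")
        if any(d < 0 for d in self.delta_eps):
            raise ValueError("delta_eps must be non-negative")
        if self.sigma_ionic < 0:
            raise ValueError("sigma_ionic must be non-negative")


@dataclass(frozen=True)
class Admittivity:
    """Material admittivity ``y = sigma + j w eps0 eps_r`` at one frequency.

    ``sigma`` may be a scalar or a symmetric positive-definite 3x3 tensor;
    ``eps_r`` likewise (scalar or tensor).  ``value`` is the complex scalar
    (or 3x3 complex array) actually used in assembly.
    """

    sigma: object
    eps_r: object
    omega: float

    def __post_init__(self) -> None:
        sig = np.asarray(self.sigma, dtype=float)
        if sig.ndim == 2:
            if sig.shape != (3, 3):
                raise ValueError("tensor sigma must be 3x3")
            if not np.allclose(sig, sig.T, atol=1e-12 * max(1.0, abs(sig).max())):
                raise ValueError("tensor sigma must be symmetric")
            if np.linalg.eigvalsh(sig).min() <= 0:
                raise ValueError("tensor sigma must be positive definite")
        eps = np.asarray(self.eps_r, dtype=float)
        if np.any(eps < 0):
            raise ValueError("eps_r must be non-negative")

    @property
    def is_tensor(self) -> bool:
        return np.asarray(self.sigma).ndim == 2

    @property
    def value(self):
        """Complex admittivity (scalar or 3x3 complex array)."""
        sig = np.asarray(self.sigma, dtype=float)
        eps = np.asarray(self.eps_r, dtype=float)
        if sig.ndim == 2 and eps.ndim == 0:
            eps = float(eps) * np.eye(3)
        if sig.ndim == 0 and eps.ndim == 2:
            sig = float(sig) * np.eye(3)
        y = sig + 1j * self.omega * EPS0 * eps
        return complex(y) if y.ndim == 0 else y


def cole_cole_eval(params: ColeColeParams, f: float) -> tuple[float, float]:
    """Evaluate the four-term Cole-Cole model at frequency ``f`` (Hz).

    Returns ``(sigma, eps_r)`` with sigma in S/m.  ``f = 0`` is handled by the
    analytic limit: the ionic term contributes only to sigma and each
    dispersion term contributes its full ``delta_eps`` to ``eps_r``.
    """
    if f < 0:
        raise ValueError("frequency must be non-negative")
    if f == 0.0:
        return float(params.sigma_ionic), float(params.eps_inf + sum(params.delta_eps))
    w = 2.0 * np.pi * f
    eps_hat = complex(params.eps_inf)
    for de, tau, alpha in zip(params.delta_eps, params.tau, params.alpha):
        # principal branch: (jwt)^(1-a) = (wt)^(1-a) * exp(j pi (1-a)/2)
        eps_hat += de / (1.0 + (1j * w * tau) ** (1.0 - alpha))
    eps_hat += params.sigma_ionic / (1j * w * EPS0)
    eps_r = eps_hat.real
    sigma = -w * EPS0 * eps_hat.imag
    return float(sigma), float(eps_r)


def admittivity_of(sigma, eps_r, f: float) -> Admittivity:
    """Build an :class:`Admittivity` at frequency ``f`` (Hz)."""
    return Admittivity(sigma=sigma, eps_r=eps_r, omega=2.0 * np.pi * f)


def anisotropic_tensor(longitudinal: float, transverse: float, direction) -> np.ndarray:
    """Symmetric conductivity tensor with eigenvalues (long, trans, trans).

    ``direction`` is the longitudinal axis (normalized internally).
    """
    d = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(d)
    if nrm == 0:
        raise ValueError("direction must be a nonzero vector")
    d = d / nrm
    return transverse * np.eye(3) + (longitudinal - transverse) * np.outer(d, d)


# ---------------------------------------------------------------------------
# Packaged tissue constants
# ---------------------------------------------------------------------------
# Four-term Cole-Cole parameter sets from Gabriel, Lau & Gabriel (1996),
# "The dielectric properties of biological tissues: III".
TISSUES: dict[str, ColeColeParams] = {
    "grey": ColeColeParams(
        eps_inf=4.0,
        delta_eps=(45.0, 400.0, 2.0e5, 4.5e7),
        tau=(7.958e-12, 15.915e-9, 106.103e-6, 5.305e-3),
        alpha=(0.10, 0.15, 0.22, 0.00),
        sigma_ionic=0.02,
    ),
    "white": ColeColeParams(
        eps_inf=4.0,
        delta_eps=(32.0, 100.0, 4.0e4, 3.5e7),
        tau=(7.958e-12, 7.958e-9, 53.052e-6, 7.958e-3),
        alpha=(0.10, 0.10, 0.30, 0.02),
        sigma_ionic=0.02,
    ),
    "csf": ColeColeParams(
        eps_inf=4.0,
        delta_eps=(65.0, 40.0, 0.0, 0.0),
        tau=(7.958e-12, 1.592e-9, 159.155e-6, 15.915e-3),
        alpha=(0.10, 0.00, 0.00, 0.00),
        sigma_ionic=2.0,
    ),
    "skull": ColeColeParams(  # cortical bone
        eps_inf=2.5,
        delta_eps=(10.0, 180.0, 5.0e3, 1.0e5),
        tau=(13.263e-12, 79.577e-9, 159.155e-6, 15.915e-3),
        alpha=(0.20, 0.20, 0.20, 0.00),
        sigma_ionic=0.02,
    ),
    "scalp": ColeColeParams(  # dry skin
        eps_inf=4.0,
        delta_eps=(32.0, 1100.0, 0.0, 0.0),
        tau=(7.234e-12, 32.481e-9, 159.155e-6, 15.915e-3),
        alpha=(0.00, 0.20, 0.20, 0.20),
        sigma_ionic=0.0002,
    ),
    # Approximate physiological saline (single Debye pole of water plus ionic
    # conductivity); stand-in for Ringer's solution in bath fixtures.
    "ringer": ColeColeParams(
        eps_inf=4.0,
        delta_eps=(76.0, 0.0, 0.0, 0.0),
        tau=(8.1e-12, 1.0e-9, 1.0e-6, 1.0e-3),
        alpha=(0.0, 0.0, 0.0, 0.0),
        sigma_ionic=1.5,
    ),
}

# Static (low-frequency) conductivities in S/m for the purely resistive model.
STATIC_SIGMA: dict[str, float] = {
    "grey": 0.27,
    "white": 0.12,
    "csf": 1.65,
    "skull": 0.01,
    "scalp": 0.46,
    "ringer": 1.5,
}


@dataclass
class TissueTable:
    """Named tissue dielectric entries.

    Each entry resolves to a :class:`ColeColeParams` (dispersive evaluation)
    and a static conductivity for the purely resistive model.
    """

    cole_cole: dict[str, ColeColeParams] = field(default_factory=lambda: dict(TISSUES))
    static_sigma: dict[str, float] = field(default_factory=lambda: dict(STATIC_SIGMA))

    def params(self, name: str) -> ColeColeParams:
        try:
            return self.cole_cole[name]
        except KeyError:
            raise KeyError(
                f"unknown tissue {name!r}; known: {sorted(self.cole_cole)}"
            ) from None

    def sigma_static(self, name: str) -> float:
        try:
            return self.static_sigma[name]
        except KeyError:
            raise KeyError(
                f"no static conductivity for tissue {name!r}; known: "
                f"{sorted(self.static_sigma)}"
            ) from None

    def admittivity(self, name: str, f: float) -> Admittivity:
        """Dispersive admittivity of a named tissue at frequency ``f``."""
        sigma, eps_r = cole_cole_eval(self.params(name), f)
        return admittivity_of(sigma, eps_r, f)


def load_tissue_table(path) -> TissueTable:
    """Load tissue overrides from a YAML or JSON file.

    Schema per entry: ``name -> {eps_inf, delta_eps: [4], tau: [4],
    alpha: [4], sigma_ionic}`` for dispersive entries, or
    ``name -> {sigma, eps_r}`` for static entries (expanded to a
    dispersionless Cole-Cole record).
    """
    text = open(path).read()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError:
        import yaml

        raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ValueError("tissue table file must contain a mapping")
    table = TissueTable()
    for name, entry in raw.items():
        if "sigma" in entry:
            eps_r = float(entry.get("eps_r", 1.0))
            table.cole_cole[name] = ColeColeParams(
                eps_inf=eps_r,
                delta_eps=(0.0, 0.0, 0.0, 0.0),
                tau=(1e-12, 1e-9, 1e-6, 1e-3),
                alpha=(0.0, 0.0, 0.0, 0.0),
                sigma_ionic=float(entry["sigma"]),
            )
            table.static_sigma[name] = float(entry["sigma"])
        else:
            table.cole_cole[name] = ColeColeParams(
                eps_inf=float(entry["eps_inf"]),
                delta_eps=tuple(float(x) for x in entry["delta_eps"]),
                tau=tuple(float(x) for x in entry["tau"]),
                alpha=tuple(float(x) for x in entry["alpha"]),
                sigma_ionic=float(entry["sigma_ionic"]),
            )
            if "sigma_static" in entry:
                table.static_sigma[name] = float(entry["sigma_static"])
    return table
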