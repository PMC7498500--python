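"""FEM-Fourier transient stimulation.

A stimulating voltage waveform is decomposed with a one-sided real FFT, the
frequency-domain FEM problem is solved once per retained frequency (with
material and electrode-interface properties evaluated per the selected
modes), and probe-point time courses are reconstructed by the inverse FFT.

Material modes
    ``dispersive``  sigma(w), eps_r(w) from the Cole-Cole model per frequency.
    ``capacitive``  sigma, eps_r frozen at the record's average frequency;
                    the displacement term j w eps0 eps_r still scales with w.

Interface modes
    ``cpa``  parallel CPA / charge-transfer surface admittance per frequency.
    ``rc``   equivalent parallel R and C evaluated at the average frequency;
             the capacitive reactance of that RC network remains frequency
             dependent.

The DC (f = 0) component is solved with a purely resistive assembly and a
faradaic interface, since both the CPA impedance and the ionic 1/(jw) term
diverge at DC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from vcfem import fem_core as fc
from vcfem.dielectrics import EPS0, ColeColeParams, cole_cole_eval
from vcfem.interface_models import InterfaceModel
from vcfem.meshkit import TetMesh

__all__ = [
    "Waveform",
    "FourierJob",
    "make_pulse",
    "decompose",
    "reconstruct",
    "prune_frequencies",
    "average_frequency",
    "run_fourier_job",
]


@dataclass
class Waveform:
    """Uniformly sampled time series (V or A)."""

    samples: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.samples))


def make_pulse(shape: str, amplitude: float, duration: float, dt: float,
               record_length: float) -> Waveform:
    """Activity waveform centered in a zero-padded record.

    ``shape`` is ``square`` (flat pulse), ``alpha`` (alpha function
    ``(t/tau) exp(1 - t/tau)`` with tau = duration/5) or ``sine`` (one full
    period over the duration, hence zero-mean).  Deterministic.
    """
    if duration > record_length:
        raise ValueError("duration exceeds record_length")
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    n = int(round(record_length / dt))
    samples = np.zeros(n)
    n_on = int(round(duration / dt))
    start = (n - n_on) // 2
    t = dt * np.arange(n_on)
    if shape == "square":
        samples[start:start + n_on] = amplitude
    elif shape == "alpha":
        tau = duration / 5.0
        samples[start:start + n_on] = amplitude * (t / tau) * np.exp(1.0 - t / tau)
    elif shape == "sine":
        samples[start:start + n_on] = amplitude * np.sin(2.0 * np.pi * t / duration)
    else:
        raise ValueError(f"unknown pulse shape {shape!r}")
    return Waveform(samples=samples, dt=dt)


def decompose(w: Waveform) -> tuple[np.ndarray, np.ndarray]:
    """One-sided real FFT: N samples -> N//2 + 1 frequencies in [0, 1/(2 dt)].

    ``reconstruct`` inverts the decomposition exactly (to rounding).
    """
    coeffs = np.fft.rfft(w.samples)
    freqs = np.fft.rfftfreq(len(w.samples), w.dt)
    return freqs, coeffs


def reconstruct(coeffs: np.ndarray, n_samples: int, dt: float,
                t0: float = 0.0) -> Waveform:
    """Inverse of :func:`decompose`."""
    return Waveform(samples=np.fft.irfft(coeffs, n=n_samples), dt=dt, t0=t0)


def average_frequency(w: Waveform) -> float:
    """Amplitude-weighted mean frequency of the record's one-sided spectrum.

    ``sum f |c(f)| / sum |c(f)|`` over positive frequencies.
    """
    freqs, coeffs = decompose(w)
    mag = np.abs(coeffs[1:])
    total = mag.sum()
    if total == 0:
        raise ValueError("waveform has no spectral content")
    return float((freqs[1:] * mag).sum() / total)


def prune_frequencies(coeffs: np.ndarray, threshold: float) -> np.ndarray:
    """Mask of retained coefficients: ``|c| >= threshold * max|c|`` plus DC.

    ``threshold = 0`` retains everything; ``threshold = 1`` retains DC and
    the peak coefficient(s) only.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    mag = np.abs(coeffs)
    keep = mag >= threshold * mag.max()
    keep[0] = True
    return keep


# ---------------------------------------------------------------------------
# Job definition and execution
# ---------------------------------------------------------------------------

@dataclass
class FourierJob:
    """One FEM-Fourier run.

    ``tissue_map`` maps cell markers to :class:`ColeColeParams`;
    ``stimulating_marker`` carries the waveform as its metal potential,
    ``ground_markers`` are held at zero.  ``probes`` are evaluation points.
    """

    mesh: TetMesh
    tissue_map: Mapping[int, ColeColeParams]
    material_mode: str
    interface_mode: str
    waveform: Waveform
    stimulating_marker: int
    ground_markers: Sequence[int]
    probes: np.ndarray
    interface: InterfaceModel = field(default_factory=lambda: InterfaceModel("parallel"))
    prune_threshold: float = 1e-4
    solver_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.material_mode not in ("capacitive", "dispersive"):
            raise ValueError(f"unknown material mode {self.material_mode!r}")
        if self.interface_mode not in ("rc", "cpa"):
            raise ValueError(f"unknown interface mode {self.interface_mode!r}")
        self.probes = np.atleast_2d(np.asarray(self.probes, dtype=float))


def _material_value(params: ColeColeParams, f: float, mode: str,
                    f_avg: float) -> complex:
    """Admittivity y(f) for the selected material mode."""
    if f == 0.0:
        # purely resistive DC component
        if mode == "dispersive":
            return complex(params.sigma_ionic)
        sigma, _ = cole_cole_eval(params, f_avg)
        return complex(sigma)
    f_mat = f if mode == "dispersive" else f_avg
    sigma, eps_r = cole_cole_eval(params, f_mat)
    return complex(sigma + 1j * 2.0 * np.pi * f * EPS0 * eps_r)


def _interface_model(base: InterfaceModel, f: float, mode: str,
                     f_avg: float) -> InterfaceModel:
    if f == 0.0:
        return InterfaceModel(mode="faradaic", cpa=base.cpa, ct=base.ct)
    if mode == "cpa":
        return base
    return InterfaceModel(mode=base.mode, cpa=base.cpa, ct=base.ct,
                          fixed_frequency=f_avg)


def run_fourier_job(job: FourierJob) -> dict:
    """Execute the FEM-Fourier loop.

    Returns ``{"probes": (n_probes, n_samples) array, "input": Waveform,
    "frequencies_solved": int, "pruned_reconstruction_error": float,
    "average_frequency": float}``.  The per-frequency solves use unit
    stimulus amplitude (linearity) and are scaled by the FFT coefficients
    before the inverse transform.
    """
    freqs, coeffs = decompose(job.waveform)
    keep = prune_frequencies(coeffs, job.prune_threshold)
    dropped = coeffs.copy()
    dropped[keep] = 0.0
    recon_err = float(np.linalg.norm(dropped) / max(np.linalg.norm(coeffs), 1e-300))
    f_avg = average_frequency(job.waveform)

    n_probes = len(job.probes)
    H = np.zeros((n_probes, len(freqs)), dtype=complex)
    failures = []
    for idx in np.flatnonzero(keep):
        f = float(freqs[idx])
        mat = {m: _material_value(p, f, job.material_mode, f_avg)
               for m, p in job.tissue_map.items()}
        ifm = _interface_model(job.interface, f, job.interface_mode, f_avg)
        if f == 0.0:
            system = fc.assemble_stiffness(job.mesh,
                                           {m: v.real for m, v in mat.items()})
            method, pre = "cg", "jacobi"
        else:
            system = fc.assemble_complex_block(job.mesh, mat)
            method, pre = "gmres", "ilu"
        fc.add_robin_interface(system, fc.ElectrodeSpec(
            job.stimulating_marker, "stimulating", ifm, phi_metal=1.0), f)
        for g in job.ground_markers:
            fc.add_robin_interface(system, fc.ElectrodeSpec(g, "ground", ifm), f)
        try:
            fld = fc.solve(system, method=method, tol=job.solver_tol,
                           preconditioner=pre, max_iter=10000)
        except fc.SolverError as exc:
            failures.append((f, str(exc)))
            continue
        H[:, idx] = fc.evaluate(fld, job.probes)
    if failures:
        raise fc.SolverError(
            f"{len(failures)} frequency solves failed: "
            + ", ".join(f"{f:.6g} Hz" for f, _ in failures[:10])
        )

    out = np.zeros((n_probes, len(job.waveform.samples)))
    for p in range(n_probes):
        spec = coeffs * H[p] * keep
        out[p] = np.fft.irfft(spec, n=len(job.waveform.samples))
    return {
        "probes": out,
        "input": job.waveform,
        "frequencies_solved": int(keep.sum()),
        "pruned_reconstruction_error": recon_err,
        "average_frequency": f_avg,
    }
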