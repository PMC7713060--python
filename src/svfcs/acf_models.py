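"""Closed-form FCS autocorrelation models for 3D diffusion.

A fluorophore diffusing through a 3D-Gaussian confocal observation volume
(lateral waist w0, axial extent z0, illumination-profile factor gamma)
produces the classic single-species autocorrelation

    G(tau) = (gamma / N) * 1/(1 + tau/tau_D) * 1/sqrt(1 + (tau/tau_D)(w0/z0)^2)

with amplitude G(0) = gamma/N set by the mean number N of fluorescent
objects in the volume, and diffusion time tau_D = w0^2 / (4 D).  A
number-weighted two-species sum describes mixtures of a fast (free) and a
slow (vesicle-bound) pool.  Units are micrometres, seconds and um^2/s
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .correlator import ACFCurve

__all__ = [
    "ObservationVolume",
    "OneComponentParams",
    "TwoComponentParams",
    "acf_one_component",
    "acf_two_component",
    "diffusion_time",
    "diffusion_coefficient",
    "normalize_acf",
]

#: Default illumination-profile factor of the instrument model.
DEFAULT_GAMMA = 0.35
#: Default structure parameter z0/w0 (elongation of the confocal volume).
DEFAULT_Z_RATIO = 5.0


@dataclass(frozen=True)
class ObservationVolume:
    """Confocal observation-volume geometry.

    Attributes
    ----------
    w0 : float
        Lateral 1/e^2 waist in um.
    z0 : float
        Axial 1/e^2 extent in um; at least ``w0``.
    gamma : float
        Illumination-profile factor in (0, 1] relating G(0) to 1/N.
    """

    w0: float
    z0: float
    gamma: float = DEFAULT_GAMMA

    def __post_init__(self) -> None:
        if not (np.isfinite(self.w0) and self.w0 > 0):
            raise ValueError(f"w0 must be positive, got {self.w0}")
        if not (np.isfinite(self.z0) and self.z0 >= self.w0):
            raise ValueError("z0 must satisfy z0 >= w0")
        if not (0 < self.gamma <= 1):
            raise ValueError("gamma must lie in (0, 1]")

    @classmethod
    def default(
        cls,
        w0: float = 0.31,
        z_ratio: float = DEFAULT_Z_RATIO,
        gamma: float = DEFAULT_GAMMA,
    ) -> "ObservationVolume":
        """Typical calibrated volume: w0 = 310 nm, z0/w0 = 5, gamma = 0.35."""
        return cls(w0=w0, z0=w0 * z_ratio, gamma=gamma)

    @property
    def aspect_sq(self) -> float:
        """(w0/z0)^2, the squared inverse structure parameter."""
        return (self.w0 / self.z0) ** 2

    @property
    def effective_volume(self) -> float:
        """Effective detection volume pi^{3/2} w0^2 z0 in um^3."""
        return float(np.pi**1.5 * self.w0**2 * self.z0)


@dataclass(frozen=True)
class OneComponentParams:
    """Single diffusing species: mean occupancy N and diffusion time tau_D [s]."""

    N: float
    tau_D: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.N) and self.N > 0):
            raise ValueError(f"N must be positive, got {self.N}")
        if not (np.isfinite(self.tau_D) and self.tau_D > 0):
            raise ValueError(f"tau_D must be positive, got {self.tau_D}")


@dataclass(frozen=True)
class TwoComponentParams:
    """Two diffusing species; species 1 is the fast (free) pool by convention."""

    N1: float
    N2: float
    tau_D1: float
    tau_D2: float

    def __post_init__(self) -> None:
        for name in ("N1", "N2"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.N1 + self.N2 <= 0:
            raise ValueError("total occupancy N1 + N2 must be positive")
        for name in ("tau_D1", "tau_D2"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive, got {v}")

    def canonical(self) -> "TwoComponentParams":
        """Return parameters reordered so that tau_D1 <= tau_D2 (fast first)."""
        if self.tau_D1 <= self.tau_D2:
            return self
        return TwoComponentParams(
            N1=self.N2, N2=self.N1, tau_D1=self.tau_D2, tau_D2=self.tau_D1
        )

    @property
    def bound_fraction(self) -> float:
        """Number fraction of the slow species, N2/(N1+N2)."""
        return self.N2 / (self.N1 + self.N2)


def _check_tau(tau) -> np.ndarray:
    tau = np.asarray(tau, dtype=float)
    if not np.all(np.isfinite(tau)):
        raise ValueError("tau contains non-finite values")
    if np.any(tau < 0):
        raise ValueError("tau must be non-negative")
    return tau


def _unit_shape(tau: np.ndarray, tau_D: float, aspect_sq: float) -> np.ndarray:
    """Unit-amplitude single-species shape G_i(tau), equal to 1 at tau = 0."""
    r = tau / tau_D
    return 1.0 / (1.0 + r) / np.sqrt(1.0 + r * aspect_sq)


def acf_one_component(tau, params: OneComponentParams, vol: ObservationVolume):
    """Single-species 3D-diffusion autocorrelation; G(0) = gamma/N."""
    tau = _check_tau(tau)
    return vol.gamma / params.N * _unit_shape(tau, params.tau_D, vol.aspect_sq)


def acf_two_component(tau, params: TwoComponentParams, vol: ObservationVolume):
    """Number-weighted two-species autocorrelation; G(0) = gamma/(N1+N2).

    Equal molecular brightness of the two species is assumed, so each
    contributes in proportion to its occupancy:
    G(tau) = gamma/N^2 * (N1 G1(tau) + N2 G2(tau)) with N = N1 + N2.
    """
    tau = _check_tau(tau)
    n_tot = params.N1 + params.N2
    mix = params.N1 * _unit_shape(
        tau, params.tau_D1, vol.aspect_sq
    ) + params.N2 * _unit_shape(tau, params.tau_D2, vol.aspect_sq)
    return vol.gamma / n_tot**2 * mix


def diffusion_time(D: float, w0: float) -> float:
    """Diffusion time tau_D = w0^2 / (4 D) for lateral waist w0 [um], D [um^2/s]."""
    if not (np.isfinite(D) and D > 0):
        raise ValueError(f"D must be positive, got {D}")
    if not (np.isfinite(w0) and w0 > 0):
        raise ValueError(f"w0 must be positive, got {w0}")
    return w0**2 / (4.0 * D)


def diffusion_coefficient(tau_D: float, w0: float) -> float:
    """Inverse of :func:`diffusion_time`: D = w0^2 / (4 tau_D)."""
    if not (np.isfinite(tau_D) and tau_D > 0):
        raise ValueError(f"tau_D must be positive, got {tau_D}")
    if not (np.isfinite(w0) and w0 > 0):
        raise ValueError(f"w0 must be positive, got {w0}")
    return w0**2 / (4.0 * tau_D)


def normalize_acf(curve: ACFCurve) -> ACFCurve:
    """Rescale a curve to unit maximum (for overlay plots of shapes)."""
    finite = curve.values[np.isfinite(curve.values)]
    if finite.size == 0 or finite.max() <= 0:
        raise ValueError("curve has no positive finite value to normalize by")
    peak = finite.max()
    return replace(curve, values=curve.values / peak, se=None)
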