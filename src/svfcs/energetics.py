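"""Two-state Boltzmann energetics of transient vesicle binding.

A protein that exchanges between a free state f and a vesicle-bound state
b, with both states always accessible (no saturation), has equilibrium
occupancies set by Boltzmann statistics:

    p_b / p_f = exp((E_f - E_b) / kBT)

so the energy difference follows directly from the measured bound
fraction, Delta E = E_f - E_b = kBT ln(p_b / (1 - p_b)).  Assigning the
free state its translational thermal energy E_f = 3/2 kBT (three degrees
of freedom) pins the bound-state energy E_b = 3/2 - ln(p_b/(1-p_b)) in
kBT units.  In equilibrium the same ratio fixes the transition rates:
r_fb / r_bf = p_b / p_f, i.e. entering the bound state is p_b/p_f times
slower than leaving it whenever p_b < 1/2.

All energies are dimensionless multiples of kBT; no absolute temperature
handling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TwoStateEnergetics",
    "EnergeticsRow",
    "energy_difference",
    "bound_state_energy",
    "rate_ratio",
    "bound_fraction_from_energy",
    "energetics_table",
]

#: Free-state energy: 3 translational degrees of freedom, f/2 kBT.
E_FREE = 1.5


def _check_pb(p_b: float) -> float:
    p_b = float(p_b)
    if not np.isfinite(p_b) or not (0.0 < p_b < 1.0):
        raise ValueError(
            f"bound fraction must lie strictly inside (0, 1); got {p_b} "
            "(the energy difference diverges at the endpoints)"
        )
    return p_b


def energy_difference(p_b: float) -> float:
    """Delta E = E_f - E_b = ln(p_b / (1 - p_b)) in kBT; negative iff p_b < 1/2."""
    p_b = _check_pb(p_b)
    return float(np.log(p_b / (1.0 - p_b)))


def bound_state_energy(p_b: float) -> float:
    """E_b = 3/2 - ln(p_b / (1 - p_b)) in kBT; strictly decreasing in p_b."""
    return E_FREE - energy_difference(p_b)


def rate_ratio(p_b: float) -> float:
    """Equilibrium transition-rate ratio r_fb / r_bf = p_b / (1 - p_b)."""
    p_b = _check_pb(p_b)
    return p_b / (1.0 - p_b)


def bound_fraction_from_energy(delta_e: float) -> float:
    """Invert :func:`energy_difference`: p_b = exp(dE) / (1 + exp(dE))."""
    if not np.isfinite(delta_e):
        raise ValueError("delta_e must be finite")
    # logistic form, stable for large |delta_e|
    return float(1.0 / (1.0 + np.exp(-delta_e)))


@dataclass(frozen=True)
class TwoStateEnergetics:
    """Complete two-state characterization derived from one bound fraction."""

    p_b: float
    p_f: float
    delta_E: float
    E_f: float
    E_b: float
    rate_ratio: float

    @classmethod
    def from_bound_fraction(cls, p_b: float) -> "TwoStateEnergetics":
        p_b = _check_pb(p_b)
        de = energy_difference(p_b)
        return cls(
            p_b=p_b,
            p_f=1.0 - p_b,
            delta_E=de,
            E_f=E_FREE,
            E_b=E_FREE - de,
            rate_ratio=p_b / (1.0 - p_b),
        )


@dataclass
class EnergeticsRow:
    """Per-condition energetics summary (energies in kBT)."""

    condition: str
    p_b_mean: float
    p_b_sd: float
    delta_E: float
    delta_E_sd: float | None
    E_b: float
    E_b_sd: float | None
    rate_ratio: float
    rate_ratio_sd: float | None
    mode: str
    n: int


def energetics_table(summaries, averaging: str = "per_point") -> list[EnergeticsRow]:
    """Convert per-condition bound fractions into energetics rows.

    ``averaging='per_point'`` evaluates the (nonlinear) energetics for each
    retained curve and then averages, reporting mean +/- SD;
    ``averaging='of_mean'`` evaluates once at the mean bound fraction.  The
    two differ for scattered p_b because E_b is convex below p_b = 1/2
    (Jensen's inequality), so both modes are recorded explicitly.  Curves
    with bound fractions outside (0, 1) are skipped with a warning.
    """
    if averaging not in ("per_point", "of_mean"):
        raise ValueError(f"unknown averaging mode {averaging!r}")
    rows = []
    for summary in summaries:
        pbs = []
        for f in summary.fits:
            pb = getattr(f, "bound_fraction", None)
            if pb is None:
                continue
            if not (0.0 < pb < 1.0):
                warnings.warn(
                    f"{summary.condition}: bound fraction {pb} outside (0,1), "
                    "curve skipped",
                    stacklevel=2,
                )
                continue
            pbs.append(pb)
        if not pbs:
            continue
        pbs = np.asarray(pbs)
        p_mean = float(pbs.mean())
        p_sd = float(pbs.std(ddof=1)) if len(pbs) > 1 else 0.0
        if averaging == "of_mean":
            e = TwoStateEnergetics.from_bound_fraction(p_mean)
            rows.append(
                EnergeticsRow(
                    condition=summary.condition,
                    p_b_mean=p_mean,
                    p_b_sd=p_sd,
                    delta_E=e.delta_E,
                    delta_E_sd=None,
                    E_b=e.E_b,
                    E_b_sd=None,
                    rate_ratio=e.rate_ratio,
                    rate_ratio_sd=None,
                    mode=averaging,
                    n=len(pbs),
                )
            )
        else:
            des = np.array([energy_difference(p) for p in pbs])
            ebs = E_FREE - des
            rrs = pbs / (1.0 - pbs)
            sd = lambda a: float(a.std(ddof=1)) if len(a) > 1 else 0.0
            rows.append(
                EnergeticsRow(
                    condition=summary.condition,
                    p_b_mean=p_mean,
                    p_b_sd=p_sd,
                    delta_E=float(des.mean()),
                    delta_E_sd=sd(des),
                    E_b=float(ebs.mean()),
                    E_b_sd=sd(ebs),
                    rate_ratio=float(rrs.mean()),
                    rate_ratio_sd=sd(rrs),
                    mode=averaging,
                    n=len(pbs),
                )
            )
    return rows
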