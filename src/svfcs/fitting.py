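"""Nonlinear least-squares fitting of FCS autocorrelation curves.

One- and two-component diffusion models are fitted by trust-region
nonlinear least squares (``scipy.optimize.least_squares``) with a
log-spaced multi-start over the diffusion time(s), since the objective has
local minima when two timescales are present.  Derived quantities follow
the field conventions: D = w0^2/(4 tau_D), bound fraction p_b = N2/(N1+N2)
under the equal-brightness assumption (one fluorescent tag per molecule in
either state).

Also provided: observation-volume calibration against a reference dye of
known D, an F-test-based one-vs-two component model selector, a
spike-based aggregate-exclusion rule for raw traces, and per-condition
batch summaries (mean +/- SD of D_free, D_bound and percent bound).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .acf_models import (
    ObservationVolume,
    OneComponentParams,
    TwoComponentParams,
    acf_one_component,
    acf_two_component,
    diffusion_coefficient,
)
from .correlator import ACFCurve, IntensityTrace

__all__ = [
    "FitResult",
    "ProteinSummary",
    "ExclusionResult",
    "fit_one_component",
    "fit_two_component",
    "calibrate_volume",
    "select_model",
    "exclude_aggregate_traces",
    "batch_analyze",
]

#: Occupancy bounds keeping fits identifiable.
N_BOUNDS = (1e-3, 1e4)
#: Minimum tau_D2/tau_D1 ratio for calling two components resolved.
RESOLUTION_FACTOR = 3.0


@dataclass
class FitResult:
    """Outcome of a single-curve fit.

    For one-component fits only ``N1``/``tau_D1`` (the single species) are
    populated and ``bound_fraction`` is None.  ``d_free``/``d_bound`` are
    in um^2/s; standard errors come from the Jacobian at the optimum and
    are NaN when the covariance is singular.
    """

    model: str  # "one" | "two"
    N1: float
    tau_D1: float
    d_free: float
    N2: float | None = None
    tau_D2: float | None = None
    d_bound: float | None = None
    bound_fraction: float | None = None
    stderr: dict = field(default_factory=dict)
    rss: float = np.nan
    converged: bool = False
    flags: list = field(default_factory=list)
    curve_id: str = ""

    @property
    def total_n(self) -> float:
        return self.N1 + (self.N2 or 0.0)

    @property
    def pct_bound(self) -> float | None:
        return None if self.bound_fraction is None else 100.0 * self.bound_fraction


def _residual_weights(curve: ACFCurve, weights) -> np.ndarray | None:
    if weights is None:
        return None
    if isinstance(weights, str):
        if weights == "relative":
            scale = np.maximum(np.abs(curve.values), 1e-4 * np.abs(curve.values).max())
            return 1.0 / scale
        if weights == "se":
            if curve.se is None:
                raise ValueError("curve carries no standard errors to weight by")
            return 1.0 / np.where(
                np.isfinite(curve.se) & (curve.se > 0), curve.se, np.inf
            )
        raise ValueError(f"unknown weighting scheme {weights!r}")
    return np.asarray(weights, dtype=float)


def _check_curve(curve: ACFCurve) -> None:
    if len(curve) < 8:
        raise ValueError("need at least 8 lag points to fit")
    if curve.lags[-1] / curve.lags[0] < 10:
        raise ValueError("lag grid must span at least one decade")


def _tau_starts(curve: ACFCurve, per_decade: int = 3) -> np.ndarray:
    lo, hi = curve.lags[0], curve.lags[-1]
    n = max(2, int(round(per_decade * np.log10(hi / lo))))
    return np.geomspace(lo * 2, hi / 2, n)


def _stderr_from_jac(res, n_points: int) -> np.ndarray:
    dof = max(n_points - res.x.size, 1)
    try:
        jtj = res.jac.T @ res.jac
        cov = np.linalg.inv(jtj) * (2 * res.cost) / dof
        return np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        return np.full(res.x.size, np.nan)


def _ls(fun, x0, bounds) -> optimize.OptimizeResult:
    return optimize.least_squares(
        fun, x0, bounds=bounds, method="trf", x_scale="jac", max_nfev=2000
    )


def _at_bound(x: np.ndarray, lo: np.ndarray, hi: np.ndarray, rtol=1e-6) -> bool:
    span = hi - lo
    return bool(np.any((x - lo) < rtol * span) or np.any((hi - x) < rtol * span))


def fit_one_component(
    curve: ACFCurve,
    vol: ObservationVolume,
    init: OneComponentParams | None = None,
    bounds: dict | None = None,
    weights="relative",
) -> FitResult:
    """Fit the single-species model; returns N, tau_D and derived D.

    ``weights`` may be ``"relative"`` (default: residuals divided by the
    curve value, appropriate when the scatter scales with the correlation
    amplitude and the curve spans decades), ``"se"`` (use the correlator's
    per-lag standard errors), ``None`` (unweighted) or an explicit array.
    """
    _check_curve(curve)
    w = _residual_weights(curve, weights)
    tau_lo, tau_hi = curve.lags[0], curve.lags[-1]
    n_lo, n_hi = N_BOUNDS
    if bounds:
        tau_lo, tau_hi = bounds.get("tau_D", (tau_lo, tau_hi))
        n_lo, n_hi = bounds.get("N", (n_lo, n_hi))
    lo = np.array([n_lo, tau_lo])
    hi = np.array([n_hi, tau_hi])

    g_max = max(curve.values.max(), 1e-12)
    n0 = np.clip(vol.gamma / g_max, n_lo * 1.01, n_hi * 0.99)

    def resid(x):
        r = curve.values - acf_one_component(
            curve.lags, OneComponentParams(N=x[0], tau_D=x[1]), vol
        )
        return r if w is None else r * w

    if init is not None:
        starts = [np.array([init.N, init.tau_D])]
    else:
        starts = [
            np.array([n0, np.clip(t, tau_lo * 1.01, tau_hi * 0.99)])
            for t in _tau_starts(curve)
        ]

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo * 1.000001 + 1e-12, hi * 0.999999)
        try:
            res = _ls(resid, x0, (lo, hi))
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("one-component fit failed from every start")

    se = _stderr_from_jac(best, len(curve))
    flags = []
    if _at_bound(best.x, lo, hi):
        flags.append("at_bound")
    if not best.success:
        flags.append("no_convergence")
    n_fit, tau_fit = best.x
    return FitResult(
        model="one",
        N1=float(n_fit),
        tau_D1=float(tau_fit),
        d_free=diffusion_coefficient(float(tau_fit), vol.w0),
        stderr={"N": float(se[0]), "tau_D": float(se[1])},
        rss=float(2 * best.cost),
        converged=bool(best.success) and "at_bound" not in flags,
        flags=flags,
        curve_id=curve.sample_id,
    )


def fit_two_component(
    curve: ACFCurve,
    vol: ObservationVolume,
    init: TwoComponentParams | None = None,
    bounds: dict | None = None,
    weights="relative",
    resolution_factor: float = RESOLUTION_FACTOR,
) -> FitResult:
    """Fit the fast/slow mixture; canonical order (fast = free) is enforced.

    When the two fitted diffusion times come out closer than
    ``resolution_factor``, the components are not meaningfully distinct and
    the result is flagged ``"unresolved"``.
    """
    _check_curve(curve)
    w = _residual_weights(curve, weights)
    tau_lo, tau_hi = curve.lags[0], curve.lags[-1]
    n_lo, n_hi = 1e-6, N_BOUNDS[1]
    if bounds:
        tau_lo, tau_hi = bounds.get("tau_D", (tau_lo, tau_hi))
        n_lo, n_hi = bounds.get("N", (n_lo, n_hi))
    lo = np.array([n_lo, n_lo, tau_lo, tau_lo])
    hi = np.array([n_hi, n_hi, tau_hi, tau_hi])

    g_max = max(curve.values.max(), 1e-12)
    n_tot0 = np.clip(vol.gamma / g_max, 2 * n_lo, n_hi / 2)

    def resid(x):
        r = curve.values - acf_two_component(
            curve.lags,
            TwoComponentParams(N1=x[0], N2=x[1], tau_D1=x[2], tau_D2=x[3]),
            vol,
        )
        return r if w is None else r * w

    if init is not None:
        starts = [np.array([init.N1, init.N2, init.tau_D1, init.tau_D2])]
    else:
        taus = _tau_starts(curve, per_decade=2)
        pairs = [
            (t1, t2)
            for t1, t2 in itertools.combinations(taus, 2)
            if t2 / t1 >= resolution_factor
        ]
        # keep the start count modest: thin to at most 12 pairs
        if len(pairs) > 12:
            idx = np.linspace(0, len(pairs) - 1, 12).astype(int)
            pairs = [pairs[i] for i in idx]
        starts = [
            np.array([0.8 * n_tot0, 0.2 * n_tot0, t1, t2]) for t1, t2 in pairs
        ]

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo * 1.01, hi * 0.99)
        try:
            res = _ls(resid, x0, (lo, hi))
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("two-component fit failed from every start")

    se = _stderr_from_jac(best, len(curve))
    params = TwoComponentParams(
        N1=float(best.x[0]),
        N2=float(best.x[1]),
        tau_D1=float(best.x[2]),
        tau_D2=float(best.x[3]),
    )
    swapped = params.tau_D1 > params.tau_D2
    params = params.canonical()
    se_n1, se_n2, se_t1, se_t2 = se
    if swapped:
        se_n1, se_n2, se_t1, se_t2 = se_n2, se_n1, se_t2, se_t1

    flags = []
    if _at_bound(best.x, lo, hi):
        flags.append("at_bound")
    if not best.success:
        flags.append("no_convergence")
    if params.tau_D2 / params.tau_D1 < resolution_factor:
        flags.append("unresolved")

    return FitResult(
        model="two",
        N1=params.N1,
        N2=params.N2,
        tau_D1=params.tau_D1,
        tau_D2=params.tau_D2,
        d_free=diffusion_coefficient(params.tau_D1, vol.w0),
        d_bound=diffusion_coefficient(params.tau_D2, vol.w0),
        bound_fraction=params.bound_fraction,
        stderr={
            "N1": float(se_n1),
            "N2": float(se_n2),
            "tau_D1": float(se_t1),
            "tau_D2": float(se_t2),
        },
        rss=float(2 * best.cost),
        converged=bool(best.success) and "at_bound" not in flags,
        flags=flags,
        curve_id=curve.sample_id,
    )


def calibrate_volume(
    curve: ACFCurve,
    D_ref: float,
    z_ratio: float = 5.0,
    gamma: float = 0.35,
) -> ObservationVolume:
    """Calibrate the beam waist from a reference-dye measurement.

    Fits the one-component model (the shape depends only on tau_D and the
    structure parameter) and converts the fitted diffusion time via
    w0 = sqrt(4 * D_ref * tau_D).  The configured z0/w0 ratio and gamma are
    carried over unchanged.
    """
    if D_ref <= 0:
        raise ValueError("D_ref must be positive")
    provisional = ObservationVolume(w0=1.0, z0=z_ratio, gamma=gamma)
    fit = fit_one_component(curve, provisional)
    if not fit.converged:
        raise RuntimeError(f"calibration fit did not converge: {fit.flags}")
    w0 = float(np.sqrt(4.0 * D_ref * fit.tau_D1))
    return ObservationVolume(w0=w0, z0=z_ratio * w0, gamma=gamma)


def _effective_correlation_length(resid: np.ndarray, max_lag: int = 25) -> float:
    """Integrated autocorrelation length of a residual vector.

    Estimates ell = 1 + 2*sum(rho_k) over positive leading autocorrelation,
    so n/ell is the effective number of independent residuals.  Measured
    and synthesized ACF curves have noise correlated across neighbouring
    lags, which an iid F-test would ignore, making it anticonservative.
    """
    r = resid - resid.mean()
    denom = float(np.dot(r, r))
    if denom <= 0:
        return 1.0
    ell = 1.0
    for k in range(1, min(max_lag, len(r) // 3)):
        rho = float(np.dot(r[:-k], r[k:])) / denom
        if rho <= 0.05:
            break
        ell += 2.0 * rho
    return ell


def select_model(
    curve: ACFCurve,
    vol: ObservationVolume,
    alpha: float = 0.05,
    resolution_factor: float = RESOLUTION_FACTOR,
    weights="relative",
    min_component_fraction: float = 0.02,
) -> tuple[str, FitResult, FitResult]:
    """Choose between one and two diffusing components for one curve.

    Returns ``(choice, one_fit, two_fit)``.  The two-component model wins
    only if it reduces the residual sum of squares significantly under an
    F-test at level ``alpha`` AND its components are resolved: diffusion
    times at least ``resolution_factor`` apart and neither pool below
    ``min_component_fraction`` of the total occupancy (a sub-2% species is
    not a detectable component in a single FCS curve).  The F-test degrees
    of freedom are deflated by the integrated autocorrelation length of
    the residuals, since per-lag noise on correlation curves is not
    independent; otherwise the parsimonious one-component description is
    kept.
    """
    one = fit_one_component(curve, vol, weights=weights)
    two = fit_two_component(
        curve, vol, weights=weights, resolution_factor=resolution_factor
    )
    n = len(curve)
    scale = float(np.mean(curve.values**2))
    if one.rss <= 1e-20 * scale * n:
        # the single-species model already fits to numerical precision
        return ("one", one, two)
    resolved = (
        "unresolved" not in two.flags
        and two.bound_fraction is not None
        and min_component_fraction
        < two.bound_fraction
        < 1 - min_component_fraction
    )
    if two.rss <= 0:
        return (("two" if resolved else "one"), one, two)
    w = _residual_weights(curve, weights)
    model = acf_two_component(
        curve.lags,
        TwoComponentParams(
            N1=max(two.N1, 1e-12),
            N2=max(two.N2, 1e-12),
            tau_D1=two.tau_D1,
            tau_D2=two.tau_D2,
        ),
        vol,
    )
    resid = curve.values - model
    if w is not None:
        resid = resid * w
    ell = _effective_correlation_length(resid)
    n_eff = max(n / ell, 9.0)
    df2 = max(n_eff - 4.0, 3.0)
    f_stat = ((one.rss - two.rss) / 2.0) / (two.rss / df2)
    p = stats.f.sf(max(f_stat, 0.0), 2, df2)
    choice = "two" if (p < alpha and resolved) else "one"
    return (choice, one, two)


@dataclass
class ExclusionResult:
    """Verdict of the aggregate-spike screen for one trace."""

    keep: bool
    threshold: float
    bin_width_s: float
    offending_bins: np.ndarray
    binned: np.ndarray


def exclude_aggregate_traces(
    trace: IntensityTrace,
    bin_width_s: float = 0.01,
    k: float = 10.0,
    min_run: int = 3,
) -> ExclusionResult:
    """Flag traces whose correlation would be distorted by bright aggregates.

    The trace is rebinned to ``bin_width_s`` bins; bins strictly above
    median + k*MAD (raw median absolute deviation, no normal-consistency
    scaling) are spike candidates, and the trace is excluded when at least
    ``min_run`` consecutive bins exceed the threshold — a sustained bright
    event, as produced by a slowly crossing aggregate, rather than shot
    noise.
    """
    if trace.duration < 1.0:
        raise ValueError("trace must be at least 1 s long for the screen")
    per_bin = max(1, int(round(bin_width_s / trace.dt)))
    n_bins = len(trace) // per_bin
    binned = trace.counts[: n_bins * per_bin].reshape(n_bins, per_bin).sum(axis=1)
    med = np.median(binned)
    mad = np.median(np.abs(binned - med))
    threshold = med + k * mad
    above = binned > threshold  # strict: a bin at exactly threshold passes
    # longest run of consecutive exceedances
    run = longest = 0
    offending = np.flatnonzero(above)
    for a in above:
        run = run + 1 if a else 0
        longest = max(longest, run)
    return ExclusionResult(
        keep=longest < min_run,
        threshold=float(threshold),
        bin_width_s=per_bin * trace.dt,
        offending_bins=offending,
        binned=binned,
    )


@dataclass
class ProteinSummary:
    """Per-condition summary over retained curves (mean +/- SD)."""

    condition: str
    mode: str  # "bulk" | "on_pattern"
    fits: list
    n_curves: int
    n_excluded: int = 0
    d_bulk_mean: float | None = None
    d_bulk_sd: float | None = None
    d_free_mean: float | None = None
    d_free_sd: float | None = None
    d_bound_mean: float | None = None
    d_bound_sd: float | None = None
    pct_bound_mean: float | None = None
    pct_bound_sd: float | None = None

    @property
    def bound_fractions(self) -> np.ndarray:
        return np.array(
            [f.bound_fraction for f in self.fits if f.bound_fraction is not None]
        )


def _mean_sd(x: list) -> tuple[float, float]:
    arr = np.asarray(x, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0


def batch_analyze(
    curves_by_condition: dict[str, list[ACFCurve]],
    vol: ObservationVolume,
    mode: str = "bulk",
    n_excluded: dict[str, int] | None = None,
    use_model_selection: bool = True,
) -> list[ProteinSummary]:
    """Fit every curve of every condition and summarize.

    ``mode='bulk'`` applies one-component fits; ``mode='on_pattern'``
    applies two-component fits, guarded by :func:`select_model` so that a
    genuinely single-species condition (e.g. a non-interacting control)
    falls back to the one-component description.
    """
    if mode not in ("bulk", "on_pattern"):
        raise ValueError(f"unknown mode {mode!r}")
    n_excluded = n_excluded or {}
    summaries = []
    for condition, curves in curves_by_condition.items():
        if len(curves) < 3:
            raise ValueError(
                f"condition {condition!r} has fewer than 3 retained curves"
            )
        fits = []
        for curve in curves:
            if mode == "bulk":
                fits.append(fit_one_component(curve, vol))
            elif use_model_selection:
                choice, one, two = select_model(curve, vol)
                fits.append(two if choice == "two" else one)
            else:
                fits.append(fit_two_component(curve, vol))
        summary = ProteinSummary(
            condition=condition,
            mode=mode,
            fits=fits,
            n_curves=len(fits),
            n_excluded=n_excluded.get(condition, 0),
        )
        if mode == "bulk":
            summary.d_bulk_mean, summary.d_bulk_sd = _mean_sd(
                [f.d_free for f in fits]
            )
        else:
            summary.d_free_mean, summary.d_free_sd = _mean_sd(
                [f.d_free for f in fits]
            )
            two_fits = [f for f in fits if f.model == "two"]
            if two_fits:
                summary.d_bound_mean, summary.d_bound_sd = _mean_sd(
                    [f.d_bound for f in two_fits]
                )
                summary.pct_bound_mean, summary.pct_bound_sd = _mean_sd(
                    [f.pct_bound for f in two_fits]
                )
            else:
                warnings.warn(
                    f"condition {condition!r}: no curve favored two components",
                    stacklevel=2,
                )
        summaries.append(summary)
    return summaries
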