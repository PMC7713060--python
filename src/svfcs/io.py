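"""File formats, configuration and the end-to-end pipeline.

All tabular outputs are plain CSV with ``#``-prefixed ``key=value``
metadata lines ahead of the header, so every file is self-describing and
inspectable.  Images are 16-bit grayscale TIFF.  A convenience reader for
a simplified ALV-style exported ASCII correlation table is included; it is
documented, not claimed bit-compatible with vendor files.

:func:`run_pipeline` ties the stages together in measurement order:
calibrate -> simulate/acquire -> exclude -> correlate/fit -> summarize ->
energetics -> stats, with every output carrying the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .acf_models import ObservationVolume, OneComponentParams, diffusion_time
from .correlator import ACFCurve, IntensityTrace
from .energetics import energetics_table
from .fitting import ProteinSummary, batch_analyze, calibrate_volume
from .stats import mann_whitney_u
from .synthetic_data import PRESETS, preset_params, synthesize_acf

logger = logging.getLogger("svfcs")

__all__ = [
    "RunConfig",
    "read_trace_csv",
    "write_trace_csv",
    "read_acf_csv",
    "write_acf_csv",
    "read_alv_ascii",
    "write_image_tiff",
    "read_image_tiff",
    "write_positions_csv",
    "read_positions_csv",
    "write_fit_table",
    "write_summary_csv",
    "write_energetics_csv",
    "load_config",
    "run_pipeline",
]


# --------------------------------------------------------------------------
# CSV with '#'-prefixed metadata


def _write_csv_with_meta(path, df: pd.DataFrame, metadata: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in metadata.items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def _read_csv_with_meta(path) -> tuple[pd.DataFrame, dict]:
    metadata = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                metadata[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return df, metadata


def write_trace_csv(path, trace: IntensityTrace, metadata: dict | None = None):
    meta = {"dt_s": repr(trace.dt), **trace.metadata, **(metadata or {})}
    df = pd.DataFrame(
        {
            "time_s": trace.dt * np.arange(len(trace)),
            "counts": trace.counts,
        }
    )
    _write_csv_with_meta(path, df, meta)


def read_trace_csv(path) -> IntensityTrace:
    df, meta = _read_csv_with_meta(path)
    if "time_s" not in df or "counts" not in df:
        raise ValueError(f"{path}: expected columns time_s,counts")
    if "dt_s" in meta:
        dt = float(meta.pop("dt_s"))
    else:
        dt = float(np.median(np.diff(df["time_s"].to_numpy())))
    return IntensityTrace(dt=dt, counts=df["counts"].to_numpy(), metadata=meta)


def write_acf_csv(path, curve: ACFCurve, metadata: dict | None = None) -> None:
    meta = {
        "sample_id": curve.sample_id,
        "condition": curve.condition,
        "acquisition_time_s": curve.acquisition_time,
        **{k: v for k, v in curve.metadata.items()},
        **(metadata or {}),
    }
    df = pd.DataFrame({"lag_s": curve.lags, "G": curve.values})
    df["se"] = curve.se if curve.se is not None else np.nan
    _write_csv_with_meta(path, df, meta)


def read_acf_csv(path) -> ACFCurve:
    df, meta = _read_csv_with_meta(path)
    if "lag_s" not in df or "G" not in df:
        raise ValueError(f"{path}: expected columns lag_s,G")
    se = df["se"].to_numpy() if "se" in df else None
    if se is not None and np.all(np.isnan(se)):
        se = None
    acq = meta.pop("acquisition_time_s", None)
    return ACFCurve(
        lags=df["lag_s"].to_numpy(),
        values=df["G"].to_numpy(),
        se=se,
        acquisition_time=float(acq) if acq not in (None, "None", "") else None,
        sample_id=meta.pop("sample_id", ""),
        condition=meta.pop("condition", ""),
        metadata=meta,
    )


def read_alv_ascii(path) -> ACFCurve:
    """Read a simplified ALV-style exported ASCII correlation table.

    Expected layout: free-text header lines, then a ``"Correlation"``
    marker line, then two whitespace-separated columns of lag (in ms, the
    vendor convention) and g(tau)-1 until a blank line or end of file.
    """
    lags, values = [], []
    in_table = False
    with open(path) as fh:
        for line in fh:
            stripped = line.strip().strip('"')
            if not in_table:
                if stripped.lower().startswith("correlation"):
                    in_table = True
                continue
            if not stripped:
                break
            parts = stripped.split()
            if len(parts) < 2:
                break
            try:
                lag_ms, g = float(parts[0]), float(parts[1])
            except ValueError:
                break
            lags.append(lag_ms * 1e-3)
            values.append(g)
    if not lags:
        raise ValueError(f"{path}: no correlation table found")
    return ACFCurve(
        lags=np.asarray(lags),
        values=np.asarray(values),
        metadata={"source": "alv-ascii"},
    )


def write_image_tiff(path, image: np.ndarray) -> None:
    """Write a 16-bit grayscale TIFF, clipping to the uint16 range."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.clip(image, 0, 65535).astype(np.uint16))


def read_image_tiff(path) -> np.ndarray:
    image = tifffile.imread(path)
    if image.ndim != 2:
        raise ValueError(f"{path}: expected a 2D grayscale image")
    return image.astype(float)


def write_positions_csv(path, positions_um: np.ndarray, metadata=None) -> None:
    df = pd.DataFrame(positions_um, columns=["x_um", "y_um"])
    _write_csv_with_meta(path, df, metadata or {})


def read_positions_csv(path) -> np.ndarray:
    df, _ = _read_csv_with_meta(path)
    return df[["x_um", "y_um"]].to_numpy()


FIT_COLUMNS = [
    "curve_id",
    "condition",
    "model",
    "N1",
    "N2",
    "tauD1_s",
    "tauD2_s",
    "D_free_um2s",
    "D_bound_um2s",
    "pct_bound",
    "rss",
    "converged",
    "flags",
]


def write_fit_table(path, summaries: list[ProteinSummary], metadata=None) -> None:
    rows = []
    for summary in summaries:
        for f in summary.fits:
            rows.append(
                {
                    "curve_id": f.curve_id,
                    "condition": summary.condition,
                    "model": f.model,
                    "N1": f.N1,
                    "N2": f.N2,
                    "tauD1_s": f.tau_D1,
                    "tauD2_s": f.tau_D2,
                    "D_free_um2s": f.d_free,
                    "D_bound_um2s": f.d_bound,
                    "pct_bound": f.pct_bound,
                    "rss": f.rss,
                    "converged": f.converged,
                    "flags": ";".join(f.flags),
                }
            )
    _write_csv_with_meta(path, pd.DataFrame(rows, columns=FIT_COLUMNS), metadata or {})


def write_summary_csv(path, summaries: list[ProteinSummary], metadata=None) -> None:
    rows = []
    for s in summaries:
        rows.append(
            {
                "condition": s.condition,
                "mode": s.mode,
                "n_curves": s.n_curves,
                "n_excluded": s.n_excluded,
                "D_bulk_um2s": s.d_bulk_mean,
                "D_bulk_sd": s.d_bulk_sd,
                "D_free_um2s": s.d_free_mean,
                "D_free_sd": s.d_free_sd,
                "D_bound_um2s": s.d_bound_mean,
                "D_bound_sd": s.d_bound_sd,
                "pct_bound": s.pct_bound_mean,
                "pct_bound_sd": s.pct_bound_sd,
            }
        )
    _write_csv_with_meta(path, pd.DataFrame(rows), metadata or {})


def write_energetics_csv(path, rows, metadata=None) -> None:
    df = pd.DataFrame(
        [
            {
                "condition": r.condition,
                "p_b_mean": r.p_b_mean,
                "p_b_sd": r.p_b_sd,
                "deltaE_kBT": r.delta_E,
                "deltaE_sd": r.delta_E_sd,
                "E_b_kBT": r.E_b,
                "E_b_sd": r.E_b_sd,
                "rate_ratio": r.rate_ratio,
                "rate_ratio_sd": r.rate_ratio_sd,
                "mode": r.mode,
                "n": r.n,
            }
            for r in rows
        ]
    )
    _write_csv_with_meta(path, df, metadata or {})


# --------------------------------------------------------------------------
# configuration


@dataclass
class ConditionSpec:
    """One simulated condition inside a run configuration."""

    preset: str
    n_curves: int = 25
    noise_fraction: float = 0.02
    seed: int = 0
    n_total: float = 5.0
    provenance: str = ""


@dataclass
class RunConfig:
    """Validated configuration for :func:`run_pipeline`."""

    w0_um: float = 0.31
    z_ratio: float = 5.0
    gamma: float = 0.35
    conditions: list = field(default_factory=list)
    calibration_d_ref: float = 400.0
    fit_alpha: float = 0.05
    energetics_averaging: str = "per_point"
    seed: int = 0

    @property
    def volume(self) -> ObservationVolume:
        return ObservationVolume(
            w0=self.w0_um, z0=self.w0_um * self.z_ratio, gamma=self.gamma
        )

    def config_hash(self) -> str:
        payload = json.dumps(
            {**asdict(self), "conditions": [asdict(c) for c in self.conditions]},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Schema::

        w0_um: 0.31            # beam waist, um
        z_ratio: 5.0           # z0 / w0
        gamma: 0.35
        calibration_d_ref: 400.0   # reference dye D, um^2/s
        fit_alpha: 0.05
        energetics_averaging: per_point   # or of_mean
        seed: 1
        conditions:
          - preset: egfp       # a key of synthetic_data.PRESETS
            n_curves: 25
            noise_fraction: 0.02
            seed: 1
            provenance: free-text note on where the values come from

    Unknown presets or fields raise before any computation.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {
        "w0_um",
        "z_ratio",
        "gamma",
        "conditions",
        "calibration_d_ref",
        "fit_alpha",
        "energetics_averaging",
        "seed",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    conditions = []
    for entry in raw.pop("conditions", []):
        spec = ConditionSpec(**entry)
        if spec.preset not in PRESETS:
            raise ValueError(f"unknown preset {spec.preset!r}")
        conditions.append(spec)
    config = RunConfig(conditions=conditions, **raw)
    if config.energetics_averaging not in ("per_point", "of_mean"):
        raise ValueError("energetics_averaging must be per_point or of_mean")
    return config


# --------------------------------------------------------------------------
# pipeline


def run_pipeline(config: RunConfig, mode: str, out_dir) -> dict:
    """Run the full analysis for every configured condition.

    ``mode``: ``bulk`` (one-component fits of free diffusion),
    ``on_pattern`` (two-component fits, bound fractions, energetics and
    pairwise bound-D comparisons) or ``density`` is handled by the CLI on
    images directly.  Outputs land in ``out_dir`` as CSV files stamped
    with the config hash and seed; returns the paths written.
    """
    if mode not in ("bulk", "on_pattern"):
        raise ValueError(f"unknown pipeline mode {mode!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not config.conditions:
        raise ValueError("configuration lists no conditions")
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    vol = config.volume

    # calibration on a noiseless synthetic reference-dye curve
    ref_params = OneComponentParams(
        N=1.0, tau_D=diffusion_time(config.calibration_d_ref, config.w0_um)
    )
    ref_curve = synthesize_acf(ref_params, vol, noise_fraction=0.0, n_curves=1)[0]
    calibrated = calibrate_volume(
        ref_curve,
        config.calibration_d_ref,
        z_ratio=config.z_ratio,
        gamma=config.gamma,
    )
    logger.info("calibrated w0 = %.1f nm", 1e3 * calibrated.w0)

    curves_by_condition = {}
    for spec in config.conditions:
        params = preset_params(
            spec.preset,
            calibrated,
            mode="bulk" if mode == "bulk" else "on_pattern",
            n_total=spec.n_total,
        )
        curves_by_condition[spec.preset] = synthesize_acf(
            params,
            calibrated,
            noise_fraction=spec.noise_fraction,
            n_curves=spec.n_curves,
            seed=spec.seed,
            condition=spec.preset,
        )

    summaries = batch_analyze(curves_by_condition, calibrated, mode=mode)
    for s in summaries:
        flagged = [f.curve_id for f in s.fits if f.flags]
        if flagged:
            logger.info("%s: flagged fits: %s", s.condition, flagged)

    written = {}
    fit_path = out_dir / "fits.csv"
    write_fit_table(fit_path, summaries, stamp)
    written["fits"] = fit_path
    summary_path = out_dir / "summary.csv"
    write_summary_csv(summary_path, summaries, stamp)
    written["summary"] = summary_path

    if mode == "on_pattern":
        rows = energetics_table(summaries, averaging=config.energetics_averaging)
        energetics_path = out_dir / "energetics.csv"
        write_energetics_csv(energetics_path, rows, stamp)
        written["energetics"] = energetics_path

        with_bound = [s for s in summaries if len(s.bound_fractions)]
        if len(with_bound) >= 2:
            records = []
            for i in range(len(with_bound)):
                for j in range(i + 1, len(with_bound)):
                    a, b = with_bound[i], with_bound[j]
                    da = [f.d_bound for f in a.fits if f.d_bound is not None]
                    db = [f.d_bound for f in b.fits if f.d_bound is not None]
                    res = mann_whitney_u(da, db)
                    records.append(
                        {
                            "condition_a": a.condition,
                            "condition_b": b.condition,
                            "U": res.statistic,
                            "pvalue": res.pvalue,
                            "method": res.method,
                        }
                    )
            pvals_path = out_dir / "pairwise_tests.csv"
            _write_csv_with_meta(pvals_path, pd.DataFrame(records), stamp)
            written["pairwise_tests"] = pvals_path

    return written
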