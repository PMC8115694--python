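"""Seeded-polymerization kinetics: curve fitting, activity normalization and
paired testing.

Polymerization time courses are fit with a 4-parameter logistic
``y(t) = y0 + A / (1 + exp(-k (t - t_half)))`` — a robust empirical shape for
sigmoidal seeded-assembly traces, not a mechanistic nucleation-growth model.
The half-time is converted to an apparent rate ``1/t_half``, and mutant
rates are normalized against a no-seed control (0) and a wild-type control
(1) to give a dimensionless activity ratio. Paired differences between
conditions use the classical paired Student t test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger("filapole")

__all__ = [
    "KineticsFit",
    "ActivityRatio",
    "fit_polymerization_curve",
    "half_time_by_interpolation",
    "activity_ratio",
    "paired_t_test",
    "fret_ratio",
    "load_plate",
    "analyze_plate",
    "holm_correction",
]


@dataclass
class KineticsFit:
    t_half: float
    apparent_rate: float          # 1 / t_half, 0 when flagged
    amplitude: float
    baseline: float
    steepness: float
    fit_quality: float            # coefficient of determination R^2
    no_polymerization: bool


@dataclass
class ActivityRatio:
    value: float
    rate_sample: float
    rate_none: float
    rate_wt: float
    out_of_range: bool            # hyperactive (>1) or inhibitory (<0)


def _logistic(t, y0, amplitude, rate, t_half):
    with np.errstate(over="ignore"):     # exp overflow saturates harmlessly
        return y0 + amplitude / (1.0 + np.exp(-rate * (t - t_half)))


def fit_polymerization_curve(t, y, min_points: int = 8,
                             amplitude_snr: float = 3.0) -> KineticsFit:
    """Least-squares logistic fit of one polymerization trace.

    Requires at least ``min_points`` strictly increasing time points. When
    the fitted amplitude is below ``amplitude_snr`` times the residual noise
    SD, or the fit fails, the trace is flagged as non-polymerizing and the
    apparent rate is 0.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("t and y must be matching 1-D vectors")
    if len(t) < min_points:
        raise ValueError(f"need at least {min_points} time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time vector must be strictly increasing")

    y0_init = float(y[: max(3, len(y) // 10)].mean())
    amp_init = float(y.max() - y.min())
    if amp_init == 0:
        amp_init = 1e-12
    half_level = y0_init + amp_init / 2
    above = np.nonzero(y >= half_level)[0]
    t_half_init = float(t[above[0]]) if above.size else float(t[len(t) // 2])
    rate_init = 4.0 / max((t[-1] - t[0]) / 4, 1e-9)

    flagged = False
    try:
        popt, _ = optimize.curve_fit(
            _logistic, t, y, p0=[y0_init, amp_init, rate_init, t_half_init],
            maxfev=20000)
        y0, amplitude, rate, t_half = (float(v) for v in popt)
        resid = y - _logistic(t, *popt)
        ss_res = float(np.sum(resid ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        noise_sd = float(np.std(resid, ddof=1))
        # a half-time outside the sampled window was never observed;
        # an amplitude within the noise floor is no polymerization signal
        if (abs(amplitude) <= amplitude_snr * noise_sd + 1e-12
                or not (t[0] < t_half < t[-1])):
            flagged = True
    except (RuntimeError, optimize.OptimizeWarning):
        flagged = True
        y0, amplitude, rate, t_half, r2 = y0_init, 0.0, 0.0, float("nan"), 0.0

    if flagged:
        return KineticsFit(t_half=float("nan"), apparent_rate=0.0,
                           amplitude=float(amplitude), baseline=float(y0),
                           steepness=float(rate), fit_quality=float(r2),
                           no_polymerization=True)
    return KineticsFit(t_half=t_half, apparent_rate=1.0 / t_half,
                       amplitude=amplitude, baseline=y0, steepness=rate,
                       fit_quality=r2, no_polymerization=False)


def half_time_by_interpolation(t, y, smooth: int = 3) -> float:
    """Model-free half-time: first crossing of the half-maximal signal,
    linearly interpolated (alternative to the logistic fit)."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        y = np.convolve(y, kernel, mode="same")
    level = (y.min() + y.max()) / 2
    above = np.nonzero(y >= level)[0]
    if not above.size or above[0] == 0:
        return float("nan")
    i = above[0]
    frac = (level - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def activity_ratio(rate_sample: float, rate_none: float, rate_wt: float
                   ) -> ActivityRatio:
    """Normalize a rate to the 0 (no-seed) .. 1 (wild-type seed) scale.

    Values outside [0, 1] are permitted (hyperactive or inhibitory mutants)
    and flagged. The normalization is affine-invariant: rescaling all three
    rates by a positive constant leaves the value unchanged.
    """
    if rate_wt == rate_none:
        raise ZeroDivisionError(
            "rate_wt equals rate_none: activity normalization undefined")
    value = (rate_sample - rate_none) / (rate_wt - rate_none)
    return ActivityRatio(value=float(value), rate_sample=float(rate_sample),
                         rate_none=float(rate_none), rate_wt=float(rate_wt),
                         out_of_range=bool(value < 0 or value > 1))


def paired_t_test(a, b) -> dict:
    """Two-sided paired Student t test on matched vectors.

    Returns ``{"t_stat", "p_value", "df", "degenerate"}``. Zero-variance
    differences give t = 0 / p = 1 when the mean difference is 0, and are
    flagged degenerate otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be matching 1-D vectors")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = b - a
    df = len(d) - 1
    if np.std(d, ddof=1) == 0:
        if np.mean(d) == 0:
            return {"t_stat": 0.0, "p_value": 1.0, "df": df,
                    "degenerate": False}
        return {"t_stat": float("inf") * np.sign(np.mean(d)),
                "p_value": 0.0, "df": df, "degenerate": True}
    res = stats.ttest_rel(b, a)
    return {"t_stat": float(res.statistic), "p_value": float(res.pvalue),
            "df": df, "degenerate": False}


def holm_correction(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (optional multiplicity control)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def fret_ratio(donor, acceptor) -> np.ndarray:
    """Elementwise acceptor / (donor + acceptor); masked where undefined."""
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    if donor.shape != acceptor.shape:
        raise ValueError("donor and acceptor must have equal length")
    total = donor + acceptor
    out = np.ma.masked_invalid(np.divide(
        acceptor, total, out=np.full_like(total, np.nan),
        where=total != 0))
    if out.mask.any():
        logger.warning("fret_ratio: %d points with zero total signal masked",
                       int(np.sum(out.mask)))
    return out


def load_plate(plate_path, meta_path) -> tuple[pd.DataFrame, dict]:
    """Read a plate table (CSV/TSV, ``time`` + one column per well) and its
    JSON metadata sidecar mapping wells to samples/roles."""
    plate_path = Path(plate_path)
    sep = "\t" if plate_path.suffix.lower() in (".tsv", ".tab") else ","
    plate = pd.read_csv(plate_path, sep=sep)
    if "time" not in plate.columns:
        raise ValueError("plate table must contain a 'time' column")
    meta = json.loads(Path(meta_path).read_text())
    if "wells" not in meta:
        raise ValueError("metadata must contain a 'wells' mapping")
    return plate, meta


def analyze_plate(plate: pd.DataFrame, meta: dict,
                  method: str = "logistic") -> pd.DataFrame:
    """Fit every well, normalize activity per sample, one row per well.

    Control rates are the means over wells with roles ``none`` and ``wt``.
    ``method`` selects the half-time extraction: the default logistic fit or
    model-free ``interpolation``.
    """
    t = plate["time"].to_numpy()
    rows = []
    for well, info in meta["wells"].items():
        if well not in plate.columns:
            raise ValueError(f"well {well} missing from plate table")
        y = plate[well].to_numpy()
        if method == "logistic":
            fit = fit_polymerization_curve(t, y)
        elif method == "interpolation":
            th = half_time_by_interpolation(t, y)
            amp = float(y.max() - y.min())
            noise = float(np.std(np.diff(y))) / np.sqrt(2)
            flagged = not np.isfinite(th) or amp < 3 * noise
            fit = KineticsFit(
                t_half=th, apparent_rate=0.0 if flagged else 1.0 / th,
                amplitude=amp, baseline=float(y.min()), steepness=float("nan"),
                fit_quality=float("nan"), no_polymerization=flagged)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({"well": well, "sample": info["sample"],
                     "replicate": info.get("replicate", 1),
                     "role": info.get("role", "mutant"),
                     "t_half": fit.t_half, "apparent_rate": fit.apparent_rate,
                     "amplitude": fit.amplitude, "r2": fit.fit_quality,
                     "no_polymerization": fit.no_polymerization})
    table = pd.DataFrame(rows)
    rate_none = table.loc[table.role == "none", "apparent_rate"].mean()
    rate_wt = table.loc[table.role == "wt", "apparent_rate"].mean()
    if not (np.isfinite(rate_none) and np.isfinite(rate_wt)):
        raise ValueError("plate must contain no-seed and WT control wells")
    table["activity_ratio"] = [
        activity_ratio(r, rate_none, rate_wt).value
        for r in table["apparent_rate"]
    ]
    return table
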