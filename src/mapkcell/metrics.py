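"""Derived quantities and statistics for recorded activation traces.

Covers activation-dynamics summaries (E_max level and timing, EC50 timing,
initial activation rate, lag, plateau conversion), oscillation detection and
classification, step-to-minute calibration, replicate robustness (SD as a
percent of the cross-run mean), and thin wrappers over the standard
hypothesis tests used to analyse runs (omnibus normality, one-way ANOVA,
t-tests, Holm–Šidák correction).

Timing conventions: stochastic traces plateau noisily, so "time to E_max" is
the first time the smoothed trace reaches 95% of its smoothed maximum (the
threshold is configurable), not the literal argmax.  Smoothing is a centred
moving average with a one-simulated-minute window by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

from .engine import TimeSeries


def smooth_trace(values: np.ndarray, times_min: np.ndarray, window_min: float = 1.0) -> np.ndarray:
    """Centred moving average over a fixed simulated-time window."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3 or window_min <= 0:
        return values.copy()
    dt = float(np.median(np.diff(times_min)))
    w = max(1, int(round(window_min / dt)))
    return (
        pd.Series(values).rolling(w, center=True, min_periods=1).mean().to_numpy()
    )


@dataclass
class DynamicsReport:
    species: str
    emax_value: float
    t_emax_min: float | None
    t_ec50_min: float | None
    initial_rate_pct_per_min: float | None
    reduction_at_emax_pct: float | None
    equilibrium_ratio: float | None
    lag_time_s: float | None
    total: int

    @property
    def defined(self) -> bool:
        return self.emax_value > 0


def dynamics_report(
    ts: TimeSeries,
    species: str = "pMAPK",
    smooth_window_min: float = 1.0,
    emax_threshold: float = 0.95,
    lag_frac: float = 0.05,
    plateau_window_min: float = 5.0,
) -> DynamicsReport:
    """Summarise an activation trace.

    * ``emax_value`` — maximum of the smoothed trace.
    * ``t_emax`` — first time the smoothed trace reaches ``emax_threshold``
      (default 95%) of the maximum.
    * ``t_ec50`` — first time it reaches 50% of the maximum.
    * ``initial_rate`` — least-squares slope over the rise segment between 10%
      and 50% of the maximum, in percent of the conserved species pool per
      minute.
    * ``lag_time`` — last recorded time before the trace first exceeds
      ``lag_frac`` (default 5%) of the pool.
    * ``reduction_at_emax`` — for pMAPK, the percent fall of the inactive-MAPK
      count at ``t_emax`` relative to its value at t0.
    * ``equilibrium_ratio`` — active/inactive count ratio of the species pair,
      averaged over the trailing ``plateau_window_min``.
    """
    if len(ts) == 0:
        raise ValueError("empty time series")
    times = ts.time_min
    raw = ts.values(species)
    total = ts.total(species)
    tr = smooth_trace(raw, times, smooth_window_min)
    emax = float(tr.max())
    if emax <= 0:
        return DynamicsReport(species, 0.0, None, None, None, None, None, None, total)

    t_emax = float(times[np.argmax(tr >= emax_threshold * emax)])
    t_ec50 = float(times[np.argmax(tr >= 0.5 * emax)])

    # rise-segment slope between 10% and 50% of emax
    i10 = int(np.argmax(tr >= 0.10 * emax))
    i50 = int(np.argmax(tr >= 0.50 * emax))
    initial_rate = None
    if total > 0 and i50 > i10:
        seg_t = times[i10 : i50 + 1]
        seg_v = tr[i10 : i50 + 1]
        slope = np.polyfit(seg_t, seg_v, 1)[0]
        initial_rate = float(100.0 * slope / total)

    lag = None
    if total > 0:
        above = tr > lag_frac * total
        if above.any():
            first = int(np.argmax(above))
            lag = float(times[max(first - 1, 0)] * 60.0)

    reduction = None
    if species == "pMAPK":
        inact = smooth_trace(ts.values("MAPK"), times, smooth_window_min)
        if inact[0] > 0:
            at = int(np.argmax(times >= t_emax))
            reduction = float(100.0 * (inact[0] - inact[at]) / inact[0])

    partner = {
        "pMAPK": "MAPK",
        "MAPK": "pMAPK",
        "pMAPKK": "MAPKK_dormant",
        "MAPKK_dormant": "pMAPKK",
        "ExR": "dExR",
        "dExR": "ExR",
    }[species]
    tail = times >= times[-1] - plateau_window_min
    num = float(np.mean(raw[tail]))
    den = float(np.mean(ts.values(partner)[tail]))
    ratio = num / den if den > 0 else None

    return DynamicsReport(
        species=species,
        emax_value=emax,
        t_emax_min=t_emax,
        t_ec50_min=t_ec50,
        initial_rate_pct_per_min=initial_rate,
        reduction_at_emax_pct=reduction,
        equilibrium_ratio=ratio,
        lag_time_s=lag,
        total=total,
    )


@dataclass
class OscillationReport:
    classification: str  # graded | oscillatory | sustained_oscillation
    peaks: list[tuple[float, float]]  # (time_min, height)
    mean_period_min: float | None
    mean_amplitude: float | None


def detect_oscillation(
    ts: TimeSeries,
    species: str = "pMAPK",
    min_prominence_frac: float = 0.1,
    min_peaks: int = 2,
    smooth_window_min: float = 1.0,
    sustain_ratio: float = 0.5,
) -> OscillationReport:
    """Classify a trace as graded, oscillatory, or showing sustained oscillation.

    Peaks are detected on the smoothed trace with prominence at least
    ``min_prominence_frac`` of the trace maximum.  Fewer than ``min_peaks``
    peaks is graded; at least three peaks whose last height is at least
    ``sustain_ratio`` of the first counts as sustained (non-decaying)
    oscillation.
    """
    if len(ts) < 20:
        raise ValueError("need at least 20 samples to classify oscillation")
    times = ts.time_min
    tr = smooth_trace(ts.values(species), times, smooth_window_min)
    emax = tr.max()
    if emax <= 0:
        return OscillationReport("graded", [], None, None)
    idx, props = signal.find_peaks(tr, prominence=min_prominence_frac * emax)
    peaks = [(float(times[i]), float(tr[i])) for i in idx]
    if len(peaks) < min_peaks:
        cls = "graded"
    elif len(peaks) >= 3 and peaks[-1][1] >= sustain_ratio * peaks[0][1]:
        cls = "sustained_oscillation"
    else:
        cls = "oscillatory"
    period = float(np.mean(np.diff([t for t, _ in peaks]))) if len(peaks) >= 2 else None
    amp = float(np.mean(props["prominences"])) if len(peaks) else None
    return OscillationReport(cls, peaks, period, amp)


def fitted_rise_time(
    ts: TimeSeries,
    species: str = "pMAPK",
    frac: float = 0.95,
    plateau_window_min: float = 30.0,
    smooth_window_min: float = 1.0,
) -> float:
    """Time to reach ``frac`` of the plateau, from a fitted exponential rise.

    This is the time-to-E_max estimator used for the time calibration.  Long
    stochastic runs drift slowly upward after the activation knee, so a
    threshold crossing against the trace maximum (or even against the plateau
    mean) can land far out on that creep instead of at the knee, making
    threshold estimators bimodal across seeds.  Instead the rise segment
    (between 10% and 80% of the trailing ``plateau_window_min`` plateau mean)
    is fit with ``P - A*exp(-k*t)`` via log-linear regression, and the
    ``frac`` crossing time is read off the fit, which is insensitive to what
    the trace does after the knee.  Returns the time in minutes.
    """
    if len(ts) == 0:
        raise ValueError("empty time series")
    times = ts.time_min
    raw = ts.values(species)
    plateau = float(np.mean(raw[times >= times[-1] - plateau_window_min]))
    if plateau <= 0:
        raise ValueError(f"{species} plateau is zero; trace never activates")
    tr = smooth_trace(raw, times, smooth_window_min)
    if not (tr >= 0.80 * plateau).any():
        raise ValueError(f"{species} never reaches 80% of its plateau mean")
    i0 = int(np.argmax(tr >= 0.10 * plateau))
    i1 = int(np.argmax(tr >= 0.80 * plateau))
    if i1 - i0 < 2:
        raise ValueError("rise segment too short to fit")
    seg_t = times[i0 : i1 + 1]
    residual = np.clip(plateau - tr[i0 : i1 + 1], 1e-9, None)
    slope, intercept = np.polyfit(seg_t, np.log(residual), 1)
    if slope >= 0:
        raise ValueError("rise segment is not increasing toward the plateau")
    k = -slope
    amplitude = float(np.exp(intercept))
    return float(np.log(amplitude / ((1.0 - frac) * plateau)) / k)


def calibrate_minutes_per_step(steps_to_emax: int, target_emax_min: float = 7.63) -> float:
    """Convert the step count needed to reach E_max into minutes per step.

    The conversion anchors model time to the literature median time-to-E_max
    of MAPK activation (7.63 min by default; 7.73 min is the mean-based
    variant).
    """
    if steps_to_emax <= 0:
        raise ValueError("steps_to_emax must be positive")
    return target_emax_min / steps_to_emax


def replicate_sd(
    runs: list[TimeSeries],
    species: str = "pMAPK",
    timepoints_min: np.ndarray | None = None,
) -> pd.DataFrame:
    """Cross-replicate standard deviation as a percent of the cross-run mean.

    Runs must share an identical sampling grid.  Returns a frame with columns
    ``time_min``, ``mean``, ``sd``, ``sd_pct`` (NaN where the mean is zero).
    """
    if len(runs) < 2:
        raise ValueError("need at least two runs")
    grid = runs[0].time_min
    for r in runs[1:]:
        if len(r.time_min) != len(grid) or not np.allclose(r.time_min, grid):
            raise ValueError("runs have mismatched sampling grids")
    mat = np.vstack([r.values(species) for r in runs])
    if timepoints_min is not None:
        cols = [int(np.argmin(np.abs(grid - t))) for t in np.asarray(timepoints_min)]
        mat = mat[:, cols]
        grid = grid[cols]
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(mean > 0, 100.0 * sd / mean, np.nan)
    return pd.DataFrame({"time_min": grid, "mean": mean, "sd": sd, "sd_pct": pct})


# ---------------------------------------------------------------------------
# hypothesis-test wrappers


def dagostino_pearson(values) -> float:
    """D'Agostino–Pearson omnibus normality test; returns the p-value."""
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise ValueError("D'Agostino-Pearson test needs at least 8 values")
    return float(stats.normaltest(x).pvalue)


def one_way_anova(*groups) -> tuple[float, float]:
    """One-way ANOVA across groups; returns (F, p)."""
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("one-way ANOVA needs at least two values per group")
    res = stats.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def t_test(a, b) -> tuple[float, float]:
    """Two-sample Student t-test; returns (t, p)."""
    if len(a) < 2 or len(b) < 2:
        raise ValueError("t-test needs at least two values per sample")
    res = stats.ttest_ind(a, b)
    return float(res.statistic), float(res.pvalue)


def holm_sidak(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm–Šidák multiple-testing correction; returns (reject, adjusted p)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("holm_sidak needs at least one p-value")
    reject, adj, _, _ = multipletests(p, alpha=alpha, method="holm-sidak")
    return reject, adj
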