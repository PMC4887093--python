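"""Re-activation delay period (RADP) schedulers.

After a pMAPKK phosphorylates a MAPK it goes dormant for its RADP — the
model's abstraction of phosphatase-mediated negative feedback on the MAPKK
tier.  The delay is drawn either

* **deterministically** (periodic): every dormancy lasts exactly the upper
  bound ``n``,
* **stochastically**: each dormancy is drawn uniformly on ``[lower, upper)``
  (a truncated-normal variant is available for sensitivity checks), or
* not at all (**constitutive** MAPKK never goes dormant on binding).

A :class:`RadpSchedule` strings several RADP configurations together with
switch triggers (fixed times or plateau detection on a recorded species),
which is how phase-switching experiments — strong stimulus, then strong
inhibition, then moderate periodic drive — are expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

VALID_MODES = ("deterministic", "stochastic", "constitutive")


@dataclass(frozen=True)
class RadpConfig:
    """One re-activation delay rule.  Times are in seconds."""

    mode: str = "constitutive"
    lower: float = 0.0
    upper: float = 0.0
    #: "uniform" (default) or "truncnorm" for the stochastic mode
    distribution: str = "uniform"

    def __post_init__(self):
        if self.mode not in VALID_MODES:
            raise ValueError(f"mode must be one of {VALID_MODES}, got {self.mode!r}")
        if not 0 <= self.lower <= self.upper:
            raise ValueError("require 0 <= lower <= upper")
        if self.distribution not in ("uniform", "truncnorm"):
            raise ValueError("distribution must be 'uniform' or 'truncnorm'")


def draw_radp(config: RadpConfig, rng: np.random.Generator, size: int | None = None):
    """Draw dormancy duration(s) in seconds for newly deactivated MAPKK."""
    if config.mode == "constitutive":
        raise ValueError("constitutive MAPKK never goes dormant: no RADP to draw")
    if config.mode == "deterministic":
        return config.upper if size is None else np.full(size, config.upper)
    if config.distribution == "truncnorm":
        lo, hi = config.lower, config.upper
        if hi == lo:
            return lo if size is None else np.full(size, lo)
        mu, sd = 0.5 * (lo + hi), (hi - lo) / 4.0
        a, b = (lo - mu) / sd, (hi - mu) / sd
        out = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size or 1, random_state=rng)
        return float(out[0]) if size is None else out
    if config.upper == config.lower:
        return config.lower if size is None else np.full(size, config.lower)
    out = rng.uniform(config.lower, config.upper, size=size or 1)
    return float(out[0]) if size is None else out


def runs_test(values) -> float:
    """One-sample (Wald–Wolfowitz) runs test about the median.

    Values equal to the median are dropped; the two-sided p-value comes from
    the normal approximation of the run-count statistic.  A small p rejects
    randomness of the ordering; the delay sequences drawn by the stochastic
    scheduler should not reject.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2 or np.all(x == x[0]):
        raise ValueError("runs test needs at least two non-identical values")
    med = np.median(x)
    signs = x[x != med] > med
    n1 = int(signs.sum())
    n2 = int(signs.size - n1)
    if n1 == 0 or n2 == 0:
        raise ValueError("runs test undefined: all retained values on one side of the median")
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n = n1 + n2
    mu = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n * n * (n - 1.0))
    z = (runs - mu) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# phase-switching schedules


@dataclass(frozen=True)
class FixedTimeTrigger:
    """Fires at a fixed simulated time (minutes)."""

    at_min: float


@dataclass(frozen=True)
class PlateauTrigger:
    """Fires when a recorded species is at equilibrium over a trailing window.

    Equilibrium means the trace is stationary: the means of the first and
    second half of the window differ by at most ``rel_tol`` of the window
    mean.  A half-mean comparison (rather than a max-min flatness test) lets
    the trigger fire on noisy or oscillating-but-stationary traces, which a
    stochastic particle count always is.  The window must lie entirely inside
    the current phase and the windowed mean must be positive, so an all-zero
    trace never counts as a plateau.
    """

    species: str = "pMAPK"
    window_min: float = 5.0
    rel_tol: float = 0.01


Trigger = FixedTimeTrigger | PlateauTrigger | None


@dataclass(frozen=True)
class Phase:
    radp: RadpConfig
    trigger: Trigger = None  # None = active from the start of the run


@dataclass
class RadpSchedule:
    phases: list[Phase] = field(default_factory=list)

    def __post_init__(self):
        if not self.phases:
            raise ValueError("schedule needs at least one phase")
        for ph in self.phases[1:]:
            if ph.trigger is None:
                raise ValueError("every phase after the first needs a trigger")

    @classmethod
    def single(cls, radp: RadpConfig) -> "RadpSchedule":
        return cls(phases=[Phase(radp)])


class ScheduleCursor:
    """Stateful walker over a schedule, advanced once per recorded step."""

    def __init__(self, schedule: RadpSchedule):
        self.schedule = schedule
        self.index = 0
        self.phase_start_min = 0.0
        self.switch_log: list[tuple[float, int]] = []

    @property
    def active(self) -> RadpConfig:
        return self.schedule.phases[self.index].radp

    def update(self, t_min: float, times_min: np.ndarray, series: dict[str, np.ndarray]) -> bool:
        """Check the next phase's trigger at time ``t_min``; advance if fired.

        ``times_min``/``series`` are the recorded history so far (including
        the current step).  Returns True when a switch happened.
        """
        if self.index + 1 >= len(self.schedule.phases):
            return False
        trig = self.schedule.phases[self.index + 1].trigger
        fired = False
        if isinstance(trig, FixedTimeTrigger):
            fired = t_min >= trig.at_min
        elif isinstance(trig, PlateauTrigger):
            lo = t_min - trig.window_min
            if lo >= self.phase_start_min:
                m = times_min >= lo
                vals = np.asarray(series[trig.species], dtype=float)[m]
                if vals.size >= 4:
                    mean = vals.mean()
                    half = vals.size // 2
                    drift = abs(vals[half:].mean() - vals[:half].mean())
                    if mean > 0 and drift / mean <= trig.rel_tol:
                        fired = True
        if fired:
            self.index += 1
            self.phase_start_min = t_min
            self.switch_log.append((t_min, self.index))
            # a later trigger may already hold (e.g. two past fixed times)
            self.update(t_min, times_min, series)
        return fired


def advance_schedule(
    schedule: RadpSchedule,
    times_min: np.ndarray,
    series: dict[str, np.ndarray],
) -> RadpConfig:
    """Replay a schedule over a recorded history; return the active config.

    Functional counterpart of :class:`ScheduleCursor`: walks the history in
    order, firing triggers as they would have fired during the run.
    """
    times_min = np.asarray(times_min, dtype=float)
    cursor = ScheduleCursor(schedule)
    for i, t in enumerate(times_min):
        hist = {k: np.asarray(v)[: i + 1] for k, v in series.items()}
        cursor.update(float(t), times_min[: i + 1], hist)
    return cursor.active
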