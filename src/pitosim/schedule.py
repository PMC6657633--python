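"""Minute-resolution simulation of maternal Pitocin concentration.

Schedules are piecewise-constant infusion-rate sequences sampled at the
circulation-cycle resolution (default one minute).  The simulator applies
the add-then-decay recursion ``C_t = (C_{t-1} + k_t) * r`` cycle by cycle,
which for a constant rate reproduces the geometric partial sums of
:mod:`pitosim.pk_core` exactly and converges to the steady state ``M*k``.
The trajectory tracked is the end-of-cycle baseline (the lower envelope of
the intra-cycle fluctuation).

Builders cover the three clinically relevant shapes: constant infusion,
the stepped ramp used in practice (rate raised every 30 minutes until a
cap), and pulsatile protocols that mimic the natural pulsed secretion of
oxytocin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .pk_core import (
    PG_PER_MILLIUNIT,
    CycleParams,
    MaternalProfile,
    multiplier,
    pitocin_mass_per_minute,
    retention_fraction,
)

__all__ = [
    "InfusionSchedule",
    "ConcentrationSeries",
    "Dose",
    "constant_schedule",
    "stepped_ramp",
    "pulsatile_schedule",
    "simulate",
    "total_dose",
    "write_series_csv",
    "series_to_json",
    "write_series_json",
    "read_schedule_csv",
]


def _n_cycles(duration_min: float, cycle_min: float, what: str) -> int:
    """Whole number of cycles in ``duration_min``; sub-cycle durations are rejected."""
    n = duration_min / cycle_min
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"{what} ({duration_min} min) is not a whole number of "
            f"{cycle_min}-min cycles; sub-cycle durations are not supported"
        )
    return int(round(n))


@dataclass(frozen=True)
class InfusionSchedule:
    """Piecewise-constant infusion rate, one entry per circulation cycle."""

    rates_mU_min: np.ndarray
    cycle_min: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates_mU_min, dtype=float)
        if rates.ndim != 1:
            raise ValueError("rates_mU_min must be one-dimensional")
        if np.any(rates < 0):
            raise ValueError("infusion rates must be non-negative")
        if self.cycle_min <= 0:
            raise ValueError(f"cycle_min must be positive, got {self.cycle_min}")
        rates.setflags(write=False)
        object.__setattr__(self, "rates_mU_min", rates)

    @property
    def n_cycles(self) -> int:
        return int(self.rates_mU_min.size)

    @property
    def duration_min(self) -> float:
        return self.n_cycles * self.cycle_min


@dataclass(frozen=True)
class ConcentrationSeries:
    """Per-cycle maternal concentration trajectory with its analytic asymptote.

    ``times_min`` stamps the *end* of each cycle (minute 1 = after the
    first cycle), so the 30-minute value is the 30th iterate.
    ``steady_state_pg_ml`` is ``M*k`` for the final rate segment.
    """

    times_min: np.ndarray
    conc_pg_ml: np.ndarray
    rates_mU_min: np.ndarray
    steady_state_pg_ml: float
    cycle_min: float = 1.0

    def __post_init__(self) -> None:
        for name in ("times_min", "conc_pg_ml", "rates_mU_min"):
            arr = np.asarray(getattr(self, name), dtype=float)
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)
        if not (
            self.times_min.size == self.conc_pg_ml.size == self.rates_mU_min.size
        ):
            raise ValueError("times, concentrations and rates must align")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times_min,
                "rate_mU_min": self.rates_mU_min,
                "conc_pg_ml": self.conc_pg_ml,
            }
        )


def constant_schedule(
    rate_mU_min: float,
    duration_min: float,
    *,
    cycle_min: float = 1.0,
    label: str = "",
) -> InfusionSchedule:
    """Uniform infusion at ``rate_mU_min`` for ``duration_min`` minutes."""
    if rate_mU_min < 0:
        raise ValueError(f"rate must be non-negative, got {rate_mU_min}")
    if duration_min <= 0:
        raise ValueError(f"duration must be positive, got {duration_min}")
    n = _n_cycles(duration_min, cycle_min, "duration_min")
    return InfusionSchedule(
        np.full(n, float(rate_mU_min)),
        cycle_min=cycle_min,
        label=label or f"constant {rate_mU_min} mU/min",
    )


def stepped_ramp(
    start_mU_min: float,
    step_mU_min: float,
    *,
    step_duration_min: float = 30.0,
    max_rate_mU_min: float,
    total_min: float,
    cycle_min: float = 1.0,
    label: str = "",
) -> InfusionSchedule:
    """Clinical ramp: rate raised by ``step`` every ``step_duration`` minutes.

    The 30-minute default step duration is the usual hold at each buildup
    interval.  The rate is capped at ``max_rate_mU_min``.
    """
    if start_mU_min < 0 or step_mU_min < 0:
        raise ValueError("start and step must be non-negative")
    if step_duration_min <= 0:
        raise ValueError("step_duration_min must be positive")
    if max_rate_mU_min < start_mU_min:
        raise ValueError(
            f"max_rate ({max_rate_mU_min}) below starting rate ({start_mU_min})"
        )
    n_total = _n_cycles(total_min, cycle_min, "total_min")
    per_step = _n_cycles(step_duration_min, cycle_min, "step_duration_min")
    rates = np.empty(n_total)
    for i in range(n_total):
        block = i // per_step
        rates[i] = min(start_mU_min + block * step_mU_min, max_rate_mU_min)
    return InfusionSchedule(
        rates,
        cycle_min=cycle_min,
        label=label
        or f"ramp {start_mU_min}+{step_mU_min}/{step_duration_min}min cap {max_rate_mU_min}",
    )


def pulsatile_schedule(
    pulse_rate_mU_min: float,
    pulse_min: float,
    period_min: float,
    total_min: float,
    *,
    cycle_min: float = 1.0,
    label: str = "",
) -> InfusionSchedule:
    """On-off protocol: ``pulse_rate`` for the first ``pulse_min`` of each period."""
    if pulse_rate_mU_min < 0:
        raise ValueError("pulse_rate must be non-negative")
    if not 0 < pulse_min <= period_min:
        raise ValueError(
            f"need 0 < pulse_min <= period_min, got {pulse_min}, {period_min}"
        )
    n_total = _n_cycles(total_min, cycle_min, "total_min")
    n_pulse = _n_cycles(pulse_min, cycle_min, "pulse_min")
    n_period = _n_cycles(period_min, cycle_min, "period_min")
    idx = np.arange(n_total)
    rates = np.where(idx % n_period < n_pulse, float(pulse_rate_mU_min), 0.0)
    return InfusionSchedule(
        rates,
        cycle_min=cycle_min,
        label=label or f"pulsatile {pulse_rate_mU_min} mU/min {pulse_min}/{period_min}",
    )


def simulate(
    schedule: InfusionSchedule,
    profile: MaternalProfile,
    cycle: CycleParams | None = None,
    *,
    initial_conc_pg_ml: float = 0.0,
) -> ConcentrationSeries:
    """Run the add-then-decay recursion over the schedule.

    ``C_0 = initial_conc`` (default 0: endogenous oxytocin is ignored);
    ``C_t = (C_{t-1} + k_t) * r`` with ``k_t`` the increment for the
    cycle's rate.  For a constant rate this equals the geometric partial
    sum at every cycle and converges to ``M*k``.
    """
    if cycle is None:
        cycle = CycleParams(schedule.cycle_min)
    elif abs(cycle.cycle_min - schedule.cycle_min) > 1e-12:
        raise ValueError(
            f"cycle length {cycle.cycle_min} does not match schedule "
            f"({schedule.cycle_min})"
        )
    if initial_conc_pg_ml < 0:
        raise ValueError("initial concentration must be non-negative")
    dt = cycle.cycle_min
    r = retention_fraction(profile.half_life_min, dt)
    k = schedule.rates_mU_min * PG_PER_MILLIUNIT * dt / profile.blood_volume_ml
    conc = np.empty(schedule.n_cycles)
    c = float(initial_conc_pg_ml)
    for t in range(schedule.n_cycles):
        c = (c + k[t]) * r
        conc[t] = c
    k_last = float(k[-1]) if k.size else 0.0
    return ConcentrationSeries(
        times_min=dt * np.arange(1, schedule.n_cycles + 1),
        conc_pg_ml=conc,
        rates_mU_min=schedule.rates_mU_min,
        steady_state_pg_ml=multiplier(r) * k_last,
        cycle_min=dt,
    )


class Dose(NamedTuple):
    """Total delivered dose in milli-units and picograms."""

    mU: float
    pg: float


def total_dose(schedule: InfusionSchedule) -> Dose:
    """Total dose over the schedule: sum of rate x cycle length."""
    mu = float(np.sum(schedule.rates_mU_min) * schedule.cycle_min)
    return Dose(mU=mu, pg=pitocin_mass_per_minute(mu))


# ---------------------------------------------------------------------------
# plain-text I/O


def write_series_csv(series: ConcentrationSeries, path) -> None:
    series.to_frame().to_csv(path, index=False, float_format="%.6f")


def series_to_json(
    series: ConcentrationSeries,
    schedule: InfusionSchedule | None = None,
    metadata: dict | None = None,
) -> dict:
    out = {
        "cycle_min": series.cycle_min,
        "steady_state_pg_ml": series.steady_state_pg_ml,
        "times_min": series.times_min.tolist(),
        "rates_mU_min": series.rates_mU_min.tolist(),
        "conc_pg_ml": series.conc_pg_ml.tolist(),
    }
    if schedule is not None:
        out["schedule_label"] = schedule.label
        out["total_dose_mU"] = total_dose(schedule).mU
    if metadata:
        out["metadata"] = dict(metadata)
    return out


def write_series_json(series, path, schedule=None, metadata=None) -> None:
    with open(path, "w") as fh:
        json.dump(series_to_json(series, schedule, metadata), fh, indent=1)


def read_schedule_csv(
    path, *, total_min: float, cycle_min: float = 1.0, label: str = ""
) -> InfusionSchedule:
    """Read piecewise-constant segments (columns start_min, rate_mU_min).

    Segments extend to the next start; the last runs to ``total_min``.
    """
    df = pd.read_csv(path, comment="#")
    required = {"start_min", "rate_mU_min"}
    if not required.issubset(df.columns):
        raise ValueError(f"schedule CSV needs columns {sorted(required)}")
    starts = df["start_min"].to_numpy(dtype=float)
    if starts.size == 0:
        raise ValueError("schedule CSV has no segments")
    if not np.all(np.diff(starts) > 0) or starts[0] != 0:
        raise ValueError("start_min must begin at 0 and be strictly increasing")
    n_total = _n_cycles(total_min, cycle_min, "total_min")
    times = cycle_min * np.arange(n_total)  # cycle start times
    seg = np.searchsorted(starts, times, side="right") - 1
    rates = df["rate_mU_min"].to_numpy(dtype=float)[seg]
    return InfusionSchedule(rates, cycle_min=cycle_min, label=label or str(path))
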