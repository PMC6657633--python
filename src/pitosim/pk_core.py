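"""Closed-form kinetics of Pitocin buildup in the maternal circulation.

The model is a discrete one-compartment description of continuous
intravenous Pitocin (synthetic oxytocin) infusion during labor.  Time is
divided into circulation cycles of length ``t'`` (default one minute, the
nominal time for the maternal blood to complete one circuit).  Each cycle
the infusion adds a concentration increment

    k = IR * 2e4 * t' / V      [pg/ml]

where ``IR`` is the infusion rate in mU/min (1 mU of Pitocin solution
carries 2e4 pg of oxytocin) and ``V`` is the maternal blood volume in ml
(65 ml per kg body weight).  Renal/hepatic clearance removes a fixed
fraction per cycle, leaving the retention fraction

    r = exp(-ln 2 * t' / t_half),

so the end-of-cycle concentration follows the add-then-decay recursion
``C_t = (C_{t-1} + k) * r``.  Summing the geometric series gives the
partial sum ``C_n = k * r * (1 - r^n) / (1 - r)`` and the steady state
``C = M * k`` with multiplier ``M = r / (1 - r)``.

All quantities are kept in pg, ml and minutes internally; conversions
(pounds, liters, iU) happen only at construction or I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ML_BLOOD_PER_KG",
    "PG_PER_MILLIUNIT",
    "KG_PER_LB",
    "LN2",
    "CycleParams",
    "MaternalProfile",
    "KineticConstants",
    "round_sig",
    "blood_volume_from_weight",
    "retention_fraction",
    "removal_retention_percent",
    "pitocin_mass_per_minute",
    "per_cycle_increment",
    "multiplier",
    "buildup_concentration",
    "steady_state_concentration",
    "kinetic_constants",
]

#: Circulating blood volume per unit body weight for an adult woman (ml/kg).
ML_BLOOD_PER_KG = 65.0

#: Oxytocin mass per milli-unit of Pitocin solution (pg/mU).
#: 1 U of solution (1 liter) contains 10 iU; 1 iU = 2 ug, so
#: 1 mU = 1e-2 iU = 2e-2 ug = 2e4 pg.
PG_PER_MILLIUNIT = 2.0e4

#: Exact avoirdupois pound (kg/lb).
KG_PER_LB = 0.45359237

LN2 = math.log(2.0)


def round_sig(x: float, figures: int = 2) -> float:
    """Round ``x`` to the given number of significant figures."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + figures - 1)


def blood_volume_from_weight(weight_kg: float) -> float:
    """Circulating blood volume (ml) at 65 ml per kg body weight."""
    if weight_kg <= 0:
        raise ValueError(f"weight_kg must be positive, got {weight_kg}")
    return weight_kg * ML_BLOOD_PER_KG


def retention_fraction(half_life_min: float, cycle_min: float = 1.0) -> float:
    """Fraction of circulating oxytocin remaining after one cycle.

    r = exp(-ln 2 * cycle_min / half_life_min), strictly in (0, 1).
    """
    if half_life_min <= 0:
        raise ValueError(f"half_life_min must be positive, got {half_life_min}")
    if cycle_min <= 0:
        raise ValueError(f"cycle_min must be positive, got {cycle_min}")
    return math.exp(-LN2 * cycle_min / half_life_min)


def removal_retention_percent(
    half_life_min: float, cycle_min: float = 1.0
) -> tuple[float, float]:
    """Percent oxytocin removed by liver/kidneys and percent remaining per cycle.

    Returns ``(removed, remaining)``; the pair sums to 100 by construction.
    """
    remaining = 100.0 * retention_fraction(half_life_min, cycle_min)
    return 100.0 - remaining, remaining


def pitocin_mass_per_minute(infusion_rate_mU_min: float) -> float:
    """Oxytocin mass (pg) delivered per minute at the given infusion rate."""
    if infusion_rate_mU_min < 0:
        raise ValueError(
            f"infusion_rate_mU_min must be non-negative, got {infusion_rate_mU_min}"
        )
    return infusion_rate_mU_min * PG_PER_MILLIUNIT


def per_cycle_increment(
    infusion_rate_mU_min: float,
    blood_volume_ml: float,
    cycle_min: float = 1.0,
) -> float:
    """Concentration increment k (pg/ml) added per circulation cycle.

    k = IR * 2e4 * cycle_min / V.  A zero rate is allowed (off-phase of a
    pulsatile schedule) and yields k = 0.
    """
    if infusion_rate_mU_min < 0:
        raise ValueError(
            f"infusion_rate_mU_min must be non-negative, got {infusion_rate_mU_min}"
        )
    if blood_volume_ml <= 0:
        raise ValueError(f"blood_volume_ml must be positive, got {blood_volume_ml}")
    if cycle_min <= 0:
        raise ValueError(f"cycle_min must be positive, got {cycle_min}")
    return pitocin_mass_per_minute(infusion_rate_mU_min) * cycle_min / blood_volume_ml


def multiplier(retention_r: float) -> float:
    """Steady-state multiplier M = r / (1 - r)."""
    if not 0.0 < retention_r < 1.0:
        raise ValueError(f"retention_r must lie strictly in (0, 1), got {retention_r}")
    return retention_r / (1.0 - retention_r)


def buildup_concentration(
    k_pg_ml: float, retention_r: float, n_cycles: float
) -> float:
    """Concentration after ``n_cycles`` cycles of constant infusion.

    Partial sum of the geometric series with the add-then-decay convention:
    ``C_n = k * r * (1 - r^n) / (1 - r)``.  ``n_cycles = math.inf`` gives
    the steady state ``M * k``.
    """
    if k_pg_ml < 0:
        raise ValueError(f"k_pg_ml must be non-negative, got {k_pg_ml}")
    if n_cycles < 0:
        raise ValueError(f"n_cycles must be non-negative, got {n_cycles}")
    m = multiplier(retention_r)
    return k_pg_ml * m * (1.0 - retention_r**n_cycles)


def steady_state_concentration(k_pg_ml: float, retention_r: float) -> float:
    """Asymptotic concentration C = M * k (pg/ml)."""
    if k_pg_ml < 0:
        raise ValueError(f"k_pg_ml must be non-negative, got {k_pg_ml}")
    return multiplier(retention_r) * k_pg_ml


@dataclass(frozen=True)
class CycleParams:
    """Duration of one maternal blood circulation cycle (minutes)."""

    cycle_min: float = 1.0

    def __post_init__(self) -> None:
        if self.cycle_min <= 0:
            raise ValueError(f"cycle_min must be positive, got {self.cycle_min}")


@dataclass(frozen=True)
class MaternalProfile:
    """Per-patient physiology: blood volume and oxytocin half-life.

    Construct either directly from a blood volume or via
    :meth:`from_weight`, which applies the 65 ml/kg rule.  With
    ``rounded_volume=True`` the derived volume is rounded to two
    significant figures (160 lb -> 4.7e3 ml, 128 lb -> 3.8e3 ml), the
    clinical shorthand used by the reference tables; default keeps full
    precision.
    """

    blood_volume_ml: float
    half_life_min: float
    weight_kg: float | None = None
    weight_lb: float | None = None

    def __post_init__(self) -> None:
        if self.blood_volume_ml <= 0:
            raise ValueError(
                f"blood_volume_ml must be positive, got {self.blood_volume_ml}"
            )
        if self.half_life_min <= 0:
            raise ValueError(
                f"half_life_min must be positive, got {self.half_life_min}"
            )
        if self.weight_kg is not None and self.weight_kg <= 0:
            raise ValueError(f"weight_kg must be positive, got {self.weight_kg}")

    @classmethod
    def from_weight(
        cls,
        *,
        weight_lb: float | None = None,
        weight_kg: float | None = None,
        half_life_min: float,
        rounded_volume: bool = False,
    ) -> "MaternalProfile":
        """Build a profile from body weight using the 65 ml/kg rule."""
        if (weight_lb is None) == (weight_kg is None):
            raise ValueError("specify exactly one of weight_lb or weight_kg")
        if weight_kg is None:
            assert weight_lb is not None
            weight_kg = weight_lb * KG_PER_LB
        else:
            weight_lb = weight_kg / KG_PER_LB
        volume = blood_volume_from_weight(weight_kg)
        if rounded_volume:
            volume = round_sig(volume, 2)
        return cls(
            blood_volume_ml=volume,
            half_life_min=half_life_min,
            weight_kg=weight_kg,
            weight_lb=weight_lb,
        )


@dataclass(frozen=True)
class KineticConstants:
    """Derived constants r, M, k and C for one (rate, profile) combination."""

    retention_r: float
    multiplier_M: float
    increment_k_pg_ml: float
    steady_state_C_pg_ml: float


def kinetic_constants(
    infusion_rate_mU_min: float,
    profile: MaternalProfile,
    cycle: CycleParams = CycleParams(),
) -> KineticConstants:
    """Solve the closed-form constants for a constant-rate infusion."""
    r = retention_fraction(profile.half_life_min, cycle.cycle_min)
    m = multiplier(r)
    k = per_cycle_increment(
        infusion_rate_mU_min, profile.blood_volume_ml, cycle.cycle_min
    )
    return KineticConstants(
        retention_r=r,
        multiplier_M=m,
        increment_k_pg_ml=k,
        steady_state_C_pg_ml=m * k,
    )
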