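"""Synthetic labor cohorts and the threshold-mixture association argument.

A population in which only labors whose cumulative fetal oxytocin
exposure crosses the desensitization threshold carry an elevated outcome
risk is a two-component mixture: exposed-but-below-threshold labors are
indistinguishable from unexposed ones (baseline risk ``p0``), while the
above-threshold minority carries risk ``p1``.  If a fraction ``f`` of
exposed labors cross, the expected population relative risk is

    RR = 1 + f * (p1/p0 - 1),

so a strong per-stratum effect (``p1/p0``) attenuates toward the null as
``f -> 0`` — weak whole-population associations are compatible with a
strong above-threshold effect.  This module generates such cohorts from
configurable parameter distributions, flags threshold crossings with the
kinetic model, and computes the 2x2 association measures.

Reproducibility: a single master seed is split into one independent
substream per drawn variable, and every distribution is sampled by
inverse CDF, so enlarging ``n_cases`` never reshuffles earlier cases.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Iterator, Union

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.contingency_tables import Table2x2

from .desensitization import constant_infusion_exposure
from .pk_core import (
    KG_PER_LB,
    ML_BLOOD_PER_KG,
    PG_PER_MILLIUNIT,
    MaternalProfile,
    round_sig,
)
from .schedule import InfusionSchedule, constant_schedule

__all__ = [
    "TruncatedNormal",
    "Uniform",
    "TruncatedLogNormal",
    "CohortConfig",
    "LaborCase",
    "LaborCohort",
    "StratumResult",
    "AssociationResult",
    "generate_cohort",
    "high_exposure_config",
    "association",
    "association_from_counts",
    "expected_relative_risk",
    "limit_for_crossing_fraction",
    "load_cohort_config",
    "write_cases_csv",
    "write_association_json",
]


# ---------------------------------------------------------------------------
# distributions (inverse-CDF sampled for prefix-stable streams)


@dataclass(frozen=True)
class TruncatedNormal:
    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self):
        if self.sd <= 0 or not self.lower < self.upper:
            raise ValueError("need sd > 0 and lower < upper")

    def ppf(self, u):
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return stats.truncnorm.ppf(u, a, b, loc=self.mean, scale=self.sd)


@dataclass(frozen=True)
class Uniform:
    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError("need low < high")

    def ppf(self, u):
        return self.low + np.asarray(u) * (self.high - self.low)


@dataclass(frozen=True)
class TruncatedLogNormal:
    """Log-normal with log-scale mean/sd, truncated to [lower, upper]."""

    log_mean: float
    log_sd: float
    lower: float
    upper: float

    def __post_init__(self):
        if self.log_sd <= 0 or not 0 < self.lower < self.upper:
            raise ValueError("need log_sd > 0 and 0 < lower < upper")

    def ppf(self, u):
        dist = stats.lognorm(s=self.log_sd, scale=math.exp(self.log_mean))
        lo, hi = dist.cdf(self.lower), dist.cdf(self.upper)
        return dist.ppf(lo + np.asarray(u) * (hi - lo))


Distribution = Union[TruncatedNormal, Uniform, TruncatedLogNormal]

_DIST_KINDS = {
    "truncnorm": TruncatedNormal,
    "uniform": Uniform,
    "trunclognorm": TruncatedLogNormal,
}


def _dist_from_dict(spec: dict) -> Distribution:
    spec = dict(spec)
    kind = spec.pop("kind")
    try:
        cls = _DIST_KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown distribution kind {kind!r}") from None
    return cls(**spec)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    The oxytocinase limit ``L`` is required (no measured value exists).
    Default distributions are illustrative clinical ranges: weight
    ~ truncated normal 150 +/- 25 lb on [90, 250]; half-life uniform on
    the reported 1-6 min; infusion rate truncated normal 12 +/- 5 mU/min
    on [1, 36]; infusion duration log-normal, median 8 h, on [1 h, 48 h].
    """

    n_cases: int
    oxytocinase_limit_pg_ml: float
    weight_lb: Distribution = TruncatedNormal(150.0, 25.0, 90.0, 250.0)
    half_life_min: Distribution = Uniform(1.0, 6.0)
    infusion_rate_mU_min: Distribution = TruncatedNormal(12.0, 5.0, 1.0, 36.0)
    duration_min: Distribution = TruncatedLogNormal(
        math.log(480.0), 0.45, 60.0, 2880.0
    )
    exposure_fraction: float = 0.5
    baseline_risk_p0: float = 0.01
    above_threshold_risk_p1: float = 0.10
    D_pg_min_per_ml: float = 1.8e6
    seed: int = 0
    rounded_volume: bool = False

    def __post_init__(self):
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        if not 0 <= self.baseline_risk_p0 <= self.above_threshold_risk_p1 <= 1:
            raise ValueError("need 0 <= p0 <= p1 <= 1")
        if not 0 <= self.exposure_fraction <= 1:
            raise ValueError("exposure_fraction must lie in [0, 1]")
        if self.oxytocinase_limit_pg_ml < 0:
            raise ValueError("oxytocinase limit must be non-negative")
        if self.D_pg_min_per_ml <= 0:
            raise ValueError("D must be positive")


def high_exposure_config(
    n_cases: int, oxytocinase_limit_pg_ml: float, *, seed: int = 0, **overrides
) -> CohortConfig:
    """Config for the high-exposure stratum: long labors at high rates.

    In the general population (the class defaults) cumulative override
    exposure essentially never reaches D, even at L = 0 — ordinary
    inductions cannot desensitize.  Attenuation experiments that need an
    appreciable above-threshold fraction therefore target the at-risk
    stratum the threshold mechanism concerns: infusion rates in the
    high-dose-protocol range (truncated normal 30 +/- 8 mU/min on
    [10, 48]), slower oxytocin clearance (half-life uniform on 3-6 min)
    and long infusions (log-normal, median 30 h, on [12 h, 48 h]).
    """
    params = dict(
        n_cases=n_cases,
        oxytocinase_limit_pg_ml=oxytocinase_limit_pg_ml,
        seed=seed,
        infusion_rate_mU_min=TruncatedNormal(30.0, 8.0, 10.0, 48.0),
        half_life_min=Uniform(3.0, 6.0),
        duration_min=TruncatedLogNormal(math.log(1800.0), 0.4, 720.0, 2880.0),
    )
    params.update(overrides)
    return CohortConfig(**params)


def load_cohort_config(path) -> CohortConfig:
    """Read a YAML key-value config; distribution entries carry a 'kind'."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("weight_lb", "half_life_min", "infusion_rate_mU_min", "duration_min"):
        if key in raw and isinstance(raw[key], dict):
            raw[key] = _dist_from_dict(raw[key])
    return CohortConfig(**raw)


# ---------------------------------------------------------------------------
# generation


@dataclass(frozen=True)
class LaborCase:
    """One synthetic labor: physiology, exposure and outcome."""

    profile: MaternalProfile
    ir_mU_min: float
    duration_min: int
    exposed: bool
    threshold_crossed: bool
    outcome: bool

    def __post_init__(self):
        if self.threshold_crossed and not self.exposed:
            raise ValueError("unexposed cases cannot cross the threshold")

    @property
    def schedule(self) -> InfusionSchedule | None:
        """Materialize the constant-rate schedule (None if unexposed)."""
        if not self.exposed:
            return None
        return constant_schedule(self.ir_mU_min, self.duration_min)


@dataclass(frozen=True)
class LaborCohort:
    """Generated cohort: one row per labor, plus the generating config."""

    frame: pd.DataFrame
    config: CohortConfig

    @property
    def n_cases(self) -> int:
        return len(self.frame)

    @property
    def crossing_fraction(self) -> float:
        """Fraction of *exposed* cases whose exposure crossed the threshold."""
        exp = self.frame["exposed"]
        if exp.sum() == 0:
            return 0.0
        return float(self.frame.loc[exp, "threshold_crossed"].mean())

    def iter_cases(self) -> Iterator[LaborCase]:
        for row in self.frame.itertuples(index=False):
            yield LaborCase(
                profile=MaternalProfile(
                    blood_volume_ml=row.blood_volume_ml,
                    half_life_min=row.half_life_min,
                    weight_kg=row.weight_lb * KG_PER_LB,
                    weight_lb=row.weight_lb,
                ),
                ir_mU_min=row.ir_mU_min,
                duration_min=int(row.duration_min),
                exposed=bool(row.exposed),
                threshold_crossed=bool(row.threshold_crossed),
                outcome=bool(row.outcome),
            )


_STREAMS = ("weight", "half_life", "ir", "duration", "exposed", "outcome")


def _draw_parameters(config: CohortConfig) -> pd.DataFrame:
    """Sample the physiological and exposure variables (no outcomes yet)."""
    n = config.n_cases
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    rngs = dict(zip(_STREAMS, (np.random.default_rng(c) for c in children)))

    weight_lb = np.asarray(config.weight_lb.ppf(rngs["weight"].random(n)))
    half_life = np.asarray(config.half_life_min.ppf(rngs["half_life"].random(n)))
    ir = np.asarray(config.infusion_rate_mU_min.ppf(rngs["ir"].random(n)))
    duration = np.rint(
        np.asarray(config.duration_min.ppf(rngs["duration"].random(n)))
    ).astype(int)
    exposed = rngs["exposed"].random(n) < config.exposure_fraction
    u_outcome = rngs["outcome"].random(n)

    volume = weight_lb * KG_PER_LB * ML_BLOOD_PER_KG
    if config.rounded_volume:
        volume = np.array([round_sig(v, 2) for v in volume])
    return pd.DataFrame(
        {
            "weight_lb": weight_lb,
            "blood_volume_ml": volume,
            "half_life_min": half_life,
            "ir_mU_min": ir,
            "duration_min": duration,
            "exposed": exposed,
            "u_outcome": u_outcome,
        }
    )


def generate_cohort(config: CohortConfig) -> LaborCohort:
    """Generate a seeded cohort and flag threshold crossings.

    Exposed cases receive a constant-rate schedule drawn from the
    configured distributions; their cumulative override exposure is
    evaluated with the closed-form constant-rate expression (identical to
    simulating the trajectory and accumulating override, see
    :func:`pitosim.desensitization.constant_infusion_exposure`).  The
    binary outcome is drawn at risk ``p1`` for crossed cases and ``p0``
    otherwise.
    """
    df = _draw_parameters(config)
    exposure = np.where(
        df["exposed"].to_numpy(),
        constant_infusion_exposure(
            df["ir_mU_min"].to_numpy(),
            df["blood_volume_ml"].to_numpy(),
            df["half_life_min"].to_numpy(),
            config.oxytocinase_limit_pg_ml,
            df["duration_min"].to_numpy(),
        ),
        0.0,
    )
    crossed = exposure >= config.D_pg_min_per_ml
    risk = np.where(
        crossed, config.above_threshold_risk_p1, config.baseline_risk_p0
    )
    outcome = df.pop("u_outcome").to_numpy() < risk
    df["exposure_pg_min_ml"] = exposure
    df["threshold_crossed"] = crossed
    df["outcome"] = outcome
    return LaborCohort(frame=df, config=config)


def limit_for_crossing_fraction(
    config: CohortConfig, fraction: float, *, tol: float = 1e-6
) -> float:
    """Oxytocinase limit L at which the given fraction of exposed cases cross.

    For each exposed case the critical limit (largest L at which its
    cumulative exposure still reaches D) is solved by bisection on the
    closed-form exposure; L is then placed between the order statistics of
    those critical limits so that exactly ``round(fraction * n_exposed)``
    cases cross under the same seed.  Used to realize prescribed
    above-threshold fractions in attenuation experiments.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    df = _draw_parameters(config)
    sub = df[df["exposed"]]
    m = len(sub)
    if m == 0:
        raise ValueError("no exposed cases to calibrate against")
    ir = sub["ir_mU_min"].to_numpy()
    vol = sub["blood_volume_ml"].to_numpy()
    hl = sub["half_life_min"].to_numpy()
    n_cyc = sub["duration_min"].to_numpy()

    r = np.exp(-math.log(2.0) / hl)
    steady = (ir * PG_PER_MILLIUNIT / vol) * r / (1.0 - r)

    def expo(L):
        return constant_infusion_exposure(ir, vol, hl, L, n_cyc)

    # critical limit per case: exposure(L*) = D; -inf where never crossing
    lo = np.zeros(m)
    hi = steady.copy()
    never = expo(np.zeros(m)) < config.D_pg_min_per_ml
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        high_side = expo(mid) >= config.D_pg_min_per_ml
        lo = np.where(high_side, mid, lo)
        hi = np.where(high_side, hi, mid)
    crit = np.where(never, -np.inf, lo)

    k = int(round(fraction * m))
    order = np.sort(crit)[::-1]
    if k == 0:
        return float(np.max(steady) + 1.0)
    attainable = int(np.sum(np.isfinite(order)))
    if k > attainable:
        raise ValueError(
            f"crossing fraction {fraction} unattainable: only {attainable}/{m} "
            "exposed cases can reach D even at L = 0"
        )
    if k == m:
        return 0.0
    # midpoint between the k-th and (k+1)-th largest critical limits
    upper, lower = order[k - 1], order[k]
    if not np.isfinite(lower):
        return float(max(upper - tol * max(upper, 1.0), 0.0))
    return float(0.5 * (upper + lower))


# ---------------------------------------------------------------------------
# association analysis


def expected_relative_risk(crossing_fraction: float, p0: float, p1: float) -> float:
    """Closed-form mixture RR: 1 + f * (p1/p0 - 1)."""
    if p0 <= 0:
        raise ValueError("p0 must be positive for a finite relative risk")
    return 1.0 + crossing_fraction * (p1 / p0 - 1.0)


@dataclass(frozen=True)
class StratumResult:
    relative_risk: float
    ci95: tuple[float, float]
    n_index: int
    n_events_index: int


@dataclass(frozen=True)
class AssociationResult:
    """2x2 exposure-outcome analysis of one cohort.

    ``contingency_2x2`` rows are (exposed, unexposed), columns are
    (outcome, no outcome).  CIs are log-scale normal approximations;
    if any cell is zero all cells get a 0.5 continuity correction and
    ``continuity_corrected`` is flagged.
    """

    contingency_2x2: np.ndarray
    relative_risk: float
    rr_ci95: tuple[float, float]
    odds_ratio: float
    or_ci95: tuple[float, float]
    log_rr_se: float
    above_threshold_fraction: float
    continuity_corrected: bool
    crossed_stratum: StratumResult | None = None
    uncrossed_stratum: StratumResult | None = None

    def to_dict(self) -> dict:
        def strat(s):
            if s is None:
                return None
            return {
                "relative_risk": s.relative_risk,
                "ci95": list(s.ci95),
                "n_index": s.n_index,
                "n_events_index": s.n_events_index,
            }

        return {
            "contingency_2x2": self.contingency_2x2.tolist(),
            "relative_risk": self.relative_risk,
            "rr_ci95": list(self.rr_ci95),
            "odds_ratio": self.odds_ratio,
            "or_ci95": list(self.or_ci95),
            "log_rr_se": self.log_rr_se,
            "above_threshold_fraction": self.above_threshold_fraction,
            "continuity_corrected": self.continuity_corrected,
            "crossed_stratum": strat(self.crossed_stratum),
            "uncrossed_stratum": strat(self.uncrossed_stratum),
        }


def _table_measures(table: np.ndarray):
    corrected = bool((table == 0).any())
    t = table.astype(float) + (0.5 if corrected else 0.0)
    t22 = Table2x2(t)
    return (
        float(t22.riskratio),
        tuple(map(float, t22.riskratio_confint(0.05))),
        float(t22.oddsratio),
        tuple(map(float, t22.oddsratio_confint(0.05))),
        float(t22.log_riskratio_se),
        corrected,
    )


def association_from_counts(
    a: int, b: int, c: int, d: int, *, above_threshold_fraction: float = float("nan")
) -> AssociationResult:
    """Association measures from a 2x2 table (a,b exposed; c,d unexposed)."""
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if a + b == 0 or c + d == 0:
        raise ValueError("need at least one exposed and one unexposed case")
    table = np.array([[a, b], [c, d]], dtype=int)
    rr, rr_ci, orat, or_ci, se, corrected = _table_measures(table)
    return AssociationResult(
        contingency_2x2=table,
        relative_risk=rr,
        rr_ci95=rr_ci,
        odds_ratio=orat,
        or_ci95=or_ci,
        log_rr_se=se,
        above_threshold_fraction=above_threshold_fraction,
        continuity_corrected=corrected,
    )


def _stratum(index: pd.DataFrame, reference: pd.DataFrame) -> StratumResult | None:
    if len(index) == 0:
        return None
    a = int(index["outcome"].sum())
    b = len(index) - a
    c = int(reference["outcome"].sum())
    d = len(reference) - c
    rr, rr_ci, *_ = _table_measures(np.array([[a, b], [c, d]]))
    return StratumResult(
        relative_risk=rr, ci95=rr_ci, n_index=len(index), n_events_index=a
    )


def association(cohort: LaborCohort) -> AssociationResult:
    """Exposure-outcome association for a cohort, with crossing strata.

    The headline measure is the relative risk (cohort sampling); the odds
    ratio is reported alongside for comparability.  Stratified relative
    risks are computed for the crossed and uncrossed exposed strata, each
    against the unexposed group.
    """
    df = cohort.frame
    exposed = df[df["exposed"]]
    unexposed = df[~df["exposed"]]
    if len(exposed) == 0 or len(unexposed) == 0:
        raise ValueError("need at least one exposed and one unexposed case")
    a = int(exposed["outcome"].sum())
    b = len(exposed) - a
    c = int(unexposed["outcome"].sum())
    d = len(unexposed) - c
    base = association_from_counts(
        a, b, c, d, above_threshold_fraction=cohort.crossing_fraction
    )
    return replace(
        base,
        crossed_stratum=_stratum(exposed[exposed["threshold_crossed"]], unexposed),
        uncrossed_stratum=_stratum(
            exposed[~exposed["threshold_crossed"]], unexposed
        ),
    )


# ---------------------------------------------------------------------------
# I/O


def write_cases_csv(cohort: LaborCohort, path) -> None:
    cohort.frame.to_csv(path, index=False, float_format="%.6f")


def write_association_json(
    result: AssociationResult, path, metadata: dict | None = None
) -> None:
    out = result.to_dict()
    if metadata:
        out["metadata"] = dict(metadata)
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1, default=float)
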