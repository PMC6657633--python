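"""Regeneration of the model's reference tables and figure datasets.

Canonical outputs are tabular (pandas DataFrames written as CSV/JSON);
figures are rendered *from* those tables so nothing downstream depends on
graphics.  ``rounded=True`` (the default here) reproduces the reference
arithmetic, which uses blood volumes rounded to two significant figures
(160 lb -> 4.7e3 ml, 128 lb -> 3.8e3 ml) and prints M to two decimals and
k to whole pg/ml.

The reference 128-lb k column was historically derived by scaling the
rounded 160-lb column by the volume ratio 1.25 and re-rounding, which
drifts up to 3 pg/ml from direct computation at the highest rates.  Direct
recomputation is canonical; ``make_table2(scaled_from_reference=True)``
regenerates the scaled variant for comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import pk_core
from .desensitization import DesensitizationModel, threshold_curve
from .pk_core import CycleParams, MaternalProfile
from .schedule import constant_schedule, simulate

__all__ = [
    "TableSpec",
    "make_table1",
    "make_table2",
    "make_fig1_data",
    "make_fig2_data",
    "make_fig3_data",
    "make_fig4_data",
    "write_table_csv",
    "write_table_json",
]


@dataclass(frozen=True)
class TableSpec:
    """Grids over which the reference tables/figures are evaluated."""

    half_life_grid_min: tuple = (1, 2, 3, 4, 5, 6)
    ir_grid_mU_min: tuple = (10, 20, 30, 40, 50)
    weights_lb: tuple = (160, 128)
    cycle_min: float = 1.0

    def __post_init__(self) -> None:
        for name in ("half_life_grid_min", "ir_grid_mU_min", "weights_lb"):
            grid = getattr(self, name)
            if len(grid) == 0 or any(x <= 0 for x in grid):
                raise ValueError(f"{name} must be non-empty and positive")


def _round_half_up(x: float) -> int:
    """Round to the nearest integer with ties away from zero (table convention)."""
    import math

    return int(math.floor(x + 0.5))


def _profile(weight_lb: float, half_life: float, rounded: bool) -> MaternalProfile:
    return MaternalProfile.from_weight(
        weight_lb=weight_lb, half_life_min=half_life, rounded_volume=rounded
    )


def make_table1(spec: TableSpec = TableSpec(), *, rounded: bool = True) -> pd.DataFrame:
    """Multiplier M per half-life (rounded to 2 decimals in rounded mode)."""
    rows = []
    for hl in spec.half_life_grid_min:
        r = pk_core.retention_fraction(hl, spec.cycle_min)
        m = pk_core.multiplier(r)
        rows.append({"half_life_min": hl, "M": round(m, 2) if rounded else m})
    return pd.DataFrame(rows)


def make_table2(
    spec: TableSpec = TableSpec(),
    *,
    rounded: bool = True,
    scaled_from_reference: bool = False,
) -> pd.DataFrame:
    """Per-cycle increment k (pg/ml) by infusion rate and maternal weight.

    Columns are ``k_<weight>lb``.  With ``scaled_from_reference=True`` the
    non-first weight columns are derived by scaling the rounded first
    column by the blood-volume ratio and re-rounding, matching the
    reference table's arithmetic instead of direct computation.
    """
    weights = spec.weights_lb
    volumes = {}
    for w in weights:
        p = _profile(w, 3.0, rounded)
        volumes[w] = p.blood_volume_ml
    rows = []
    for ir in spec.ir_grid_mU_min:
        row = {"ir_mU_min": ir}
        for j, w in enumerate(weights):
            k = pk_core.per_cycle_increment(ir, volumes[w], spec.cycle_min)
            if scaled_from_reference and j > 0:
                # reference arithmetic: scale the *rounded* first column by
                # the unrounded volume ratio (= weight ratio) and re-round
                k_ref = pk_core.per_cycle_increment(
                    ir, volumes[weights[0]], spec.cycle_min
                )
                k = _round_half_up(k_ref) * (weights[0] / w)
            row[f"k_{w}lb"] = _round_half_up(k) if rounded else k
        rows.append(row)
    return pd.DataFrame(rows)


def make_fig1_data(
    half_life_grid_min=None, cycle_min: float = 1.0
) -> pd.DataFrame:
    """Percent oxytocin removed / remaining per cycle vs half-life."""
    if half_life_grid_min is None:
        half_life_grid_min = np.linspace(1.0, 6.0, 51)
    rows = []
    for hl in np.asarray(half_life_grid_min, dtype=float):
        removed, remaining = pk_core.removal_retention_percent(hl, cycle_min)
        rows.append(
            {"half_life_min": hl, "pct_removed": removed, "pct_remaining": remaining}
        )
    return pd.DataFrame(rows)


def make_fig2_data(
    ir_mU_min: float = 20.0,
    half_life_min: float = 3.0,
    weight_lb: float = 160.0,
    duration_min: float = 60.0,
    *,
    rounded: bool = True,
) -> pd.DataFrame:
    """Minute-by-minute buildup toward the asymptote M*k.

    Defaults are the worked example: 20 mU/min, 3-min half-life, 160-lb
    woman.  The series is produced by :func:`pitosim.schedule.simulate`
    (single code path with the simulator).
    """
    profile = _profile(weight_lb, half_life_min, rounded)
    series = simulate(constant_schedule(ir_mU_min, duration_min), profile)
    df = series.to_frame()
    df["steady_state_pg_ml"] = series.steady_state_pg_ml
    return df


def make_fig3_data(
    spec: TableSpec = TableSpec(), *, rounded: bool = True
) -> pd.DataFrame:
    """Steady-state concentration C = M*k over (weight, IR, half-life).

    For fixed IR and weight, C is exactly linear in M; both the half-life
    and M columns are emitted so either abscissa can be plotted.
    """
    rows = []
    for w in spec.weights_lb:
        for ir in spec.ir_grid_mU_min:
            for hl in spec.half_life_grid_min:
                kc = pk_core.kinetic_constants(
                    ir, _profile(w, hl, rounded), CycleParams(spec.cycle_min)
                )
                rows.append(
                    {
                        "weight_lb": w,
                        "ir_mU_min": ir,
                        "half_life_min": hl,
                        "M": kc.multiplier_M,
                        "k_pg_ml": kc.increment_k_pg_ml,
                        "C_pg_ml": kc.steady_state_C_pg_ml,
                    }
                )
    return pd.DataFrame(rows)


#: Labor-duration verticals marked on the threshold figure (hours 6/12/24/48).
FIG4_MARKED_TIMES_MIN = (360.0, 720.0, 1440.0, 2880.0)


def make_fig4_data(
    time_grid_min=None,
    *,
    D_pg_min_per_ml: float = 1.8e6,
    fifty_pct_time_factor: float = 1.4,
) -> pd.DataFrame:
    """Desensitization threshold and 50%-level hyperbolas vs exposure time."""
    if time_grid_min is None:
        time_grid_min = np.unique(
            np.concatenate(
                [np.linspace(60.0, 2880.0, 142), np.asarray(FIG4_MARKED_TIMES_MIN)]
            )
        )
    model = DesensitizationModel(
        oxytocinase_limit_pg_ml=0.0,
        D_pg_min_per_ml=D_pg_min_per_ml,
        fifty_pct_time_factor=fifty_pct_time_factor,
    )
    t = np.asarray(time_grid_min, dtype=float)
    threshold, fifty = threshold_curve(t, model)
    return pd.DataFrame(
        {
            "time_min": t,
            "threshold_pg_ml": threshold,
            "fifty_pct_pg_ml": fifty,
            "marked": np.isin(t, FIG4_MARKED_TIMES_MIN),
        }
    )


def write_table_csv(df: pd.DataFrame, path, float_format: str = "%.6f") -> None:
    """Deterministic CSV: fixed column order and decimal formatting."""
    df.to_csv(path, index=False, float_format=float_format)


def write_table_json(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        json.dump(df.to_dict(orient="records"), fh, indent=1, default=float)


def plot_figures(outdir, spec: TableSpec = TableSpec()) -> list:
    """Render PNGs of the four figure datasets into ``outdir`` (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots()
    d1 = make_fig1_data()
    ax.plot(d1.half_life_min, d1.pct_removed, label="% removed per cycle")
    ax.plot(d1.half_life_min, d1.pct_remaining, label="% remaining per cycle")
    ax.set_xlabel("oxytocin half-life (min)")
    ax.set_ylabel("percent")
    ax.legend()
    fig.savefig(outdir / "fig1_removal_retention.png", dpi=120)
    plt.close(fig)
    written.append(outdir / "fig1_removal_retention.png")

    fig, ax = plt.subplots()
    d2 = make_fig2_data()
    ax.plot(d2.time_min, d2.conc_pg_ml, label="baseline concentration")
    ax.axhline(d2.steady_state_pg_ml.iloc[0], ls="--", c="gray", label="M·k")
    ax.set_xlabel("infusion time (min)")
    ax.set_ylabel("concentration (pg/ml)")
    ax.legend()
    fig.savefig(outdir / "fig2_buildup.png", dpi=120)
    plt.close(fig)
    written.append(outdir / "fig2_buildup.png")

    d3 = make_fig3_data(spec)
    fig, axes = plt.subplots(1, len(spec.weights_lb), sharey=True, figsize=(9, 4))
    axes = np.atleast_1d(axes)
    for ax, w in zip(axes, spec.weights_lb):
        sub = d3[d3.weight_lb == w]
        for ir, grp in sub.groupby("ir_mU_min"):
            ax.plot(grp.half_life_min, grp.C_pg_ml, marker="o", label=f"{ir} mU/min")
        ax.set_title(f"{w} lb")
        ax.set_xlabel("half-life (min)")
    axes[0].set_ylabel("steady-state C (pg/ml)")
    axes[-1].legend(fontsize=7)
    fig.savefig(outdir / "fig3_steady_state.png", dpi=120)
    plt.close(fig)
    written.append(outdir / "fig3_steady_state.png")

    fig, ax = plt.subplots()
    d4 = make_fig4_data()
    ax.plot(d4.time_min / 60, d4.threshold_pg_ml, label="desensitization threshold")
    ax.plot(d4.time_min / 60, d4.fifty_pct_pg_ml, label="50% level")
    for t in FIG4_MARKED_TIMES_MIN:
        ax.axvline(t / 60, ls=":", c="gray")
    ax.set_xlabel("continuous infusion time (h)")
    ax.set_ylabel("override concentration (pg/ml)")
    ax.set_yscale("log")
    ax.legend()
    fig.savefig(outdir / "fig4_threshold.png", dpi=120)
    plt.close(fig)
    written.append(outdir / "fig4_threshold.png")
    return written
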