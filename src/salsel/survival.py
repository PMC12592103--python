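"""Interval-mortality trajectories and control-vs-treatment K-S comparisons.

Interval mortality per census is (deaths during the interval / number alive
at the start of the interval) x 100.  Mortality distributions are compared
with the two-sided two-sample Kolmogorov-Smirnov test, exact for small
samples (n*m <= 10000) and asymptotic otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

logger = logging.getLogger(__name__)


def validate_mortality_table(table: pd.DataFrame) -> None:
    """Check census-table invariants; raises ``ValueError`` on violation."""
    if (table["deaths"] < 0).any() or (table["alive_at_start"] < 0).any():
        raise ValueError("negative counts in mortality table")
    for tank, sub in table.groupby("tank"):
        sub = sub.sort_values("census_hour")
        if sub["census_hour"].duplicated().any():
            raise ValueError(f"duplicate census hours for tank {tank}")
        if (sub["deaths"] > sub["alive_at_start"]).any():
            raise ValueError(f"deaths exceed alive_at_start in tank {tank}")
        alive = sub["alive_at_start"].to_numpy()
        if (np.diff(alive) > 0).any():
            raise ValueError(f"alive_at_start increases over time in tank {tank}")


def interval_mortality(table: pd.DataFrame) -> pd.DataFrame:
    """Per-tank interval and cumulative mortality (percent per census).

    Censuses with nobody alive at the start yield NaN interval mortality
    (defined missing, not an error).  Cumulative mortality is relative to
    the tank's initial count.
    """
    validate_mortality_table(table)
    out = []
    for tank, sub in table.groupby("tank"):
        sub = sub.sort_values("census_hour").reset_index(drop=True)
        alive = sub["alive_at_start"].to_numpy(dtype=float)
        deaths = sub["deaths"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            interval = np.where(alive > 0, 100.0 * deaths / np.where(alive > 0, alive, 1), np.nan)
        initial = alive[0] if len(alive) else 0.0
        cumulative = (
            100.0 * np.cumsum(deaths) / initial if initial > 0 else np.full_like(deaths, np.nan)
        )
        out.append(
            pd.DataFrame(
                {
                    "tank": tank,
                    "census_hour": sub["census_hour"],
                    "interval_mortality": interval,
                    "cumulative_mortality": cumulative,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sided two-sample K-S statistic and p.

    Exact small-sample p when n*m <= 10000, asymptotic otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("K-S test requires non-empty samples")
    method = "exact" if len(x) * len(y) <= 10_000 else "asymp"
    res = ks_2samp(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class MortalityComparison:
    comparison: str
    n_control: int
    n_treatment: int
    d: float
    p: float


def compare_mortality(
    series: pd.DataFrame,
    control_tank: str,
    treatment_tanks: list[str],
) -> pd.DataFrame:
    """K-S tests of control interval mortality against treatments.

    Reports the pooled comparison (all treatment tanks' interval values as
    one sample) and one comparison per replicate.  All tanks must share the
    census grid; tanks whose interval series is entirely missing are skipped
    with a warning.
    """
    grids = {
        tank: tuple(sub.sort_values("census_hour")["census_hour"])
        for tank, sub in series.groupby("tank")
    }
    control_grid = grids[control_tank]
    for tank in treatment_tanks:
        if grids[tank] != control_grid:
            raise ValueError(f"census grid of {tank} differs from control")

    def values(tank: str) -> np.ndarray:
        v = series.loc[series["tank"] == tank, "interval_mortality"].to_numpy(float)
        return v[~np.isnan(v)]

    control = values(control_tank)
    rows: list[MortalityComparison] = []
    pooled_parts = []
    for tank in treatment_tanks:
        v = values(tank)
        if len(v) == 0:
            logger.warning("treatment tank %s has no usable censuses; skipped", tank)
            continue
        pooled_parts.append(v)
        d, p = ks_two_sample(control, v)
        rows.append(MortalityComparison(f"{control_tank}_vs_{tank}", len(control), len(v), d, p))
    if pooled_parts:
        pooled = np.concatenate(pooled_parts)
        d, p = ks_two_sample(control, pooled)
        rows.insert(
            0,
            MortalityComparison(f"{control_tank}_vs_pooled", len(control), len(pooled), d, p),
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def plot_mortality(series: pd.DataFrame, path) -> None:
    """Interval-mortality curves per tank (optional figure output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for tank, sub in series.groupby("tank"):
        sub = sub.sort_values("census_hour")
        ax.plot(sub["census_hour"], sub["interval_mortality"], marker="o", label=str(tank))
    ax.set_xlabel("hours since exposure start")
    ax.set_ylabel("interval mortality (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
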