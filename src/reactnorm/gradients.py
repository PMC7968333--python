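"""Heat-load environmental gradients from hourly weather.

The exposure of a heifer to heat stress is summarised over a *critical
period* — a window of days anchored on her first-service day — using the
temperature-humidity index (THI) computed from hourly dry-bulb and
dew-point temperatures:

    THI = Tdb + 0.36 * Tdp + 41.2        (temperatures in deg C)

Two gradients are supported:

``prop``
    Proportion of heat-stress days in the window, where a heat-stress day
    has hourly THI above a threshold (default 72) for at least six
    *continuous* hours.  Ranges over [0, 1].
``mthi``
    Mean of the daily minimum hourly THI over the window, clipped to
    [15, 75] (the plotted gradient axis).  A measure of the thermal floor:
    high values mean no overnight relief from heat.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

THI_THRESHOLD = 72.0
MIN_RUN_HOURS = 6
MTHI_CLIP = (15.0, 75.0)
#: minimum hourly records for a day to be usable
MIN_HOURS_PER_DAY = 18


def hourly_thi(tdb_c, tdp_c):
    """Temperature-humidity index from dry-bulb and dew-point temperature (deg C)."""
    tdb = np.asarray(tdb_c, dtype=float)
    tdp = np.asarray(tdp_c, dtype=float)
    if not (np.all(np.isfinite(tdb)) and np.all(np.isfinite(tdp))):
        raise ValueError("non-finite temperature input")
    out = tdb + 0.36 * tdp + 41.2
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class EGSpec:
    """Definition of an environmental gradient.

    Parameters
    ----------
    kind : {"prop", "mthi"}
    window : (int, int)
        Inclusive day offsets relative to the first-service day; negative
        means before, day 0 is the first-service day itself.
    """

    kind: str
    window: tuple[int, int] = (-30, 30)
    thi_threshold: float = THI_THRESHOLD
    min_run_hours: int = MIN_RUN_HOURS
    mthi_clip: tuple[float, float] = MTHI_CLIP

    def __post_init__(self):
        if self.kind not in ("prop", "mthi"):
            raise ValueError(f"unknown gradient kind {self.kind!r}")
        if self.window[0] >= self.window[1]:
            raise ValueError("window start must precede window end")

    @property
    def length(self) -> int:
        """Window length in days (inclusive endpoints)."""
        return self.window[1] - self.window[0] + 1


def _max_hot_run(hours: np.ndarray, hot: np.ndarray) -> int:
    """Longest run of consecutive-hour records with ``hot`` true.

    A missing hour (gap in ``hours``) breaks the run.
    """
    best = run = 0
    prev_hour = None
    for h, flag in zip(hours, hot):
        if flag and prev_hour is not None and h == prev_hour + 1 and run > 0:
            run += 1
        elif flag:
            run = 1
        else:
            run = 0
        best = max(best, run)
        prev_hour = h
    return best


def daily_summaries(
    weather: pd.DataFrame,
    thi_threshold: float = THI_THRESHOLD,
    min_run_hours: int = MIN_RUN_HOURS,
    min_hours: int = MIN_HOURS_PER_DAY,
) -> pd.DataFrame:
    """Collapse hourly weather to daily THI summaries and heat-day flags.

    Parameters
    ----------
    weather : DataFrame
        Columns ``time`` (datetime-like, hourly), ``tdb_c``, ``tdp_c``.

    Returns
    -------
    DataFrame indexed by date with columns ``thi_mean``, ``thi_min``,
    ``n_hours``, ``heat_day`` and ``usable``.  Days with fewer than
    ``min_hours`` records are flagged unusable; a missing hour breaks a
    heat run (conservative).
    """
    if len(weather) == 0:
        raise ValueError("empty weather table")
    t = pd.to_datetime(weather["time"])
    thi = hourly_thi(weather["tdb_c"].to_numpy(), weather["tdp_c"].to_numpy())
    df = pd.DataFrame(
        {"date": t.dt.normalize().to_numpy(), "hour": t.dt.hour.to_numpy(), "thi": thi}
    ).sort_values(["date", "hour"])

    rows = []
    for date, grp in df.groupby("date", sort=True):
        hours = grp["hour"].to_numpy()
        vals = grp["thi"].to_numpy()
        run = _max_hot_run(hours, vals > thi_threshold)
        rows.append(
            {
                "date": date,
                "thi_mean": vals.mean(),
                "thi_min": vals.min(),
                "n_hours": len(vals),
                "heat_day": run >= min_run_hours,
                "usable": len(vals) >= min_hours,
            }
        )
    out = pd.DataFrame(rows).set_index("date")
    return out


def eg_value(spec: EGSpec, daily: pd.DataFrame, first_service) -> float:
    """Gradient value for a single first-service date. See :func:`eg_values`."""
    return float(eg_values(spec, daily, [first_service])[0])


def eg_values(spec: EGSpec, daily: pd.DataFrame, first_service_dates) -> np.ndarray:
    """Per-animal gradient values for a vector of first-service dates.

    Raises
    ------
    ValueError
        If any animal's window is not fully covered by usable weather days.
    """
    dates = pd.to_datetime(pd.Series(first_service_dates)).dt.normalize()
    idx = pd.to_datetime(daily.index)
    day0 = idx.min()
    ord_idx = ((idx - day0).days).to_numpy()
    n_days = int(ord_idx.max()) + 1

    usable = np.zeros(n_days, dtype=bool)
    heat = np.zeros(n_days, dtype=float)
    tmin = np.full(n_days, np.nan)
    usable[ord_idx] = daily["usable"].to_numpy()
    heat[ord_idx] = daily["heat_day"].to_numpy().astype(float)
    tmin[ord_idx] = daily["thi_min"].to_numpy()

    # prefix sums for O(1) window aggregation
    cum_heat = np.concatenate([[0.0], np.cumsum(np.where(usable, heat, 0.0))])
    cum_ok = np.concatenate([[0], np.cumsum(usable.astype(int))])
    cum_tmin = np.concatenate([[0.0], np.cumsum(np.where(usable, np.nan_to_num(tmin), 0.0))])

    start = (dates - day0).dt.days.to_numpy() + spec.window[0]
    stop = (dates - day0).dt.days.to_numpy() + spec.window[1]  # inclusive
    if start.min() < 0 or stop.max() >= n_days:
        raise ValueError("critical-period window extends outside weather coverage")
    n_ok = cum_ok[stop + 1] - cum_ok[start]
    if np.any(n_ok < spec.length):
        raise ValueError(
            "critical-period window contains missing or unusable weather days"
        )
    if spec.kind == "prop":
        return (cum_heat[stop + 1] - cum_heat[start]) / spec.length
    mthi = (cum_tmin[stop + 1] - cum_tmin[start]) / spec.length
    return np.clip(mthi, *spec.mthi_clip)


DEFAULT_WINDOW_STARTS = (-90, -60, -30, -10, 0)
DEFAULT_WINDOW_LENGTHS = (30, 40, 60, 70)
MAX_WINDOW_END = 60


def candidate_windows(
    starts: Sequence[int] = DEFAULT_WINDOW_STARTS,
    lengths: Sequence[int] = DEFAULT_WINDOW_LENGTHS,
    max_end: int = MAX_WINDOW_END,
) -> list[tuple[int, int]]:
    """Default grid of candidate critical-period windows.

    Cartesian product of start offsets and window lengths, keeping windows
    that end no later than ``max_end`` days after first service.  The
    default grid has 19 windows, spans lengths 30-70 days, and includes
    the reference window (-30, 30) together with the windows selected by
    the AIC scan in the source population: (-90, -30), (-90, -60),
    (-10, 30) and (-10, 60).  Fully configurable.
    """
    out = []
    for s in starts:
        for length in lengths:
            e = s + length
            if e <= max_end:
                out.append((s, e))
    return out


def aic(logl: float, k: int) -> float:
    """Akaike information criterion, ``-2 logL + 2 k``.

    ``k`` counts estimated (co)variance parameters only (REML convention):
    4 for a reaction norm model, 2 for a plain animal model.
    """
    return -2.0 * logl + 2.0 * k


def scan_critical_period(
    kind: str,
    windows: Iterable[tuple[int, int]],
    daily: pd.DataFrame,
    first_service_dates,
    fitter: Callable[[np.ndarray], object],
    spec_template: EGSpec | None = None,
) -> pd.DataFrame:
    """Fit a reaction norm model per candidate window and rank by AIC.

    ``fitter`` receives the per-record gradient values for one window and
    must return an object with an ``aic`` attribute (a fitted-model
    results instance).  Fit failures are recorded (``aic`` NaN), not
    raised, so one bad window does not abort the scan.

    Returns a DataFrame sorted ascending by AIC with columns
    ``start``, ``end``, ``aic``, ``converged``, ``error``.
    """
    template = spec_template or EGSpec(kind=kind, window=(-30, 30))
    rows = []
    for (s, e) in windows:
        spec = replace(template, kind=kind, window=(s, e))
        try:
            x = eg_values(spec, daily, first_service_dates)
            res = fitter(x)
            rows.append({"start": s, "end": e, "aic": res.aic, "converged": True, "error": ""})
        except Exception as exc:  # non-convergence is data, not a crash
            rows.append({"start": s, "end": e, "aic": np.nan, "converged": False, "error": str(exc)})
    out = pd.DataFrame(rows).sort_values("aic", na_position="last").reset_index(drop=True)
    return out
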