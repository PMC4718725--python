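"""Engineering of environmental/developmental (ED) parameters from weather,
soil-moisture and phenology inputs.

The parameter grid covers, for each sampling time: trailing linear averages
(L) of the six climatic factors over windows from 15 min to 15 d;
exponentially transformed short-term solar-radiation averages (NL+ / NL-);
recent changes (delta) over 20 min / 1 h / 2 h for the most dynamic factors;
temperature-fluctuation averages (eps) of the remainder of a seasonal
decomposition of the daily cycle; soil moisture at 15 and 30 cm; a binary
field indicator; and a piecewise-linear developmental-stage index anchored
at transplanting (0), end of tillering (40) and heading (100).

All windows are trailing and closed at both ends on the uniform weather
grid.  Near-duplicate parameters (|r| above a merge threshold) are averaged
after sign alignment; every parameter is finally centered per
genotype x season and scaled to unit standard deviation over the whole
design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import FIELDS, SoilMoistureSeries, WeatherSeries

#: Table of linear-average windows (label -> duration).
L_WINDOWS = {
    "15min": pd.Timedelta(minutes=15),
    "1hr": pd.Timedelta(hours=1),
    "4hr": pd.Timedelta(hours=4),
    "24hr": pd.Timedelta(hours=24),
    "3d": pd.Timedelta(days=3),
    "6d": pd.Timedelta(days=6),
    "10d": pd.Timedelta(days=10),
    "15d": pd.Timedelta(days=15),
}
#: Short-term solar windows that get the nonlinear transforms.
NL_WINDOWS = ("15min", "1hr", "4hr")
#: Recent-change lags and the base averaging window used for each.
DELTA_LAGS = {
    "20min": (pd.Timedelta(minutes=20), pd.Timedelta(minutes=5)),
    "1hr": (pd.Timedelta(hours=1), pd.Timedelta(minutes=10)),
    "2hr": (pd.Timedelta(hours=2), pd.Timedelta(minutes=30)),
}
DELTA_FACTORS = ("tp", "hu", "so", "wd")
#: Fluctuation (remainder-average) windows, temperature only.
EPS_WINDOWS = {
    "1hr": pd.Timedelta(hours=1),
    "4hr": pd.Timedelta(hours=4),
    "24hr": pd.Timedelta(hours=24),
}
CLIMATE_FACTORS = ("tp", "hu", "so", "wd", "ps", "ra")


def nl_transform(x, direction: str):
    """Exponential transform of a short-term solar-radiation average (W/m2):
    NL+(x) = exp((x-400)/200) amplifies high irradiance, NL-(x) =
    exp((400-x)/200) amplifies low irradiance; NL+(x) * NL-(x) = 1."""
    x = np.asarray(x, dtype=float)
    if direction == "+":
        return np.exp((x - 400.0) / 200.0)
    if direction == "-":
        return np.exp((400.0 - x) / 200.0)
    raise ValueError(f"direction must be '+' or '-', got {direction!r}")


def _trailing_mean(values: np.ndarray, index: pd.DatetimeIndex,
                   t_end: pd.Timestamp, window: pd.Timedelta) -> float:
    t_start = t_end - window
    if t_start < index[0] or t_end > index[-1]:
        raise ValueError(
            f"window [{t_start}, {t_end}] extends outside the series")
    i0 = index.searchsorted(t_start, side="left")
    i1 = index.searchsorted(t_end, side="right")
    return float(values[i0:i1].mean())


def window_average(weather: WeatherSeries, factor: str, window: pd.Timedelta,
                   t_sample: pd.Timestamp) -> float:
    """Mean of a climatic factor over the closed trailing window
    [t_sample - window, t_sample]."""
    season = weather.season_of(t_sample)
    frame = weather.frames[season]
    return _trailing_mean(frame[factor].to_numpy(), frame.index,
                          t_sample, window)


def recent_change(weather: WeatherSeries, factor: str, lag_label: str,
                  t_sample: pd.Timestamp) -> float:
    """Recent change (delta): short trailing average at the sampling time
    minus the same average one lag earlier."""
    lag, base = DELTA_LAGS[lag_label]
    now = window_average(weather, factor, base, t_sample)
    before = window_average(weather, factor, base, t_sample - lag)
    return now - before


def seasonal_remainder(series: pd.Series, period: int) -> pd.Series:
    """Remainder after decomposing a uniformly sampled series into a daily
    periodic component plus trend.

    Uses the classical moving-average decomposition (centered one-period
    trend filter, periodic means for the daily cycle, trend extrapolated
    linearly at the edges); on a noiseless sinusoid plus linear trend the
    remainder vanishes identically.
    """
    if len(series) < 2 * period:
        raise ValueError("series shorter than two periods")
    from statsmodels.tsa.seasonal import seasonal_decompose
    res = seasonal_decompose(series.to_numpy(), period=period,
                             model="additive", extrapolate_trend="freq")
    return pd.Series(res.resid, index=series.index)


def fluctuation_residual(weather: WeatherSeries, window_label: str,
                         t_sample: pd.Timestamp, factor: str = "tp",
                         remainder: pd.Series | None = None) -> float:
    """Fluctuation (eps): trailing-window mean of the seasonal-decomposition
    remainder of the factor, ending at the sampling time."""
    season = weather.season_of(t_sample)
    if remainder is None:
        frame = weather.frames[season]
        period = int(round(24 * 60 / weather.resolution_min))
        remainder = seasonal_remainder(frame[factor], period)
    return _trailing_mean(remainder.to_numpy(), remainder.index,
                          t_sample, EPS_WINDOWS[window_label])


# ---------------------------------------------------------------------------
# Developmental stage
# ---------------------------------------------------------------------------

@dataclass
class DevAnchors:
    """Phenology anchors per (season, field): transplanting stage (0),
    end of tillering production (40), heading (100)."""

    anchors: Mapping[tuple[str, str], tuple[pd.Timestamp, ...]]

    def __post_init__(self) -> None:
        fixed = {}
        for key, dates in self.anchors.items():
            dates = tuple(pd.Timestamp(d) for d in dates)
            if len(dates) != 3 or not (dates[0] < dates[1] < dates[2]):
                raise ValueError(
                    f"anchors for {key} must be 3 strictly increasing dates")
            fixed[key] = dates
        self.anchors = fixed

    @classmethod
    def default_synthetic(cls) -> "DevAnchors":
        base = {
            ("dry", "irrigated"): ("2013-01-01", "2013-02-03", "2013-03-10"),
            ("dry", "rainfed"): ("2013-01-03", "2013-02-06", "2013-03-14"),
            ("wet", "irrigated"): ("2013-06-23", "2013-08-03", "2013-09-10"),
            ("wet", "rainfed"): ("2013-06-26", "2013-08-06", "2013-09-14"),
        }
        return cls(anchors=base)


STAGE_VALUES = (0.0, 40.0, 100.0)


def dev_stage(anchors: DevAnchors, season: str, field: str,
              t_sample: pd.Timestamp) -> float:
    """Developmental-stage index: piecewise-linear through the anchors."""
    dates = anchors.anchors[(season, field)]
    t = pd.Timestamp(t_sample)
    if t < dates[0]:
        raise ValueError(f"{t} precedes the transplanting anchor {dates[0]}")
    xs = np.array([d.value for d in dates], dtype=float)
    return float(np.interp(t.value, xs, np.array(STAGE_VALUES)))


def field_indicator(field: str) -> int:
    """Binary field parameter: 0 irrigated, 1 rainfed."""
    if field not in FIELDS:
        raise ValueError(f"unknown field label {field!r}")
    return 0 if field == "irrigated" else 1


def soil_moisture_params(sm: SoilMoistureSeries,
                         t_sample: pd.Timestamp) -> tuple[float, float]:
    """Soil moisture (relative saturation) at 15 and 30 cm at, or nearest
    before, the sampling time."""
    for frame in sm.frames.values():
        if frame.index[0] <= t_sample <= frame.index[-1]:
            i = frame.index.searchsorted(t_sample, side="right") - 1
            row = frame.iloc[i]
            return float(row["sm15"]), float(row["sm30"])
    raise ValueError(f"{t_sample} not covered by the soil series")


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass
class EDParameterMatrix:
    """Finalized parameters x design columns, with per-parameter metadata
    (factor, transform, window) and the merge map applied during
    finalization."""

    values: pd.DataFrame
    param_meta: pd.DataFrame
    design_meta: pd.DataFrame
    merge_map: Mapping[str, str]


def build_raw_parameters(weather: WeatherSeries,
                         soil: Mapping[str, SoilMoistureSeries],
                         anchors: DevAnchors,
                         design_meta: pd.DataFrame,
                         include_field: bool = True,
                         include_soil: bool = True,
                         extra_l_windows: Mapping[str, pd.Timedelta] | None = None,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute the raw (unmerged, unscaled) parameter grid over the design
    columns described by ``design_meta`` (columns: season, field, timepoint,
    timestamp; one row per design column)."""
    times = pd.to_datetime(design_meta["timestamp"])
    rows: dict[str, np.ndarray] = {}
    meta_rows = []

    l_windows = dict(L_WINDOWS)
    if extra_l_windows:
        l_windows.update(extra_l_windows)

    def add(pid, values, factor, transform, window):
        rows[pid] = np.asarray(values, dtype=float)
        meta_rows.append({"id": pid, "factor": factor,
                          "transform": transform, "window": window})

    for factor in CLIMATE_FACTORS:
        for label, window in l_windows.items():
            vals = [window_average(weather, factor, window, t) for t in times]
            add(f"{factor}_{label}", vals, factor, "L", label)
    for label in NL_WINDOWS:
        base = rows[f"so_{label}"]
        add(f"so_{label}_NL+", nl_transform(base, "+"), "so", "NL+", label)
        add(f"so_{label}_NL-", nl_transform(base, "-"), "so", "NL-", label)
    for factor in DELTA_FACTORS:
        for label in DELTA_LAGS:
            vals = [recent_change(weather, factor, label, t) for t in times]
            add(f"{factor}_delta{label}", vals, factor, "D", label)

    period = int(round(24 * 60 / weather.resolution_min))
    remainders = {s: seasonal_remainder(f["tp"], period)
                  for s, f in weather.frames.items()}
    for label in EPS_WINDOWS:
        vals = [fluctuation_residual(weather, label, t,
                                     remainder=remainders[weather.season_of(t)])
                for t in times]
        add(f"tp_eps{label}", vals, "tp", "R", label)

    if include_soil:
        sm_vals = np.array(
            [soil_moisture_params(soil[f], t)
             for f, t in zip(design_meta["field"], times)])
        add("sm15", sm_vals[:, 0], "sm15", "identity", "")
        add("sm30", sm_vals[:, 1], "sm30", "identity", "")
    if include_field:
        add("field", [field_indicator(f) for f in design_meta["field"]],
            "field", "identity", "")
    add("dev", [dev_stage(anchors, s, f, t) for s, f, t in
                zip(design_meta["season"], design_meta["field"], times)],
        "dev", "identity", "")

    values = pd.DataFrame(rows).T
    values.columns = design_meta.index
    return values, pd.DataFrame(meta_rows).set_index("id")


def merge_similar(values: pd.DataFrame, merge_r: float = 0.98,
                  on_constant: str = "error",
                  ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Average near-duplicate parameters: connected components of the
    |r| > merge_r graph, each replaced by the mean of its sign-aligned,
    unit-variance members.  Returns the reduced matrix and the map from
    original ids to merged ids.

    A parameter constant over the design carries no information and cannot
    be scaled; with ``on_constant="error"`` it raises, with ``"drop"`` it is
    removed and recorded in the merge map under the id ``"<dropped>"``.

    Averaging a component can create a profile that again exceeds the
    threshold against another row, so merging is iterated to a fixpoint.
    """
    merged, merge_map = _merge_once(values, merge_r, on_constant)
    while len(merged) > 1:
        corr = np.corrcoef(merged.to_numpy())
        np.fill_diagonal(corr, 0.0)
        if np.abs(corr).max() <= merge_r:
            break
        merged, next_map = _merge_once(merged, merge_r, on_constant)
        merge_map = {orig: next_map[mid] for orig, mid in merge_map.items()
                     if mid in next_map} | {
            orig: mid for orig, mid in merge_map.items()
            if mid not in next_map}
    return merged, merge_map


def _merge_once(values: pd.DataFrame, merge_r: float,
                on_constant: str) -> tuple[pd.DataFrame, dict[str, str]]:
    X = values.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    dropped: dict[str, str] = {}
    if (sd == 0).any():
        bad = values.index[sd == 0].tolist()
        if on_constant != "drop":
            raise ValueError(f"constant parameter rows: {bad}")
        dropped = {pid: "<dropped>" for pid in bad}
        values = values.loc[sd > 0]
        X = values.to_numpy(dtype=float)
        sd = sd[sd > 0]
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    corr = np.corrcoef(Z)
    adj = np.abs(corr) > merge_r
    # union-find over the |r| graph
    parent = list(range(len(values)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(values)):
        for j in range(i + 1, len(values)):
            if adj[i, j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[int]] = {}
    for i in range(len(values)):
        groups.setdefault(find(i), []).append(i)

    merged_rows, ids, merge_map = [], [], {}
    # scaled (unit-variance) members, sign-aligned to the first member
    Zs = X / sd[:, None]
    for root in sorted(groups):
        members = groups[root]
        first = members[0]
        signs = np.sign(corr[first, members])
        signs[signs == 0] = 1.0
        merged = (Zs[members] * signs[:, None]).mean(axis=0)
        if len(members) == 1:
            mid = values.index[first]
        else:
            mid = "+".join(values.index[m] for m in members)
        ids.append(mid)
        merged_rows.append(merged)
        for m in members:
            merge_map[values.index[m]] = mid
    merge_map.update(dropped)
    out = pd.DataFrame(np.vstack(merged_rows),
                       index=pd.Index(ids, name="parameter"),
                       columns=values.columns)
    return out, merge_map


def finalize(values: pd.DataFrame, design_meta: pd.DataFrame) -> pd.DataFrame:
    """Center every parameter per genotype x season block and scale to unit
    standard deviation over the whole design."""
    out = values.copy().astype(float)
    keys = ["season"]
    if "genotype" in design_meta.columns:
        keys = ["genotype", "season"]
    for _, subset in design_meta.groupby(keys, observed=True):
        block = out[subset.index]
        out[subset.index] = block.sub(block.mean(axis=1), axis=0)
    sd = out.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = out.index[sd == 0].tolist()
        raise ValueError(f"constant parameter rows after centering: {bad}")
    return out.div(sd, axis=0)


def assemble_and_finalize(weather: WeatherSeries,
                          soil: Mapping[str, SoilMoistureSeries],
                          anchors: DevAnchors,
                          design_meta: pd.DataFrame,
                          merge_r: float = 0.98,
                          include_field: bool = True,
                          include_soil: bool = True,
                          on_constant: str = "drop",
                          extra_l_windows=None) -> EDParameterMatrix:
    """Full parameter pipeline: raw grid, near-duplicate merging, centering
    and scaling.  Parameters constant over the sampled design (e.g. a rain
    window that never caught an event) are dropped by default and recorded
    in the merge map.

    Similarity for merging is measured on the finalized (per-block-centered,
    scaled) values — the scale every downstream correlation rule operates
    on — so the output matrix is guaranteed to respect the threshold.
    """
    raw, param_meta = build_raw_parameters(
        weather, soil, anchors, design_meta,
        include_field=include_field, include_soil=include_soil,
        extra_l_windows=extra_l_windows)
    sd0 = raw.std(axis=1, ddof=1)
    if on_constant == "drop":
        raw = raw.loc[sd0 > 0]
    pre = finalize(raw, design_meta)
    merged, merge_map = merge_similar(pre, merge_r=merge_r,
                                      on_constant=on_constant)
    merge_map.update({pid: "<dropped>" for pid in sd0.index[sd0 == 0]})
    final = finalize(merged, design_meta)
    kept_meta = []
    for mid in final.index:
        members = [k for k, v in merge_map.items() if v == mid]
        first = param_meta.loc[members[0]]
        kept_meta.append({"id": mid, "factor": first["factor"],
                          "transform": first["transform"],
                          "window": first["window"],
                          "n_members": len(members)})
    return EDParameterMatrix(values=final,
                             param_meta=pd.DataFrame(kept_meta).set_index("id"),
                             design_meta=design_meta,
                             merge_map=merge_map)
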