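"""Synthetic field-trial generator: weather, soil moisture, sampling schedules
and cluster-structured gene expression with known ground-truth linear models.

The generator emulates a two-season (dry / wet) rice field trial with an
irrigated and a rainfed field, two genotypes and two replicate sub-fields:
15 sampling timepoints per series, 48 h apart, taken 4 h after sunrise, for
240 samples in total.  Gene expression is generated so that, after the
standard preprocessing (log transform, replicate averaging, per-subset
centering, per-gene scaling), each cluster's mean profile is a noisy linear
combination of engineered environmental/developmental (ED) parameters —
optionally a different combination per season and/or field segment — which
downstream model selection is expected to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SEASONS = ("dry", "wet")
FIELDS = ("irrigated", "rainfed")

#: Default season spans: weather starts 15 days before the first sampling
#: so that every 15-day trailing window is covered.
_DEFAULT_SPANS = {
    "dry": ("2013-01-01 00:00", "2013-02-28 23:55"),
    "wet": ("2013-07-01 00:00", "2013-08-31 23:55"),
}
_DEFAULT_FIRST_SAMPLING = {"dry": "2013-01-16", "wet": "2013-07-16"}


class InvalidConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass
class WeatherConfig:
    """Configuration of the two-season weather simulator.

    Diurnal cycles are sinusoidal; day-to-day variation is AR(1) noise on a
    5-min grid; rain falls as discrete events drawn from a Poisson process
    with exponentially distributed magnitudes (accumulated mm per interval).
    """

    season_spans: Mapping[str, tuple[str, str]] = dc_field(
        default_factory=lambda: dict(_DEFAULT_SPANS))
    resolution_min: int = 5
    tp_mean: Mapping[str, float] = dc_field(
        default_factory=lambda: {"dry": 26.8, "wet": 27.6})
    tp_amplitude: float = 4.0          # half peak-to-trough, degC
    tp_trend: Mapping[str, float] = dc_field(
        default_factory=lambda: {"dry": 0.02, "wet": 0.0})  # degC / day
    diurnal_peak_hour: float = 14.0
    hu_base: float = 82.0              # percent RH
    hu_amplitude: float = 12.0
    so_max: float = 800.0              # clear-sky noon irradiance, W/m2
    sunrise_hour: Mapping[str, float] = dc_field(
        default_factory=lambda: {"dry": 6.0, "wet": 6.0})
    daylight_hours: float = 12.0
    wd_mean: float = 2.0               # m/s
    ps_mean: float = 1010.0            # hPa
    noise_scale: float = 0.8
    noise_phi: float = 0.98            # fast AR(1) coefficient per 5-min step
    synoptic_scale: float = 1.2        # slow (multi-day) weather variability
    synoptic_phi: float = 0.9988       # ~3-day correlation time
    rain_rate: Mapping[str, float] = dc_field(
        default_factory=lambda: {"dry": 0.4, "wet": 2.5})   # events / day
    rain_scale: Mapping[str, float] = dc_field(
        default_factory=lambda: {"dry": 2.5, "wet": 3.5})   # mean mm / event
    rain_duration_mean_steps: int = 48  # mean event length, 5-min intervals
    seed: int = 0

    def validate(self) -> None:
        if 15 % self.resolution_min != 0 or self.resolution_min <= 0:
            raise InvalidConfigError(
                "resolution must be a positive divisor of 15 min")
        for season, (start, end) in self.season_spans.items():
            if pd.Timestamp(end) <= pd.Timestamp(start):
                raise InvalidConfigError(
                    f"season {season!r}: end {end} <= start {start}")
        if self.tp_amplitude < 0 or self.hu_amplitude < 0 or self.so_max < 0:
            raise InvalidConfigError("amplitudes must be >= 0")
        if any(r < 0 for r in self.rain_rate.values()):
            raise InvalidConfigError("rain rate must be >= 0")


@dataclass
class WeatherSeries:
    """Uniformly sampled multivariate climate log, one frame per season.

    Each frame is indexed by timestamp with columns tp (temperature, degC),
    hu (relative humidity, %), so (solar radiation, W/m2), wd (wind speed,
    m/s), ps (atmospheric pressure, hPa), ra (rainfall, mm per interval).
    """

    frames: Mapping[str, pd.DataFrame]
    resolution_min: int
    #: per-season log of generated rain events (start index, magnitude mm);
    #: total rainfall in each frame equals the sum of its event magnitudes
    rain_events: Mapping[str, pd.DataFrame] | None = None

    def season_of(self, t: pd.Timestamp) -> str:
        for season, frame in self.frames.items():
            if frame.index[0] <= t <= frame.index[-1]:
                return season
        raise KeyError(f"timestamp {t} outside every season span")


FACTORS = ("tp", "hu", "so", "wd", "ps", "ra")


def _ar1(rng: np.random.Generator, n: int, phi: float, scale: float) -> np.ndarray:
    # stationary AR(1); innovations scaled so the marginal sd equals `scale`
    if scale == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, scale * np.sqrt(1 - phi**2), n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, scale)
    for i in range(1, n):
        out[i] = phi * out[i - 1] + eps[i]
    return out


def simulate_weather(config: WeatherConfig) -> WeatherSeries:
    """Simulate the full two-season climate log on a uniform grid."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    frames = {}
    events = {}
    for season, (start, end) in config.season_spans.items():
        idx = pd.date_range(start, end, freq=f"{config.resolution_min}min")
        n = len(idx)
        hours = idx.hour.values + idx.minute.values / 60.0
        days = (idx - idx[0]).total_seconds().values / 86400.0

        def wander(scale_fast, scale_slow):
            # fast fluctuation plus an independent synoptic component, so
            # trailing averages at different windows stay distinguishable
            return (_ar1(rng, n, config.noise_phi, scale_fast)
                    + _ar1(rng, n, config.synoptic_phi, scale_slow))

        diurnal = np.sin(2 * np.pi * (hours - (config.diurnal_peak_hour - 6.0)) / 24.0)
        tp = (config.tp_mean[season]
              + config.tp_trend[season] * days
              + config.tp_amplitude * diurnal
              + wander(config.noise_scale, config.synoptic_scale))
        hu = np.clip(config.hu_base - config.hu_amplitude * diurnal
                     + wander(2.5 * config.noise_scale,
                              3.0 * config.synoptic_scale),
                     0.0, 100.0)

        sr = config.sunrise_hour[season]
        frac = (hours - sr) / config.daylight_hours
        day_mask = (frac > 0) & (frac < 1)
        clear = np.where(day_mask, np.sin(np.pi * np.clip(frac, 0, 1)), 0.0)
        # cloud-cover modulation in (0, 1]: slow synoptic component plus
        # fast passing-cloud flicker, so different windows decorrelate
        cloud = 1.0 / (1.0 + np.exp(-(_ar1(rng, n, 0.995, 1.0)
                                      + _ar1(rng, n, 0.5, 1.0) + 1.0)))
        so = np.maximum(config.so_max * clear * cloud, 0.0)

        wd = np.abs(config.wd_mean
                    + wander(config.noise_scale, config.synoptic_scale))
        ps = (config.ps_mean
              + 1.5 * np.sin(2 * np.pi * (hours - 4.0) / 12.0)
              + wander(0.3 * config.noise_scale,
                       2.0 * config.synoptic_scale))

        # rain: Poisson number of events; each event's total magnitude is
        # exponential and spread over a geometric number of intervals with
        # linearly decaying intensity (renormalized within the series), so
        # total rainfall equals the sum of the event magnitudes exactly
        ra = np.zeros(n)
        span_days = (idx[-1] - idx[0]).total_seconds() / 86400.0
        n_events = rng.poisson(config.rain_rate[season] * span_days)
        if n_events:
            starts = rng.integers(0, n, n_events)
            mags = rng.exponential(config.rain_scale[season], n_events)
            durs = rng.geometric(1.0 / config.rain_duration_mean_steps,
                                 n_events)
            for start, mag, dur in zip(starts, mags, durs):
                stop = min(start + dur, n)
                weights = np.arange(dur, 0, -1, dtype=float)[:stop - start]
                ra[start:stop] += mag * weights / weights.sum()
            events[season] = pd.DataFrame(
                {"start": starts, "magnitude": mags, "duration": durs})
        else:
            events[season] = pd.DataFrame(
                columns=["start", "magnitude", "duration"])

        frames[season] = pd.DataFrame(
            {"tp": tp, "hu": hu, "so": so, "wd": wd, "ps": ps, "ra": ra},
            index=idx)
    return WeatherSeries(frames=frames, resolution_min=config.resolution_min,
                         rain_events=events)


# ---------------------------------------------------------------------------
# Soil moisture
# ---------------------------------------------------------------------------

@dataclass
class SoilConfig:
    """Bucket model for rainfed soil; irrigated soil is held at saturation.

    Units are relative saturation in [0, 1]; saturation value = 1.0.
    Between rains the water content decays exponentially; each mm of rain
    recharges a fixed fraction; the 30 cm horizon reacts with a lag and a
    slower decay than the 15 cm horizon.
    """

    saturation: float = 1.0
    decay_15: float = 2e-4        # per 5-min step  (~6 %/day)
    decay_30: float = 8e-5
    recharge_per_mm: float = 0.02
    lag_30_steps: int = 36        # 3 h lag at 5-min resolution


@dataclass
class SoilMoistureSeries:
    frames: Mapping[str, pd.DataFrame]   # columns sm15, sm30
    field: str


def _bucket(ra: np.ndarray, decay: float, recharge: float,
            saturation: float) -> np.ndarray:
    out = np.empty(len(ra))
    s = saturation
    for i, r in enumerate(ra):
        s = min(saturation, s * (1.0 - decay) + recharge * r)
        out[i] = s
    return out


def simulate_soil_moisture(weather: WeatherSeries, field: str,
                           config: SoilConfig | None = None) -> SoilMoistureSeries:
    """Soil water content at 15 and 30 cm: constant saturation when
    irrigated, a decay/recharge bucket driven by rainfall when rainfed."""
    config = config or SoilConfig()
    if field not in FIELDS:
        raise ValueError(f"unknown field label {field!r}")
    frames = {}
    for season, wf in weather.frames.items():
        if field == "irrigated":
            sm15 = np.full(len(wf), config.saturation)
            sm30 = sm15.copy()
        else:
            ra = wf["ra"].to_numpy()
            sm15 = _bucket(ra, config.decay_15, config.recharge_per_mm,
                           config.saturation)
            ra_lag = np.concatenate(
                [np.zeros(config.lag_30_steps), ra])[:len(ra)]
            sm30 = _bucket(ra_lag, config.decay_30, config.recharge_per_mm,
                           config.saturation)
        frames[season] = pd.DataFrame(
            {"sm15": sm15, "sm30": sm30}, index=wf.index)
    return SoilMoistureSeries(frames=frames, field=field)


# ---------------------------------------------------------------------------
# Sampling schedule
# ---------------------------------------------------------------------------

@dataclass
class ScheduleConfig:
    n_timepoints: int = 15
    spacing_hours: float = 48.0
    offset_after_sunrise_hours: float = 4.0
    first_sampling_date: Mapping[str, str] = dc_field(
        default_factory=lambda: dict(_DEFAULT_FIRST_SAMPLING))
    genotypes: Sequence[str] = ("G1", "G2")
    replicates: Sequence[int] = (1, 2)


def make_schedule(config: ScheduleConfig | None = None,
                  weather_config: WeatherConfig | None = None) -> pd.DataFrame:
    """Sampling schedule: per season/field/genotype/replicate series of
    evenly spaced timepoints taken a fixed offset after sunrise.

    Returns a DataFrame with one row per sample and columns sample_id,
    season, field, genotype, replicate, timepoint, timestamp.
    """
    config = config or ScheduleConfig()
    weather_config = weather_config or WeatherConfig()
    rows = []
    for season in SEASONS:
        sunrise = weather_config.sunrise_hour[season]
        t0 = (pd.Timestamp(config.first_sampling_date[season])
              + pd.Timedelta(hours=sunrise + config.offset_after_sunrise_hours))
        times = [t0 + pd.Timedelta(hours=config.spacing_hours * i)
                 for i in range(config.n_timepoints)]
        span_start, span_end = map(pd.Timestamp,
                                   weather_config.season_spans[season])
        if times[-1] > span_end or times[0] < span_start:
            raise InvalidConfigError(
                f"season {season!r} span too short for "
                f"{config.n_timepoints} timepoints")
        for fld in FIELDS:
            for geno in config.genotypes:
                for rep in config.replicates:
                    for i, t in enumerate(times, start=1):
                        rows.append({
                            "sample_id": f"{season}.{fld}.{geno}.r{rep}.t{i:02d}",
                            "season": season, "field": fld, "genotype": geno,
                            "replicate": rep, "timepoint": i, "timestamp": t})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

@dataclass
class ClusterSpec:
    """Ground-truth generative model for one co-expression cluster.

    ``equations`` maps a segment label (e.g. ``"all"``, ``"season=dry"``,
    ``"season=wet|field=rainfed"``) to a list of (parameter id, coefficient)
    pairs, at most three terms per segment.  The segment labels of one
    cluster must partition the design columns.
    """

    cluster_id: int
    n_genes: int
    equations: Mapping[str, Sequence[tuple[str, float]]]
    loading_spread: float = 0.15    # sd of per-gene multiplicative loading
    gene_noise_sd: float = 0.25     # sd of per-gene, per-sample noise
    #: cluster-wide biological noise shared by all member genes (per
    #: genotype and design cell).  Co-expressed genes co-vary beyond the
    #: climatic signal, so the cluster mean does not become arbitrarily
    #: clean as the cluster grows; this sets the cluster-mean SNR.
    shared_noise_sd: float = 0.0
    genotype_effect_sd: float = 0.0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise InvalidConfigError("cluster needs >= 1 gene")
        for seg, terms in self.equations.items():
            if len(terms) > 3:
                raise InvalidConfigError(
                    f"segment {seg!r}: more than 3 terms")
            for pid, coef in terms:
                if not np.isfinite(coef):
                    raise InvalidConfigError(f"non-finite coefficient for {pid}")


@dataclass
class GroundTruth:
    """Cluster specs plus the filter-fodder pools used to exercise filters."""

    clusters: Sequence[ClusterSpec]
    n_low_cv_genes: int = 20
    n_low_mean_genes: int = 20
    #: environmentally stable background genes at varied abundance.  Real
    #: transcriptomes are dominated by such genes; they anchor the
    #: median-of-ratios size factors (otherwise the cluster signals leak
    #: into the factors and imprint a shared artifact on every profile)
    #: and are then removed by the CV filter.
    n_background_genes: int = 240
    #: per-sample sequencing-depth multipliers: lognormal with this sd of
    #: log2 depth; 0 disables depth variation
    depth_log2_sd: float = 0.3
    baseline_log_expression: float = 8.0
    #: stable genes sit at high abundance, where counting noise is small
    #: enough that their post-preprocessing CV falls below the filter
    low_cv_baseline: float = 12.0
    #: low-abundance genes sit just under the mean filter but are detected
    #: often enough to pass the detection filter
    low_mean_log_level: float = 0.9
    seed: int = 0

    def gene_cluster_map(self) -> pd.Series:
        names, labels = [], []
        for spec in self.clusters:
            for g in range(spec.n_genes):
                names.append(f"c{spec.cluster_id:02d}_g{g:03d}")
                labels.append(spec.cluster_id)
        for g in range(self.n_low_cv_genes):
            names.append(f"lowcv_g{g:03d}")
            labels.append(-1)
        for g in range(self.n_low_mean_genes):
            names.append(f"lowmean_g{g:03d}")
            labels.append(-2)
        for g in range(self.n_background_genes):
            names.append(f"bg_g{g:03d}")
            labels.append(-3)
        return pd.Series(labels, index=pd.Index(names, name="gene"))


def _segment_mask(label: str, meta: pd.DataFrame) -> np.ndarray:
    if label == "all":
        return np.ones(len(meta), dtype=bool)
    mask = np.ones(len(meta), dtype=bool)
    for clause in label.split("|"):
        key, value = clause.split("=")
        mask &= (meta[key].astype(str) == value).to_numpy()
    if not mask.any():
        raise InvalidConfigError(f"segment {label!r} matches no sample")
    return mask


def cluster_signal(spec: ClusterSpec, ed_values: pd.DataFrame,
                   meta: pd.DataFrame) -> np.ndarray:
    """Ground-truth cluster-mean signal over the design columns of ``ed_values``
    (parameters x samples)."""
    spec.validate()
    signal = np.zeros(ed_values.shape[1])
    covered = np.zeros(ed_values.shape[1], dtype=bool)
    for seg, terms in spec.equations.items():
        mask = _segment_mask(seg, meta)
        if (covered & mask).any():
            raise InvalidConfigError(
                f"cluster {spec.cluster_id}: overlapping segments")
        covered |= mask
        for pid, coef in terms:
            if pid not in ed_values.index:
                raise KeyError(f"unknown parameter id {pid!r}")
            signal[mask] += coef * ed_values.loc[pid].to_numpy()[mask]
    if not covered.all():
        raise InvalidConfigError(
            f"cluster {spec.cluster_id}: segments do not cover the design")
    return signal


def simulate_expression(ed_values: pd.DataFrame, design_meta: pd.DataFrame,
                        schedule: pd.DataFrame, truth: GroundTruth,
                        mode: str = "counts") -> pd.DataFrame:
    """Generate a genes x samples matrix over the full sampling schedule.

    ``ed_values`` holds the finalized ED parameters over the design columns
    (one column per season/field/timepoint combination); ``design_meta`` is
    the matching per-column metadata.  Each scheduled sample receives the
    signal of its design cell plus genotype and gene-level noise.  In
    ``counts`` mode values are Poisson draws around the exponentiated
    log-scale signal; ``continuous`` mode returns the log-scale values
    directly, for exact tests.
    """
    if mode not in ("counts", "continuous"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(truth.seed)
    # map each scheduled sample to its design column
    design_key = (design_meta["season"].astype(str) + "."
                  + design_meta["field"].astype(str) + "."
                  + design_meta["timepoint"].astype(str))
    col_of = {k: j for j, k in enumerate(design_key)}
    sample_key = (schedule["season"].astype(str) + "."
                  + schedule["field"].astype(str) + "."
                  + schedule["timepoint"].astype(str))
    sample_cols = np.array([col_of[k] for k in sample_key])
    n_samples = len(schedule)
    genotypes = schedule["genotype"].to_numpy()
    geno_levels = pd.unique(genotypes)

    level_of = {g: i for i, g in enumerate(geno_levels)}
    geno_idx_all = np.array([level_of[g] for g in genotypes])

    blocks, names = [], []
    for spec in truth.clusters:
        signal = cluster_signal(spec, ed_values, design_meta)[sample_cols]
        if spec.shared_noise_sd:
            shared = rng.normal(0.0, spec.shared_noise_sd,
                                (len(geno_levels), ed_values.shape[1]))
            signal = signal + shared[geno_idx_all, sample_cols]
        loadings = 1.0 + rng.normal(0.0, spec.loading_spread, spec.n_genes)
        block = loadings[:, None] * signal[None, :]
        if spec.genotype_effect_sd:
            geno_offsets = rng.normal(0.0, spec.genotype_effect_sd,
                                      (spec.n_genes, len(geno_levels)))
            block = block + geno_offsets[:, geno_idx_all]
        block = block + rng.normal(0.0, spec.gene_noise_sd,
                                   (spec.n_genes, n_samples))
        blocks.append(block + truth.baseline_log_expression)
        names.extend(f"c{spec.cluster_id:02d}_g{g:03d}"
                     for g in range(spec.n_genes))
    if truth.n_low_cv_genes:
        # essentially constant expression: removed by the CV filter
        block = truth.low_cv_baseline + rng.normal(
            0.0, 1e-4, (truth.n_low_cv_genes, n_samples))
        blocks.append(block)
        names.extend(f"lowcv_g{g:03d}" for g in range(truth.n_low_cv_genes))
    if truth.n_low_mean_genes:
        # mean below 1 on the log scale: removed by the mean filter
        block = np.abs(rng.normal(truth.low_mean_log_level, 0.05,
                                  (truth.n_low_mean_genes, n_samples)))
        blocks.append(block)
        names.extend(f"lowmean_g{g:03d}"
                     for g in range(truth.n_low_mean_genes))
    if truth.n_background_genes:
        # stable genes across a range of abundances high enough that
        # counting noise keeps their CV under the stable-gene filter
        bases = rng.uniform(9.0, 13.0, truth.n_background_genes)
        block = np.tile(bases[:, None], (1, n_samples))
        blocks.append(block)
        names.extend(f"bg_g{g:03d}"
                     for g in range(truth.n_background_genes))
    log_expr = np.vstack(blocks)
    frame = pd.DataFrame(log_expr, index=pd.Index(names, name="gene"),
                         columns=schedule["sample_id"].to_numpy())
    if mode == "continuous":
        return frame
    depth = np.exp2(rng.normal(0.0, truth.depth_log2_sd, n_samples)) \
        if truth.depth_log2_sd else np.ones(n_samples)
    lam = np.maximum(np.exp2(log_expr) - 1.0, 0.0) * depth[None, :]
    counts = rng.poisson(lam)
    return pd.DataFrame(counts, index=frame.index, columns=frame.columns)
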