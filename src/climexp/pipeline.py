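"""End-to-end orchestration: synthetic data, preprocessing, ED parameters,
clustering, piecewise model selection, context analysis and transfer, from
a single seeded configuration, with machine-readable stage outputs and a
manifest."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as cio
from .cluster import PAMClusterer
from .context import summarize_clusters
from .envparams import (DevAnchors, EDParameterMatrix, assemble_and_finalize)
from .preprocess import average_genotypes, preprocess_counts
from .selection import (PiecewiseEDRegressor, SelectionConfig,
                        select_piecewise, SUBSET_CONFIG,
                        one_factor_compositions)
from .simulate import (ClusterSpec, GroundTruth, ScheduleConfig, SoilConfig,
                       WeatherConfig, make_schedule, simulate_expression,
                       simulate_soil_moisture, simulate_weather)
from .transfer import (center_by_time_of_day, eligible_source_models,
                       transfer_model)

MODES = ("dry-season-two-genotype", "two-season-averaged",
         "irrigated-two-season", "target-transfer")


@dataclass
class PipelineConfig:
    """All thresholds and synthetic-data settings of a pipeline run.

    Defaults reproduce the method's standard settings, so an explicitly
    configured value is always a deliberate override.
    """

    mode: str = "two-season-averaged"
    seed: int = 0
    # filters
    max_undetected: int = 40
    cv_threshold: float = 0.01
    mean_threshold: float = 1.0
    # ED parameters
    merge_r: float = 0.98
    # clustering
    k_max: int = 80
    min_cluster_frac: float = 0.01
    max_small_mass: float = 0.05
    # context thresholds
    genotype_r_cutoff: float = 0.9
    field_r_cutoff: float = 0.8
    # model selection
    corr_cap: float = 0.85
    selection: SelectionConfig = dc_field(default_factory=SelectionConfig)
    subset_selection: SelectionConfig = dc_field(
        default_factory=lambda: SelectionConfig(threshold=0.7, fraction=0.7))
    # transfer
    transfer_min_r2: float = 0.5
    # synthetic-data scenario
    n_clusters: int = 10
    genes_per_cluster: int = 30
    n_low_cv_genes: int = 20
    n_low_mean_genes: int = 20
    n_background_genes: int = 240
    snr: float = 4.0
    genotype_effect_sd: float = 0.05
    loading_spread: float = 0.15
    expression_mode: str = "counts"
    # optional file inputs (None -> simulate)
    counts_path: str | None = None
    metadata_path: str | None = None
    weather_path: str | None = None

    def validate(self) -> list[str]:
        """List of violated invariants; empty means the run can start."""
        issues = []
        if self.mode not in MODES:
            issues.append(f"unknown mode {self.mode!r}")
        for name, lo, hi in (("corr_cap", 0, 1), ("merge_r", 0, 1),
                             ("field_r_cutoff", -1, 1),
                             ("genotype_r_cutoff", -1, 1),
                             ("min_cluster_frac", 0, 1),
                             ("max_small_mass", 0, 1),
                             ("transfer_min_r2", 0, 1)):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                issues.append(f"{name}={v} outside [{lo}, {hi}]")
        if self.cv_threshold < 0 or self.mean_threshold < 0:
            issues.append("filter thresholds must be >= 0")
        if self.max_undetected < 0:
            issues.append("max_undetected must be >= 0")
        for label, cfg in (("selection", self.selection),
                           ("subset_selection", self.subset_selection)):
            try:
                cfg.validate()
            except ValueError as exc:
                issues.append(f"{label}: {exc}")
        if (self.counts_path is None) != (self.metadata_path is None):
            issues.append("counts_path and metadata_path must come together")
        if self.expression_mode not in ("counts", "continuous"):
            issues.append(f"unknown expression_mode {self.expression_mode!r}")
        return issues

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        data = dict(data)
        for key in ("selection", "subset_selection"):
            if key in data and isinstance(data[key], Mapping):
                data[key] = SelectionConfig(**data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# Scenario construction
# ---------------------------------------------------------------------------

#: Drivers for single-term ground-truth equations: distinctive domain
#: parameters (nonlinear solar, soil moisture, development) whose only
#: strong correlates are direct proxies of themselves, which the
#: prune-by-best-single-model rule resolves.
SINGLE_TERM_POOL = (
    "so_1hr_NL-", "sm15", "dev", "so_15min_NL+", "tp_4hr",
)
#: Maximum within-segment correlation a parameter may have with any other
#: grid parameter to serve as a multi-term ground-truth driver.  Beyond
#: this, a proxy parameter can absorb the driver's share of a combined
#: signal and exact set recovery becomes ill-posed.
MULTI_TERM_DECOY_CAP = 0.8
MULTI_TERM_POOL_SIZE = 12

#: Segment-structure templates cycled over clusters: global, field-specific,
#: season-specific, and the mixed form (field-specific in the dry season
#: only).
_SEGMENTATIONS = (
    ("all",),
    ("field=irrigated", "field=rainfed"),
    ("season=dry", "season=wet"),
    ("season=wet", "season=dry|field=irrigated", "season=dry|field=rainfed"),
)


def _resolve_params(ed: EDParameterMatrix,
                    preferred: Sequence[str]) -> list[str]:
    out = []
    for pid in preferred:
        hits = [mid for mid in ed.values.index
                if mid == pid or pid in mid.split("+")]
        if hits and hits[0] not in out:
            out.append(hits[0])
    return out


def default_cluster_specs(ed: EDParameterMatrix, config: PipelineConfig,
                          rng: np.random.Generator,
                          segmentations=_SEGMENTATIONS) -> list[ClusterSpec]:
    """Ground-truth clusters with 1-3-term equations over weakly correlated
    parameters, signals scaled to unit variance so ``gene_noise_sd`` =
    1 / SNR."""
    from .selection import segment_mask as _seg_mask
    from .simulate import _segment_mask, cluster_signal
    design = ed.design_meta
    single_pool = _resolve_params(ed, SINGLE_TERM_POOL)
    # multi-term drivers: parameters without a strong proxy in any segment
    seg_labels_all = sorted({lab for segs in segmentations for lab in segs})
    worst = pd.Series(0.0, index=ed.values.index)
    for lab in seg_labels_all:
        mask = _seg_mask(lab, design)
        corr = ed.values.T[mask].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = np.maximum(worst, corr.max(axis=1))
    eligible = worst[worst <= MULTI_TERM_DECOY_CAP].sort_values()
    # rainfall windows are dominated by single events and behave like
    # spikes inside short segments; they are left out of the truth pools
    multi_pool = [pid for pid in eligible.index
                  if pid not in single_pool
                  and not any(m.startswith("ra_")
                              for m in pid.split("+"))][:MULTI_TERM_POOL_SIZE]
    specs = []
    prev_signals: list[np.ndarray] = []
    for c in range(config.n_clusters):
        seg_labels = segmentations[c % len(segmentations)]
        n_terms = 1 + (c % 3)
        pool = single_pool + multi_pool if n_terms == 1 else multi_pool
        # redraw until this cluster's signal is distinguishable from every
        # earlier cluster (PAM cannot separate nearly collinear signals)
        for attempt in range(4 * len(pool)):
            equations = {}
            for si, seg in enumerate(seg_labels):
                mask = _segment_mask(seg, design)
                seg_vals = ed.values.loc[pool].T[mask]
                seg_sd = seg_vals.std(ddof=1)
                seg_corr = seg_vals.corr().abs()
                # rotate through the pool, requiring real within-segment
                # variance and avoiding co-selected correlated pairs
                chosen: list[str] = []
                offset = (2 * c + 3 * si + attempt) % len(pool)
                for j in range(len(pool)):
                    pid = pool[(offset + j) % len(pool)]
                    if seg_sd[pid] < 0.5:
                        continue
                    if all(seg_corr.loc[pid, q] <= 0.5 for q in chosen):
                        chosen.append(pid)
                    if len(chosen) == n_terms:
                        break
                signs = [1.0 if (c + si + t + attempt) % 2 == 0 else -1.0
                         for t in range(len(chosen))]
                mags = rng.uniform(0.5, 1.0, len(chosen))
                equations[seg] = [(pid, s * m) for pid, s, m
                                  in zip(chosen, signs, mags)]
            spec = ClusterSpec(cluster_id=c + 1,
                               n_genes=config.genes_per_cluster,
                               equations=equations,
                               loading_spread=config.loading_spread,
                               gene_noise_sd=1.0 / config.snr,
                               shared_noise_sd=1.0 / config.snr,
                               genotype_effect_sd=config.genotype_effect_sd)
            sig = cluster_signal(spec, ed.values, design)
            sig = sig / sig.std(ddof=1)
            if all(abs(np.corrcoef(sig, s0)[0, 1]) < 0.5
                   for s0 in prev_signals):
                break
        # normalize the signal to unit sd so SNR is exactly as configured
        sd = cluster_signal(spec, ed.values, design).std(ddof=1)
        spec.equations = {seg: [(pid, coef / sd) for pid, coef in terms]
                          for seg, terms in spec.equations.items()}
        prev_signals.append(sig)
        specs.append(spec)
    return specs


def averaged_design(schedule: pd.DataFrame) -> pd.DataFrame:
    """Genotype-averaged design: one column per (season, field, timepoint)."""
    key = ["season", "field", "timepoint"]
    design = (schedule.drop_duplicates(subset=key)[key + ["timestamp"]]
              .reset_index(drop=True))
    design["genotype"] = "avg"
    design.index = pd.Index(
        design["season"].astype(str) + "." + design["field"].astype(str)
        + "." + design["timepoint"].astype(str), name="column")
    return design


def build_source_inputs(config: PipelineConfig):
    """Simulate weather, soil, schedule and the finalized ED matrix over the
    genotype-averaged two-season design."""
    wc = WeatherConfig(seed=config.seed)
    weather = simulate_weather(wc)
    soil = {f: simulate_soil_moisture(weather, f, SoilConfig())
            for f in ("irrigated", "rainfed")}
    schedule = make_schedule(ScheduleConfig(), wc)
    design = averaged_design(schedule)
    anchors = DevAnchors.default_synthetic()
    ed = assemble_and_finalize(weather, soil, anchors, design,
                               merge_r=config.merge_r)
    return weather, soil, schedule, design, ed


# ---------------------------------------------------------------------------
# Run
# ---------------------------------------------------------------------------

def _align_columns(em_values: pd.DataFrame, em_meta: pd.DataFrame,
                   design: pd.DataFrame):
    """Reorder expression columns to the design-column order via the
    (season, field, timepoint) key."""
    key = (em_meta["season"].astype(str) + "."
           + em_meta["field"].astype(str) + "."
           + em_meta["timepoint"].astype(str))
    lookup = dict(zip(key, em_meta.index))
    order = [lookup[k] for k in design.index]
    return em_values[order], em_meta.loc[order]


def run(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the configured analysis end to end; returns the report
    bundle (also written under ``outdir``)."""
    issues = config.validate()
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    weather, soil, schedule, design, ed = build_source_inputs(config)
    cio.write_weather(weather, outdir / "weather.csv")

    if config.counts_path is not None:
        counts = cio.read_counts_tsv(config.counts_path)
        meta = cio.read_metadata(config.metadata_path)
        truth = None
    else:
        specs = default_cluster_specs(ed, config, rng)
        truth = GroundTruth(clusters=specs,
                            n_low_cv_genes=config.n_low_cv_genes,
                            n_low_mean_genes=config.n_low_mean_genes,
                            n_background_genes=config.n_background_genes,
                            seed=config.seed + 1)
        counts = simulate_expression(ed.values, design, schedule, truth,
                                     mode=config.expression_mode)
        meta = schedule.set_index("sample_id")
        cio.write_counts_tsv(counts, outdir / "counts.tsv")
        cio.write_metadata(meta, outdir / "sample_metadata.csv")
        cio.write_json({
            "clusters": [{
                "cluster_id": s.cluster_id, "n_genes": s.n_genes,
                "equations": {seg: [[pid, float(c)] for pid, c in terms]
                              for seg, terms in s.equations.items()},
            } for s in specs]}, outdir / "ground_truth.json")

    em, report = preprocess_counts(
        counts, meta, max_undetected=config.max_undetected,
        cv_threshold=config.cv_threshold,
        mean_threshold=config.mean_threshold,
        counts_are_continuous=(config.expression_mode == "continuous"
                               and config.counts_path is None))
    cio.write_json({"stages": report.stages}, outdir / "filter_report.json")

    mode = config.mode
    results: dict[int, object] = {}
    bundle: dict = {"mode": mode, "seed": config.seed,
                    "filter_report": report.stages}

    if mode in ("two-season-averaged", "irrigated-two-season",
                "target-transfer"):
        em_avg = average_genotypes(em)
        if mode == "two-season-averaged":
            analysis_design = design
            single_factor = False
            ed_analysis = ed
        else:
            analysis_design = design[design["field"] == "irrigated"]
            single_factor = True
            ed_analysis = assemble_and_finalize(
                weather, soil, DevAnchors.default_synthetic(),
                analysis_design, merge_r=config.merge_r,
                include_field=False, include_soil=False)
            irr_cols = [c for c in em_avg.meta.index
                        if em_avg.meta.loc[c, "field"] == "irrigated"]
            from .preprocess import ExpressionMatrix, center_subsets, scale_genes
            em_avg = ExpressionMatrix(values=em_avg.values[irr_cols],
                                      meta=em_avg.meta.loc[irr_cols],
                                      stage="replicate-averaged")
            em_avg = scale_genes(center_subsets(em_avg))
        values, meta_a = _align_columns(em_avg.values, em_avg.meta,
                                        analysis_design)
        clusterer = PAMClusterer(n_clusters="auto", k_max=config.k_max,
                                 min_cluster_frac=config.min_cluster_frac,
                                 max_small_mass=config.max_small_mass)
        clusterer.fit(values.to_numpy())
        means = clusterer.means(values)
        X = ed_analysis.values.T
        X.index = analysis_design.index
        r2 = {}
        for cid, y in means.iterrows():
            reg = PiecewiseEDRegressor(
                B=config.selection.B, ev=config.selection.ev,
                threshold=config.selection.threshold,
                fraction=config.selection.fraction,
                subset_threshold=config.subset_selection.threshold,
                subset_fraction=config.subset_selection.fraction,
                corr_cap=config.corr_cap,
                cv_folds=config.selection.cv_folds,
                cv_repeats=config.selection.cv_repeats,
                subset_factors=("season",) if single_factor
                else ("season", "field"),
                single_factor=single_factor,
                random_state=config.seed + 100 + int(cid))
            reg.fit(X, y.to_numpy(), design=analysis_design)
            results[int(cid)] = reg.result_
            r2[int(cid)] = reg.r2(X, y.to_numpy())
        labels = pd.DataFrame({"gene": values.index,
                               "cluster": clusterer.labels_})
        labels.to_csv(outdir / "cluster_labels.tsv", sep="\t", index=False)
        means.to_csv(outdir / "cluster_means.tsv", sep="\t",
                     float_format=cio.FLOAT_FMT)
        cio.write_json(
            {str(cid): cio.selection_record(res)
             for cid, res in results.items()}, outdir / "models.json")
        bundle.update(n_clusters=clusterer.n_clusters_,
                      cluster_sizes=clusterer.cluster_sizes_.tolist(),
                      r2={str(k): v for k, v in r2.items()})

        if mode == "two-season-averaged":
            geno_means = pd.DataFrame(
                {cid: em.values.iloc[np.where(clusterer.labels_ == cid)[0]]
                 .mean(axis=0) for cid in np.unique(clusterer.labels_)}).T
            summary = summarize_clusters(
                means, meta_a, genotype_means=geno_means,
                genotype_meta=em.meta,
                genotype_r_cutoff=config.genotype_r_cutoff,
                field_r_cutoff=config.field_r_cutoff)
            summary.to_csv(outdir / "context_summary.tsv", sep="\t",
                           float_format=cio.FLOAT_FMT)
            bundle["context_groups"] = summary["group"].to_dict()

        if mode == "target-transfer":
            transfer_out = run_transfer_stage(
                config, results, r2, means, analysis_design, rng)
            cio.write_json(transfer_out, outdir / "transfer.json")
            bundle["transfer"] = transfer_out

    elif mode == "dry-season-two-genotype":
        dry_cols = [c for c in em.meta.index
                    if em.meta.loc[c, "season"] == "dry"]
        from .preprocess import ExpressionMatrix, center_subsets, scale_genes
        em_dry = ExpressionMatrix(values=em.values[dry_cols],
                                  meta=em.meta.loc[dry_cols],
                                  stage="replicate-averaged")
        em_dry = scale_genes(center_subsets(em_dry))
        dry_design = em_dry.meta.copy()
        ed_dry = assemble_and_finalize(
            weather, soil, DevAnchors.default_synthetic(), dry_design,
            merge_r=config.merge_r)
        clusterer = PAMClusterer(n_clusters="auto", k_max=config.k_max,
                                 min_cluster_frac=config.min_cluster_frac,
                                 max_small_mass=config.max_small_mass)
        clusterer.fit(em_dry.values.to_numpy())
        means = clusterer.means(em_dry.values)
        X = ed_dry.values.T
        X.index = dry_design.index
        for cid, y in means.iterrows():
            res = select_piecewise(
                X, y.to_numpy(), dry_design,
                cfg=SelectionConfig(
                    **{**vars(config.selection),
                       "seed": config.seed + 100 + int(cid)}),
                subset_cfg=config.subset_selection,
                subset_factors=("genotype", "field"))
            results[int(cid)] = res
        means.to_csv(outdir / "cluster_means.tsv", sep="\t",
                     float_format=cio.FLOAT_FMT)
        cio.write_json({str(cid): cio.selection_record(res)
                        for cid, res in results.items()},
                       outdir / "models.json")
        bundle.update(n_clusters=clusterer.n_clusters_,
                      cluster_sizes=clusterer.cluster_sizes_.tolist())

    manifest = {
        "mode": mode, "seed": config.seed,
        "thresholds": {
            "max_undetected": config.max_undetected,
            "cv_threshold": config.cv_threshold,
            "mean_threshold": config.mean_threshold,
            "merge_r": config.merge_r, "corr_cap": config.corr_cap,
            "genotype_r_cutoff": config.genotype_r_cutoff,
            "field_r_cutoff": config.field_r_cutoff,
            "min_cluster_frac": config.min_cluster_frac,
            "max_small_mass": config.max_small_mass},
        "outputs": {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                    for p in sorted(outdir.iterdir()) if p.is_file()
                    and p.name != "manifest.json"},
    }
    cio.write_json(manifest, outdir / "manifest.json")
    bundle["manifest"] = manifest
    return bundle


# ---------------------------------------------------------------------------
# Transfer stage (synthetic target)
# ---------------------------------------------------------------------------

TARGET_TIMES = {8: 8, 10: 12, 12: 16, 14: 8, 16: 8}   # hour -> n samples


def simulate_target_inputs(seed: int, noise_sd: float = 0.2):
    """Synthetic temperate, irrigated-only target: 52 daytime samples at
    five times of day over a 7-week vegetative window, with the same ED
    parameter definitions plus 8- and 12-h short-term averages and a
    days-after-transplanting developmental covariate."""
    wc = WeatherConfig(
        season_spans={"target": ("2008-05-15 00:00", "2008-08-20 23:55")},
        tp_mean={"target": 24.0}, tp_trend={"target": 0.05},
        sunrise_hour={"target": 4.5},
        rain_rate={"target": 1.2}, rain_scale={"target": 2.0},
        seed=seed + 7)
    weather = simulate_weather(wc)
    transplant = pd.Timestamp("2008-06-01")
    rows = []
    rng = np.random.default_rng(seed + 13)
    for hour, count in TARGET_TIMES.items():
        days = np.linspace(15, 62, count).round().astype(int)
        for d in days:
            t = transplant + pd.Timedelta(days=int(d), hours=hour)
            rows.append({"sample_id": f"d{d:02d}_h{hour:02d}",
                         "season": "target", "field": "irrigated",
                         "timepoint": int(d), "time_of_day": hour,
                         "timestamp": t})
    design = pd.DataFrame(rows).set_index("sample_id")

    from .envparams import build_raw_parameters
    anchors = DevAnchors(anchors={("target", "irrigated"):
                                  ("2008-06-01", "2008-07-10", "2008-08-20")})
    extra = {"8hr": pd.Timedelta(hours=8), "12hr": pd.Timedelta(hours=12)}
    raw, _ = build_raw_parameters(weather, {}, anchors, design,
                                  include_field=False, include_soil=False,
                                  extra_l_windows=extra)
    # days after transplanting as the developmental covariate
    raw.loc["dev"] = [(pd.Timestamp(t) - transplant).days
                      for t in design["timestamp"]]
    tod = design["time_of_day"]
    centered = center_by_time_of_day(raw, tod)
    sd = centered.std(axis=1, ddof=1)
    keep = sd > 0
    X_target = centered.loc[keep].div(sd[keep], axis=0)
    return X_target, design


def run_transfer_stage(config: PipelineConfig,
                       results: Mapping[int, object],
                       r2: Mapping[int, float],
                       means: pd.DataFrame,
                       design: pd.DataFrame,
                       rng: np.random.Generator,
                       target_noise_sd: float = 0.3) -> dict:
    """Build the synthetic target whose eligible cluster means follow the
    source equations (same signs) and run the sign-constrained transfer."""
    X_target, t_design = simulate_target_inputs(config.seed)
    eligible = eligible_source_models(
        results, r2, min_r2=config.transfer_min_r2)
    tod = t_design["time_of_day"].to_numpy()
    out = {"eligible_clusters": eligible, "results": {}}
    for cid in eligible:
        eq = results[cid].model.equations["all"]
        terms = [(pid, coef) for pid, coef in eq.terms
                 if pid in X_target.index]
        y = np.zeros(X_target.shape[1])
        for pid, coef in terms:
            y += coef * X_target.loc[pid].to_numpy()
        y = y + rng.normal(0.0, target_noise_sd, len(y))
        # center the target profile per time of day, as the expression side
        y = pd.Series(y, index=X_target.columns)
        for hour in np.unique(tod):
            mask = tod == hour
            y[mask] -= y[mask].mean()
        res = transfer_model(terms, X_target.T, y.to_numpy(),
                             strata=tod, cluster_id=cid,
                             seed=config.seed + 500 + cid)
        out["results"][str(cid)] = {
            "tested": [pid for pid, _ in terms],
            "retained": [{"parameter": pid, "coefficient": float(c)}
                         for pid, c in res.retained_terms],
            "r2": res.r2, "null": res.null}
    return out
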