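"""Self-validation studies on synthetic data with known ground truth.

Each function builds its own inputs from a seed, runs the relevant part of
the pipeline, and measures how well the known generative structure is
recovered: closed-form identities of the feature transforms, equivalence of
the model search with brute-force enumeration, exact-parameter-set and
coefficient recovery, segmentation (composition) assignment, transfer-rule
soundness and bitwise determinism of the full run.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .cluster import PAMClusterer, correlation_distance, pam, select_k, \
    small_cluster_mass
from .envparams import (DELTA_FACTORS, DELTA_LAGS, EPS_WINDOWS, L_WINDOWS,
                        build_raw_parameters, dev_stage, nl_transform,
                        seasonal_remainder)
from .pipeline import (PipelineConfig, _align_columns, build_source_inputs,
                       default_cluster_specs, simulate_target_inputs)
from .preprocess import average_genotypes, preprocess_counts
from .selection import (SelectionConfig, bic, composite_mse, cv_mse,
                        make_folds, prune_correlated_candidates,
                        select_equation, select_piecewise)
from .simulate import GroundTruth, cluster_signal, simulate_expression
from .transfer import transfer_model

warnings.filterwarnings("ignore")


# ---------------------------------------------------------------------------
# Closed-form layer
# ---------------------------------------------------------------------------

def closed_form_checks() -> dict[str, float]:
    """Exact identities of the feature transforms and pooling rules."""
    x = np.linspace(0.0, 1000.0, 201)
    nl_product_dev = float(np.abs(
        nl_transform(x, "+") * nl_transform(x, "-") - 1.0).max())
    nl_anchor_dev = float(max(abs(nl_transform(400.0, "+") - 1.0),
                              abs(nl_transform(400.0, "-") - 1.0)))

    from .envparams import DevAnchors
    anchors = DevAnchors.default_synthetic()
    d = anchors.anchors[("dry", "irrigated")]
    dev_anchor_dev = float(max(
        abs(dev_stage(anchors, "dry", "irrigated", d[0]) - 0.0),
        abs(dev_stage(anchors, "dry", "irrigated", d[1]) - 40.0),
        abs(dev_stage(anchors, "dry", "irrigated", d[2]) - 100.0)))
    mid = d[1] + (d[2] - d[1]) / 2
    dev_midpoint = float(dev_stage(anchors, "dry", "irrigated", mid))

    rng = np.random.default_rng(0)
    segs = [rng.uniform(size=n) for n in (7, 13, 25, 15)]
    pooled = composite_mse(segs)
    weighted = sum(s.sum() for s in segs) / sum(len(s) for s in segs)
    pooling_dev = float(abs(pooled - weighted))

    log2_dev = float(max(abs(np.log2(0 + 1) - 0), abs(np.log2(1 + 1) - 1),
                         abs(np.log2(3 + 1) - 2)))
    return {
        "nl_product_identity_max_dev": nl_product_dev,
        "nl_anchor_max_dev": nl_anchor_dev,
        "dev_stage_anchor_max_dev": dev_anchor_dev,
        "dev_stage_midpoint": dev_midpoint,
        "composite_mse_pooling_dev": pooling_dev,
        "log2_transform_max_dev": log2_dev,
    }


# ---------------------------------------------------------------------------
# Oracle equivalence
# ---------------------------------------------------------------------------

def oracle_equation_agreement(n_instances: int = 50, seed: int = 1) -> float:
    """Fraction of random instances on which ``select_equation`` matches an
    independently coded brute-force search over all admissible <=3-term
    subsets with shared CV folds (expected: 1.0)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for trial in range(n_instances):
        n = 40
        p = int(rng.integers(4, 11))
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"p{i:02d}" for i in range(p)])
        X = (X - X.mean()) / X.std(ddof=0)
        beta = np.zeros(p)
        k = int(rng.integers(1, min(4, p + 1)))
        beta[rng.choice(p, k, replace=False)] = rng.normal(0, 1, k)
        y = X.to_numpy() @ beta + rng.normal(0, 0.4, n)
        cfg = SelectionConfig(seed=trial)
        folds = make_folds(n, 5, 5, np.random.default_rng(trial))
        eq = select_equation(X, y, list(X.columns), cfg, folds)

        corr = X.corr().abs()
        cands = prune_correlated_candidates(list(X.columns), X, y, folds,
                                            cfg.corr_cap)
        best = (bic(cv_mse(np.empty((n, 0)), y, folds)[0], n, 0), 0, ())
        for size in (1, 2, 3):
            for sub in itertools.combinations(cands, size):
                if any(corr.loc[a, b] > cfg.corr_cap
                       for a, b in itertools.combinations(sub, 2)):
                    continue
                mse, _ = cv_mse(X[list(sub)].to_numpy(), y, folds)
                cand = (bic(mse, n, size), size, tuple(sorted(sub)))
                if cand < best:
                    best = cand
        agree += tuple(sorted(eq.parameter_ids)) == best[2]
    return agree / n_instances


def oracle_select_k_agreement(n_cases: int = 20, seed: int = 2) -> float:
    """Fraction of synthetic clusterings on which ``select_k`` matches an
    independent descending scan of the 5%/1% rule (expected: 1.0)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_cases):
        n_clusters = int(rng.integers(2, 6))
        sizes = rng.integers(4, 25, n_clusters)
        centers = rng.normal(size=(n_clusters, 20))
        rows = np.vstack([
            centers[c] + rng.normal(0, rng.uniform(0.1, 0.6), (sizes[c], 20))
            for c in range(n_clusters)])
        D = correlation_distance(rows)
        k_max = int(rng.integers(3, 9))
        got, _ = select_k(D, k_max=k_max)
        expected = 2
        for k in range(min(k_max, len(D) - 1), 1, -1):
            labels, _ = pam(D, k)
            if small_cluster_mass(labels, 0.01) <= 0.05:
                expected = k
                break
        agree += got == expected
    return agree / n_cases


def window_param_max_dev(seed: int = 3) -> float:
    """Maximum deviation of every windowed / delta / fluctuation parameter
    from a direct brute-force recomputation on the raw 5-min grid
    (expected: < 1e-10)."""
    weather, soil, schedule, design, _ = build_source_inputs(
        PipelineConfig(seed=seed))
    from .envparams import DevAnchors
    raw, _ = build_raw_parameters(weather, soil,
                                  DevAnchors.default_synthetic(), design)
    times = pd.to_datetime(design["timestamp"])
    period = int(round(24 * 60 / weather.resolution_min))
    remainders = {s: seasonal_remainder(f["tp"], period)
                  for s, f in weather.frames.items()}
    max_dev = 0.0

    def trailing(series, index, t, window):
        mask = (index >= t - window) & (index <= t)
        return series[mask].mean()

    for t in times:
        season = weather.season_of(t)
        frame = weather.frames[season]
        for factor in ("tp", "hu", "so", "wd", "ps", "ra"):
            for label, window in L_WINDOWS.items():
                direct = trailing(frame[factor].to_numpy(),
                                  frame.index, t, window)
                got = raw.loc[f"{factor}_{label}",
                              design.index[times == t][0]]
                max_dev = max(max_dev, abs(got - direct))
        for factor in DELTA_FACTORS:
            for label, (lag, base) in DELTA_LAGS.items():
                direct = (trailing(frame[factor].to_numpy(), frame.index,
                                   t, base)
                          - trailing(frame[factor].to_numpy(), frame.index,
                                     t - lag, base))
                got = raw.loc[f"{factor}_delta{label}",
                              design.index[times == t][0]]
                max_dev = max(max_dev, abs(got - direct))
        rem = remainders[season]
        for label, window in EPS_WINDOWS.items():
            direct = trailing(rem.to_numpy(), rem.index, t, window)
            got = raw.loc[f"tp_eps{label}", design.index[times == t][0]]
            max_dev = max(max_dev, abs(got - direct))
    return float(max_dev)


# ---------------------------------------------------------------------------
# Parameter recovery (full pipeline)
# ---------------------------------------------------------------------------

def parameter_recovery_study(n_seeds: int = 20, seed: int = 1,
                             k_max: int = 15) -> dict[str, float]:
    """Full-pipeline exact-parameter-set recovery on global-equation
    clusters at the generator's standard SNR, aggregated over seeds.

    Returns the exact-set rate, the rate at which the recovered set
    contains the truth with correct signs (superset-inclusive), and the
    fraction of exactly recovered clusters whose coefficients sit within 3
    standard errors of the projected truth.
    """
    exact = superset = coef_ok = total = 0
    for s in range(n_seeds):
        run_seed = seed + 1000 * s
        cfg = PipelineConfig(seed=run_seed)
        weather, soil, schedule, design, ed = build_source_inputs(cfg)
        rng = np.random.default_rng(run_seed)
        specs = default_cluster_specs(ed, cfg, rng,
                                      segmentations=(("all",),))
        truth = GroundTruth(clusters=specs, seed=run_seed + 1)
        counts = simulate_expression(ed.values, design, schedule, truth)
        em, _ = preprocess_counts(counts, schedule.set_index("sample_id"))
        em_avg = average_genotypes(em)
        values, _ = _align_columns(em_avg.values, em_avg.meta, design)
        clusterer = PAMClusterer(n_clusters="auto", k_max=k_max)
        clusterer.fit(values.to_numpy())
        means = clusterer.means(values)
        labels = pd.Series(clusterer.labels_, index=values.index)
        X = ed.values.T
        X.index = design.index
        tm = truth.gene_cluster_map()
        for spec in specs:
            total += 1
            genes = [g for g in values.index
                     if tm[g] == spec.cluster_id]
            y = means.loc[labels[genes].mode()[0]].to_numpy()
            res = select_piecewise(X, y, design,
                                   seed=run_seed + 100 + spec.cluster_id)
            model = res.model
            truth_terms = dict(spec.equations["all"])
            truth_set = tuple(sorted(truth_terms))
            union = {}
            for eq in model.equations.values():
                union.update(dict(eq.terms))
            if set(truth_set) <= set(union) and all(
                    np.sign(union[p]) == np.sign(truth_terms[p])
                    for p in truth_set):
                superset += 1
            is_exact = (model.composition_id == 1 and tuple(sorted(
                p for p, _ in model.equations["all"].terms)) == truth_set)
            exact += is_exact
            if is_exact:
                sig = cluster_signal(spec, ed.values, design)
                c = float(y @ sig / (sig @ sig))
                Xs = X[list(truth_set)].to_numpy()
                beta = np.linalg.solve(Xs.T @ Xs, Xs.T @ y)
                resid = y - Xs @ beta
                dof = len(y) - len(truth_set)
                cov = np.linalg.inv(Xs.T @ Xs) * (resid @ resid) / dof
                se = np.sqrt(np.diag(cov))
                devs = [abs(b - c * truth_terms[p]) / e
                        for p, b, e in zip(truth_set, beta, se)]
                coef_ok += all(d <= 3 for d in devs)
    return {
        "exact_set_rate": exact / total,
        "signed_superset_rate": superset / total,
        "coef_within_3se_rate": coef_ok / max(exact, 1),
        "n": total,
        "n_exact": exact,
    }


# ---------------------------------------------------------------------------
# Segmentation recovery
# ---------------------------------------------------------------------------

_SEG_SCENARIOS = {
    "global": ((("all",),), 1),
    "field": (((("field=irrigated", "field=rainfed")),), 3),
    "mixed": ((("season=wet", "season=dry|field=irrigated",
                "season=dry|field=rainfed"),), 5),
}


def segmentation_recovery_study(n_seeds: int = 50, seed: int = 1
                                ) -> dict[str, float]:
    """How often BIC assigns the true composition to cluster means
    generated under a global, a field-specific (opposite-sign) and the
    mixed (field-specific in the dry season only) segmentation."""
    cfg = PipelineConfig(seed=seed)
    weather, soil, schedule, design, ed = build_source_inputs(cfg)
    X = ed.values.T
    X.index = design.index
    out = {}
    for name, (segs, true_comp) in _SEG_SCENARIOS.items():
        hits = 0
        for s in range(n_seeds):
            rng = np.random.default_rng(seed + 2000 + 17 * s)
            specs = default_cluster_specs(ed, cfg, rng,
                                          segmentations=segs)
            spec = specs[s % len(specs)]
            if name == "field":
                terms = spec.equations["field=irrigated"]
                spec.equations = {
                    "field=irrigated": terms,
                    "field=rainfed": [(p, -c) for p, c in terms]}
            sig = cluster_signal(spec, ed.values, design)
            sig = sig / sig.std(ddof=1)
            y = sig + rng.normal(0.0, 0.25 / np.sqrt(2), len(sig))
            res = select_piecewise(X, y, design, seed=seed + s)
            hits += res.model.composition_id == true_comp
        out[f"{name}_rate"] = hits / n_seeds
    out["n"] = n_seeds
    return out


# ---------------------------------------------------------------------------
# Transfer soundness
# ---------------------------------------------------------------------------

def transfer_soundness_study(n_seeds: int = 100, seed: int = 1
                             ) -> dict[str, float]:
    """Sign-constraint soundness (flipped targets never retained),
    self-transfer R² agreement, and null-model rate on noise targets."""
    X_target, design = simulate_target_inputs(seed=seed)
    strata = design["time_of_day"].to_numpy()
    ids = list(X_target.index)
    rng = np.random.default_rng(seed)

    violations = 0
    for s in range(n_seeds):
        pid = ids[int(rng.integers(0, len(ids)))]
        y = -1.0 * X_target.loc[pid].to_numpy() \
            + rng.normal(0, 0.1, X_target.shape[1])
        res = transfer_model([(pid, 1.0)], X_target.T, y, strata=strata,
                             seed=seed + s)
        violations += any(p == pid for p, _ in res.retained_terms)

    max_r2_dev = 0.0
    for s in range(10):
        chosen = rng.choice(len(ids), 3, replace=False)
        terms = [(ids[i], float(rng.choice([-1, 1]) * rng.uniform(0.4, 1)))
                 for i in chosen]
        y = sum(c * X_target.loc[p].to_numpy() for p, c in terms)
        y = y + rng.normal(0, 0.05, len(y))
        sub = [p for p, _ in terms]
        Xs = X_target.T[sub].to_numpy()
        beta = np.linalg.lstsq(Xs, y, rcond=None)[0]
        source_r2 = 1 - ((y - Xs @ beta) ** 2).sum() / (y ** 2).sum()
        res = transfer_model(list(zip(sub, beta)), X_target.T, y,
                             strata=strata, seed=seed + s)
        if set(p for p, _ in res.retained_terms) == set(sub):
            max_r2_dev = max(max_r2_dev, abs(res.r2 - source_r2))
        else:
            max_r2_dev = np.inf

    nulls = 0
    for s in range(n_seeds):
        chosen = rng.choice(len(ids), 3, replace=False)
        terms = [(ids[i], float(rng.choice([-1, 1]) * rng.uniform(0.4, 1)))
                 for i in chosen]
        y = np.random.default_rng(seed + 5000 + s).normal(
            0, 1, X_target.shape[1])
        res = transfer_model(terms, X_target.T, y, strata=strata,
                             seed=seed + s)
        nulls += res.null
    return {
        "sign_violations": float(violations),
        "self_transfer_r2_max_dev": float(max_r2_dev),
        "noise_null_rate": nulls / n_seeds,
        "n": n_seeds,
    }


# ---------------------------------------------------------------------------
# Determinism
# ---------------------------------------------------------------------------

def determinism_check(workdir, config_path=None, seed: int = 0) -> bool:
    """Run the small end-to-end configuration twice with the same seed and
    compare every output byte for byte."""
    from pathlib import Path

    from .pipeline import run
    if config_path is None:
        config_path = Path(__file__).resolve().parents[2] \
            / "configs" / "tiny.yaml"
    if Path(config_path).exists():
        cfg = PipelineConfig.from_yaml(config_path)
    else:
        cfg = PipelineConfig(n_clusters=4, genes_per_cluster=15,
                             n_low_cv_genes=10, n_low_mean_genes=10,
                             n_background_genes=120, k_max=8)
    cfg.seed = seed
    workdir = Path(workdir)
    run(cfg, workdir / "a")
    run(cfg, workdir / "b")
    for f in sorted((workdir / "a").iterdir()):
        if (workdir / "b" / f.name).read_bytes() != f.read_bytes():
            return False
    return True
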