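"""Piecewise linear ED-model selection.

For each cluster-mean profile the selector (i) finds a stable candidate set
of ED parameters by lasso stability selection over B subsamples, (ii)
exhaustively fits every admissible equation of one to three candidates
(parameters correlated above a cap may not share an equation) scoring each
by repeated cross-validated MSE and BIC, (iii) does so for every season /
field segment of the design and assembles the eight piecewise compositions
(one global equation up to four segment equations), and (iv) picks the
composition minimizing BIC computed on the pooled cross-validation
residuals with the summed parameter count.  The candidate-selection step is
repeated on season and field subsets of the data, and the final model is
the BIC argmin of the three passes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import lars_path
from sklearn.utils.validation import check_is_fitted

#: Floor applied to MSE inside the BIC: fits below this are numerically
#: perfect and compared by parsimony alone rather than by noise-level
#: differences in ~1e-30 residuals.
_MSE_FLOOR = 1e-12


@dataclass
class SelectionConfig:
    """Stability-selection and cross-validation settings.

    ``ev`` bounds the expected number of false selections; together with the
    selection-frequency ``threshold`` it fixes the number of variables kept
    per subsample path through q = floor(sqrt(ev * (2*threshold - 1) * p)).
    """

    B: int = 300
    ev: float = 2.0
    threshold: float = 0.65
    fraction: float = 0.85
    max_terms: int = 3
    corr_cap: float = 0.85
    cv_folds: int = 5
    cv_repeats: int = 5
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.fraction <= 1):
            raise ValueError("fraction must be in (0, 1]")
        if not (0.5 < self.threshold <= 1):
            raise ValueError("threshold must be in (0.5, 1]")
        if self.B < 1:
            raise ValueError("B must be >= 1")


#: Standard settings for the season / field subset passes.
SUBSET_CONFIG = SelectionConfig(threshold=0.7, fraction=0.7)


@dataclass
class LinearEDEquation:
    """A <=3-term linear equation fitted without intercept on centered data."""

    terms: Sequence[tuple[str, float]]
    mse: float
    bic: float
    sq_residuals: np.ndarray
    n: int

    @property
    def parameter_ids(self) -> tuple[str, ...]:
        return tuple(pid for pid, _ in self.terms)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        out = np.zeros(len(X))
        for pid, coef in self.terms:
            out += coef * X[pid].to_numpy()
        return out


@dataclass
class PiecewiseEDModel:
    """A segmentation of the design plus one equation per segment."""

    composition_id: int
    segment_labels: Sequence[str]
    equations: Mapping[str, LinearEDEquation]
    mse: float
    p: int
    bic: float
    n: int

    def predict(self, X: pd.DataFrame, design: pd.DataFrame) -> np.ndarray:
        out = np.zeros(len(X))
        for label, eq in self.equations.items():
            mask = segment_mask(label, design)
            out[mask] = eq.predict(X.loc[mask])
        return out

    def r2(self, X: pd.DataFrame, y: np.ndarray,
           design: pd.DataFrame) -> float:
        """Variance explained by the full-data refit of the model."""
        pred = np.zeros(len(X))
        for label, eq in self.equations.items():
            mask = segment_mask(label, design)
            ids = list(eq.parameter_ids)
            if ids:
                Xs = X.loc[mask, ids].to_numpy()
                beta, *_ = np.linalg.lstsq(Xs, y[mask], rcond=None)
                pred[mask] = Xs @ beta
        sst = float(np.sum(y**2))
        if sst == 0:
            return 0.0
        return 1.0 - float(np.sum((y - pred) ** 2)) / sst


@dataclass
class SelectionResult:
    model: PiecewiseEDModel
    pass_models: Mapping[str, PiecewiseEDModel]
    candidate_sets: Mapping[str, tuple[str, ...]]
    composition_bics: Mapping[str, Mapping[int, float]]
    null_model: bool = False
    fallback: bool = False


# ---------------------------------------------------------------------------
# Segmentation machinery
# ---------------------------------------------------------------------------

def segment_mask(label: str, design: pd.DataFrame) -> np.ndarray:
    """Boolean mask for a segment label like ``"season=dry|field=rainfed"``;
    ``"all"`` selects everything."""
    if label == "all":
        return np.ones(len(design), dtype=bool)
    mask = np.ones(len(design), dtype=bool)
    for clause in label.split("|"):
        key, value = clause.split("=")
        mask &= (design[key].astype(str) == value).to_numpy()
    return mask


def two_factor_compositions(factor_a: str = "season",
                            levels_a: Sequence[str] = ("dry", "wet"),
                            factor_b: str = "field",
                            levels_b: Sequence[str] = ("irrigated", "rainfed"),
                            ) -> dict[int, list[str]]:
    """The eight candidate segmentations of a 2x2 design: one piece, split
    by either factor, the four mixed three-piece forms, and four pieces."""
    a1, a2 = (f"{factor_a}={v}" for v in levels_a)
    b1, b2 = (f"{factor_b}={v}" for v in levels_b)

    def cell(a, b):
        return f"{a}|{b}"

    return {
        1: ["all"],
        2: [a1, a2],
        3: [b1, b2],
        4: [a1, cell(a2, b1), cell(a2, b2)],
        5: [a2, cell(a1, b1), cell(a1, b2)],
        6: [b1, cell(a1, b2), cell(a2, b2)],
        7: [b2, cell(a1, b1), cell(a2, b1)],
        8: [cell(a1, b1), cell(a1, b2), cell(a2, b1), cell(a2, b2)],
    }


def one_factor_compositions(factor: str = "season",
                            levels: Sequence[str] = ("dry", "wet"),
                            ) -> dict[int, list[str]]:
    """Season-independent vs. season-specific segmentations (used for the
    single-field analysis)."""
    return {1: ["all"], 2: [f"{factor}={v}" for v in levels]}


# ---------------------------------------------------------------------------
# Cross-validation and information criterion
# ---------------------------------------------------------------------------

def make_folds(n: int, folds: int, repeats: int, rng: np.random.Generator,
               strata: np.ndarray | None = None) -> np.ndarray:
    """(repeats, n) array of fold labels, stratified so every fold spans all
    strata (season x field cells)."""
    if strata is None:
        strata = np.zeros(n, dtype=int)
    strata = np.asarray(strata)
    out = np.empty((repeats, n), dtype=int)
    for r in range(repeats):
        for s in np.unique(strata):
            idx = np.where(strata == s)[0]
            perm = rng.permutation(idx)
            out[r, perm] = np.arange(len(perm)) % folds
    return out


def _fit_beta(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    # normal equations are safe here: designs are tiny (<= 3 standardized,
    # not-too-collinear columns); fall back to lstsq on singularity
    try:
        return np.linalg.solve(X.T @ X, X.T @ y)
    except np.linalg.LinAlgError:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return beta


def cv_sq_residuals(X: np.ndarray, y: np.ndarray,
                    fold_labels: np.ndarray) -> np.ndarray:
    """Pooled out-of-fold squared residuals of the no-intercept least-squares
    fit, concatenated over repeats (length repeats * n)."""
    repeats, n = fold_labels.shape
    out = np.empty(repeats * n)
    for r in range(repeats):
        labels = fold_labels[r]
        for f in np.unique(labels):
            test = labels == f
            if X.shape[1]:
                beta = _fit_beta(X[~test], y[~test])
                resid = y[test] - X[test] @ beta
            else:
                resid = y[test]
            out[r * n:(r + 1) * n][test] = resid**2
    return out


def cv_mse(X: np.ndarray, y: np.ndarray, fold_labels: np.ndarray
           ) -> tuple[float, np.ndarray]:
    sq = cv_sq_residuals(X, y, fold_labels)
    return float(sq.mean()), sq


def bic(mse: float, n: int, p: int) -> float:
    """n * ln(MSE) + p * ln(n); no intercept is counted (all data centered).

    MSEs below a small floor count as perfect fits so that noiseless models
    are compared by their complexity penalty only.
    """
    return n * math.log(max(mse, _MSE_FLOOR)) + p * math.log(n)


def composite_mse(sq_residual_vectors: Sequence[np.ndarray]) -> float:
    """MSE of a piecewise model: mean of the concatenated per-segment
    squared-residual vectors (the sample-size-weighted mean of segment
    MSEs)."""
    return float(np.concatenate(sq_residual_vectors).mean())


# ---------------------------------------------------------------------------
# Stability selection
# ---------------------------------------------------------------------------

def stability_q(ev: float, threshold: float, p_total: int) -> int:
    """Per-subsample active-set size from the expected-false-selection bound
    q^2 <= ev * (2*threshold - 1) * p_total."""
    return max(1, int(math.floor(math.sqrt(ev * (2 * threshold - 1) * p_total))))


def _lasso_entry_set(X: np.ndarray, y: np.ndarray, q: int) -> set[int]:
    """Indices of the first q variables to enter the lasso (LARS) path.

    A lean LARS implementation with the lasso modification (sign-crossing
    variables are dropped and may re-enter); only the order of first entry
    is tracked, and the path stops once q distinct variables have entered.
    Falls back to sklearn's ``lars_path`` on numerical failure.
    """
    try:
        return _lasso_entry_set_fast(X.T @ X, X.T @ y, q)
    except np.linalg.LinAlgError:
        return _lasso_entry_set_sklearn(X, y, q)


_TINY = 1e-12


def _lasso_entry_set_fast(G: np.ndarray, Xty: np.ndarray, q: int) -> set[int]:
    p = len(Xty)
    beta = np.zeros(p)
    active: list[int] = []
    entered: list[int] = []
    drop_ban: int | None = None   # just-dropped variable may not re-enter now
    for _ in range(8 * q + 16):
        c = Xty - G @ beta
        inactive = np.ones(p, dtype=bool)
        if active:
            inactive[active] = False
        if not inactive.any():
            break
        C = np.abs(c).max()
        if C < _TINY:
            break
        # entering variable: inactive index achieving the maximal |c|
        cand = np.where(inactive & (np.abs(c) >= C - 1e-10 * max(C, 1.0)))[0]
        cand = cand[cand != drop_ban] if drop_ban is not None else cand
        if cand.size:
            j = int(cand[0])
            active.append(j)
            if j not in entered:
                entered.append(j)
                if len(entered) >= q:
                    break
        drop_ban = None
        A = np.array(active)
        sA = np.sign(c[A])
        sA[sA == 0] = 1.0
        GA = G[np.ix_(A, A)]
        w = np.linalg.solve(GA + _TINY * np.eye(len(A)), sA)
        denom = float(sA @ w)
        if denom <= _TINY:
            raise np.linalg.LinAlgError("degenerate equiangular direction")
        aa = 1.0 / math.sqrt(denom)
        wA = aa * w                      # beta-direction on the active set
        a = G[:, A] @ wA                 # d|c|/d(gamma) for all variables
        CA = np.abs(c[A]).max()
        # max step: all inactive correlations catch up with the active ones
        gamma = CA / aa
        if inactive.any():
            ci, ai = c[inactive], a[inactive]
            for num, den in ((CA - ci, aa - ai), (CA + ci, aa + ai)):
                ok = den > _TINY
                if ok.any():
                    g = (num[ok] / den[ok])
                    g = g[g > _TINY]
                    if g.size:
                        gamma = min(gamma, g.min())
        # lasso modification: drop an active variable whose coefficient
        # would cross zero before gamma
        drop_idx = None
        dirs = wA
        cross = -beta[A] / np.where(np.abs(dirs) > _TINY, dirs, np.inf)
        pos = (cross > _TINY) & (cross < gamma - _TINY)
        if pos.any():
            k = int(np.argmin(np.where(pos, cross, np.inf)))
            gamma = float(cross[k])
            drop_idx = k
        beta[A] += gamma * dirs
        if drop_idx is not None:
            dropped = active.pop(drop_idx)
            beta[dropped] = 0.0
            drop_ban = dropped
    return set(entered[:q])


def _lasso_entry_set_sklearn(X: np.ndarray, y: np.ndarray, q: int
                             ) -> set[int]:
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    coefs = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for max_iter in (q + 8, q + 2, q):
            try:
                _, _, coefs = lars_path(X, y, method="lasso",
                                        max_iter=max_iter)
                break
            except ValueError:
                continue
        if coefs is None:
            from sklearn.linear_model import lasso_path
            _, coefs, _ = lasso_path(X, y, n_alphas=100, eps=1e-4)
    entered: list[int] = []
    seen = set()
    for step in range(coefs.shape[1]):
        for j in np.where(coefs[:, step] != 0)[0]:
            if j not in seen:
                seen.add(j)
                entered.append(j)
        if len(entered) >= q:
            break
    return set(entered[:q])


def stability_select(X: pd.DataFrame, y: np.ndarray,
                     cfg: SelectionConfig,
                     rng: np.random.Generator | None = None
                     ) -> tuple[tuple[str, ...], pd.Series]:
    """Stable parameter set: parameters selected (among the first q to enter
    the lasso path) in at least ``cfg.threshold`` of ``cfg.B`` subsamples of
    size ``cfg.fraction * n``.

    Returns (selected ids, per-parameter selection frequency).
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n, p = X.shape
    m = int(round(cfg.fraction * n))
    if m < cfg.max_terms + 2:
        raise ValueError(f"subsample size {m} too small")
    q = stability_q(cfg.ev, cfg.threshold, p)
    Xv = X.to_numpy(dtype=float)
    counts = np.zeros(p)
    idx_all = np.stack([rng.choice(n, size=m, replace=False)
                        for _ in range(cfg.B)])
    # batched standardization and Gram computation over all subsamples
    Xg = Xv[idx_all]                                   # (B, m, p)
    mu = Xg.mean(axis=1, keepdims=True)
    sd = Xg.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Xg = (Xg - mu) / sd
    yg = y[idx_all]
    yg = yg - yg.mean(axis=1, keepdims=True)
    G_all = np.matmul(Xg.transpose(0, 2, 1), Xg)       # (B, p, p)
    Xty_all = np.matmul(Xg.transpose(0, 2, 1), yg[:, :, None])[:, :, 0]
    for b in range(cfg.B):
        try:
            selected_b = _lasso_entry_set_fast(G_all[b], Xty_all[b], q)
        except np.linalg.LinAlgError:
            selected_b = _lasso_entry_set_sklearn(Xg[b], yg[b], q)
        for j in selected_b:
            counts[j] += 1
    freq = pd.Series(counts / cfg.B, index=X.columns, name="frequency")
    selected = tuple(X.columns[counts / cfg.B >= cfg.threshold])
    return selected, freq


# ---------------------------------------------------------------------------
# Exhaustive equation search
# ---------------------------------------------------------------------------

def enumerate_equations(candidates: Sequence[str], corr: pd.DataFrame,
                        max_terms: int = 3, corr_cap: float = 0.85
                        ) -> list[tuple[str, ...]]:
    """All parameter subsets of size 1..max_terms that contain no pair
    correlated above ``corr_cap`` in absolute value."""
    candidates = list(candidates)
    banned = set()
    for a, b in itertools.combinations(candidates, 2):
        if abs(corr.loc[a, b]) > corr_cap:
            banned.add(frozenset((a, b)))
    out = []
    for size in range(1, max_terms + 1):
        for subset in itertools.combinations(candidates, size):
            if not any(frozenset(pair) in banned
                       for pair in itertools.combinations(subset, 2)):
                out.append(subset)
    return out


def prune_correlated_candidates(candidates: Sequence[str], X: pd.DataFrame,
                                y: np.ndarray, fold_labels: np.ndarray,
                                corr_cap: float = 0.85) -> list[str]:
    """Among each pair of candidates correlated above the cap, keep the one
    whose single-parameter model has the lower cross-validated MSE.

    Pairs are resolved in descending |r| order, so correlation chains reduce
    deterministically.
    """
    kept = list(candidates)
    if len(kept) < 2:
        return kept
    corr = X[kept].corr()
    pairs = sorted(
        ((abs(corr.loc[a, b]), a, b)
         for a, b in itertools.combinations(kept, 2)
         if abs(corr.loc[a, b]) > corr_cap),
        key=lambda t: (-t[0], t[1], t[2]))
    mse_cache: dict[str, float] = {}

    def single_mse(pid: str) -> float:
        if pid not in mse_cache:
            mse_cache[pid], _ = cv_mse(
                X[[pid]].to_numpy(), y, fold_labels)
        return mse_cache[pid]

    removed: set[str] = set()
    for _, a, b in pairs:
        if a in removed or b in removed:
            continue
        removed.add(b if single_mse(a) <= single_mse(b) else a)
    return [c for c in kept if c not in removed]


def select_equation(X: pd.DataFrame, y: np.ndarray,
                    candidates: Sequence[str], cfg: SelectionConfig,
                    fold_labels: np.ndarray,
                    bic_n: int | None = None) -> LinearEDEquation:
    """Best-BIC equation over all admissible subsets of the candidates
    (including the empty/null equation), scored by repeated-CV MSE with
    shared folds; coefficients refitted on the full segment."""
    n = len(y)
    bic_n = bic_n or n
    pruned = prune_correlated_candidates(candidates, X, y, fold_labels,
                                         corr_cap=cfg.corr_cap)
    subsets: list[tuple[str, ...]] = [()]
    if pruned:
        corr = X[pruned].corr()
        subsets += enumerate_equations(pruned, corr, cfg.max_terms,
                                       cfg.corr_cap)
    best = None
    for subset in subsets:
        Xs = X[list(subset)].to_numpy() if subset else np.empty((n, 0))
        mse, sq = cv_mse(Xs, y, fold_labels)
        score = (bic(mse, bic_n, len(subset)), len(subset), tuple(sorted(subset)))
        if best is None or score < best[0]:
            best = (score, subset, mse, sq)
    score, subset, mse, sq = best
    if subset:
        beta = _fit_beta(X[list(subset)].to_numpy(), y)
        terms = list(zip(subset, beta))
    else:
        terms = []
    return LinearEDEquation(terms=terms, mse=mse, bic=score[0],
                            sq_residuals=sq, n=n)


# ---------------------------------------------------------------------------
# Piecewise model assembly
# ---------------------------------------------------------------------------

def _pass_model(X: pd.DataFrame, y: np.ndarray, design: pd.DataFrame,
                candidates: Sequence[str], cfg: SelectionConfig,
                compositions: Mapping[int, Sequence[str]],
                rng: np.random.Generator,
                ) -> tuple[PiecewiseEDModel, dict[int, float]]:
    n = len(y)
    strata = (design["season"].astype(str) + "|"
              + design["field"].astype(str)).to_numpy() \
        if {"season", "field"} <= set(design.columns) \
        else design.iloc[:, 0].astype(str).to_numpy()
    # one equation per distinct segment label across all compositions
    labels = sorted({lab for segs in compositions.values() for lab in segs})
    equations: dict[str, LinearEDEquation] = {}
    for lab in labels:
        mask = segment_mask(lab, design)
        if not mask.any():
            raise ValueError(f"design cell {lab!r} is empty")
        folds = make_folds(int(mask.sum()), cfg.cv_folds, cfg.cv_repeats,
                           rng, strata=strata[mask])
        equations[lab] = select_equation(
            X.loc[mask], y[mask], candidates, cfg, folds)
    models = {}
    bics = {}
    for cid, segs in sorted(compositions.items()):
        mse = composite_mse([equations[lab].sq_residuals for lab in segs])
        p = sum(len(equations[lab].terms) for lab in segs)
        b = bic(mse, n, p)
        models[cid] = PiecewiseEDModel(
            composition_id=cid, segment_labels=tuple(segs),
            equations={lab: equations[lab] for lab in segs},
            mse=mse, p=p, bic=b, n=n)
        bics[cid] = b
    winner = min(models.values(), key=lambda m: (m.bic, m.p, m.composition_id))
    return winner, bics


def select_piecewise(X: pd.DataFrame, y: np.ndarray, design: pd.DataFrame,
                     cfg: SelectionConfig | None = None,
                     subset_cfg: SelectionConfig | None = None,
                     compositions: Mapping[int, Sequence[str]] | None = None,
                     subset_factors: Sequence[str] = ("season", "field"),
                     seed: int | None = None) -> SelectionResult:
    """Full piecewise selection for one cluster mean over the design.

    Three candidate-selection passes — global, pooled per-``season`` and
    pooled per-``field`` subsets — each followed by the exhaustive piecewise
    search; the final model is the BIC argmin of the three pass winners.
    """
    cfg = cfg or SelectionConfig()
    subset_cfg = subset_cfg or SUBSET_CONFIG
    if compositions is None:
        compositions = two_factor_compositions(
            subset_factors[0], sorted(design[subset_factors[0]].unique()),
            subset_factors[1], sorted(design[subset_factors[1]].unique()))
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    candidate_sets: dict[str, tuple[str, ...]] = {}
    stable, _ = stability_select(X, y, cfg, rng)
    candidate_sets["global"] = stable
    for factor in subset_factors:
        pool: list[str] = []
        for level in sorted(design[factor].astype(str).unique()):
            mask = (design[factor].astype(str) == level).to_numpy()
            sel, _ = stability_select(X.loc[mask], y[mask], subset_cfg, rng)
            pool.extend(s for s in sel if s not in pool)
        candidate_sets[f"{factor}-pool"] = tuple(pool)

    pass_models: dict[str, PiecewiseEDModel] = {}
    composition_bics: dict[str, dict[int, float]] = {}
    for name, cands in candidate_sets.items():
        model, bics = _pass_model(X, y, design, cands, cfg,
                                  compositions, rng)
        pass_models[name] = model
        composition_bics[name] = bics
    order = list(candidate_sets)
    final = min(pass_models.items(),
                key=lambda kv: (kv[1].bic, kv[1].p, order.index(kv[0])))[1]
    null = all(not eq.terms for eq in final.equations.values())
    fallback = all(len(c) == 0 for c in candidate_sets.values())
    return SelectionResult(model=final, pass_models=pass_models,
                           candidate_sets=candidate_sets,
                           composition_bics=composition_bics,
                           null_model=null, fallback=fallback)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

class StabilitySelector(BaseEstimator):
    """Lasso stability selection as a fit-shaped feature selector.

    After ``fit(X, y)`` (X a DataFrame of samples x parameters),
    ``support_`` holds the boolean mask of stable parameters,
    ``frequencies_`` the per-parameter selection frequency.
    """

    def __init__(self, B: int = 300, ev: float = 2.0, threshold: float = 0.65,
                 fraction: float = 0.85, random_state: int = 0):
        self.B = B
        self.ev = ev
        self.threshold = threshold
        self.fraction = fraction
        self.random_state = random_state

    def _config(self) -> SelectionConfig:
        return SelectionConfig(B=self.B, ev=self.ev, threshold=self.threshold,
                               fraction=self.fraction, seed=self.random_state)

    def fit(self, X, y):
        X = pd.DataFrame(X)
        selected, freq = stability_select(X, np.asarray(y, dtype=float),
                                          self._config())
        self.selected_ = selected
        self.frequencies_ = freq
        self.support_ = np.array([c in selected for c in X.columns])
        return self

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        return pd.DataFrame(X).loc[:, self.support_]


class PiecewiseEDRegressor(BaseEstimator, RegressorMixin):
    """Piecewise linear ED model with BIC composition choice, as an
    estimator.

    ``fit(X, y, design=...)`` expects X as a DataFrame of samples x ED
    parameters and ``design`` with the segmentation factors (season, field)
    per sample.  Fitted attributes: ``result_`` (full
    :class:`SelectionResult`), ``composition_`` (chosen segmentation id),
    ``equations_``, ``bic_``, ``mse_``.
    """

    def __init__(self, B: int = 300, ev: float = 2.0, threshold: float = 0.65,
                 fraction: float = 0.85, subset_threshold: float = 0.7,
                 subset_fraction: float = 0.7, max_terms: int = 3,
                 corr_cap: float = 0.85, cv_folds: int = 5,
                 cv_repeats: int = 5, subset_factors=("season", "field"),
                 single_factor: bool = False, random_state: int = 0):
        self.B = B
        self.ev = ev
        self.threshold = threshold
        self.fraction = fraction
        self.subset_threshold = subset_threshold
        self.subset_fraction = subset_fraction
        self.max_terms = max_terms
        self.corr_cap = corr_cap
        self.cv_folds = cv_folds
        self.cv_repeats = cv_repeats
        self.subset_factors = subset_factors
        self.single_factor = single_factor
        self.random_state = random_state

    def fit(self, X, y, design: pd.DataFrame = None):
        if design is None:
            raise ValueError("fit requires the design metadata")
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        common = dict(max_terms=self.max_terms, corr_cap=self.corr_cap,
                      cv_folds=self.cv_folds, cv_repeats=self.cv_repeats,
                      seed=self.random_state)
        cfg = SelectionConfig(B=self.B, ev=self.ev, threshold=self.threshold,
                              fraction=self.fraction, **common)
        sub = SelectionConfig(B=self.B, ev=self.ev,
                              threshold=self.subset_threshold,
                              fraction=self.subset_fraction, **common)
        if self.single_factor:
            factor = self.subset_factors[0]
            comps = one_factor_compositions(
                factor, sorted(design[factor].astype(str).unique()))
            factors = (factor,)
        else:
            comps = None
            factors = tuple(self.subset_factors)
        self.result_ = select_piecewise(
            X, y, design, cfg=cfg, subset_cfg=sub, compositions=comps,
            subset_factors=factors, seed=self.random_state)
        model = self.result_.model
        self.composition_ = model.composition_id
        self.equations_ = model.equations
        self.bic_ = model.bic
        self.mse_ = model.mse
        self.design_ = design
        self.X_columns_ = list(X.columns)
        return self

    def predict(self, X, design: pd.DataFrame = None):
        check_is_fitted(self, "result_")
        design = design if design is not None else self.design_
        return self.result_.model.predict(pd.DataFrame(X), design)

    def r2(self, X, y, design: pd.DataFrame = None) -> float:
        check_is_fitted(self, "result_")
        design = design if design is not None else self.design_
        return self.result_.model.r2(pd.DataFrame(X),
                                     np.asarray(y, dtype=float), design)
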