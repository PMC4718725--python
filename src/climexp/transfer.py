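"""Cross-dataset model transfer under sign constraints.

A source model (selected on the irrigated-field, two-season data) is tested
on a target dataset sampled at several times of day: the target expression
and parameters are centered per time-of-day stratum to remove circadian
offsets, then every subset of the source parameters (including the empty
model) is refitted without intercept, subsets whose refitted coefficient
signs disagree with the source are discarded, and the BIC argmin is kept.
Transferability is only assessed for clusters whose source model is
season-independent and explains more than half of the cluster-mean
variance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .selection import (LinearEDEquation, SelectionConfig, SelectionResult,
                        bic, cv_mse, make_folds, select_equation)


def center_by_time_of_day(values: pd.DataFrame,
                          time_of_day: pd.Series) -> pd.DataFrame:
    """Center each row within every time-of-day stratum (mean 0 per
    stratum), eliminating circadian-clock offsets between sampling hours."""
    out = values.copy().astype(float)
    labels = time_of_day.astype(str)
    for tod in labels.unique():
        cols = values.columns[(labels == tod).to_numpy()]
        block = out[cols]
        out[cols] = block.sub(block.mean(axis=1), axis=0)
    return out


def eligible_source_models(results: Mapping[int, SelectionResult],
                           r2: Mapping[int, float],
                           season_independent_ids: Sequence[int] = (1,),
                           min_r2: float = 0.5) -> list[int]:
    """Clusters whose chosen composition is season-independent and whose
    model explains more than ``min_r2`` of the cluster-mean variance."""
    out = []
    for cid, res in results.items():
        if res.model.composition_id in season_independent_ids \
                and r2[cid] > min_r2:
            out.append(cid)
    return sorted(out)


@dataclass
class TransferResult:
    cluster_id: int | None
    source_terms: Sequence[tuple[str, float]]
    retained_terms: Sequence[tuple[str, float]]
    r2: float
    bic: float
    null: bool


def transfer_model(source_terms: Sequence[tuple[str, float]],
                   X_target: pd.DataFrame, y_target: np.ndarray,
                   cfg: SelectionConfig | None = None,
                   strata: np.ndarray | None = None,
                   cluster_id: int | None = None,
                   seed: int | None = None) -> TransferResult:
    """Refit combinations of the source parameters on the target and keep
    the BIC-best subset whose coefficients keep the source signs.

    ``X_target`` is samples x parameters (already centered per time of
    day); the empty (null) model is always admissible.
    """
    cfg = cfg or SelectionConfig()
    y = np.asarray(y_target, dtype=float)
    n = len(y)
    for pid, _ in source_terms:
        if pid not in X_target.columns:
            raise KeyError(f"source parameter {pid!r} absent from target")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    folds = make_folds(n, cfg.cv_folds, cfg.cv_repeats, rng, strata=strata)
    source_sign = {pid: np.sign(coef) for pid, coef in source_terms}
    ids = [pid for pid, _ in source_terms]
    best = None
    for size in range(0, len(ids) + 1):
        for subset in itertools.combinations(ids, size):
            if subset:
                Xs = X_target[list(subset)].to_numpy()
                beta = np.linalg.lstsq(Xs, y, rcond=None)[0]
                if any(np.sign(b) != source_sign[pid]
                       for pid, b in zip(subset, beta)):
                    continue
            else:
                Xs = np.empty((n, 0))
                beta = np.array([])
            mse, _ = cv_mse(Xs, y, folds)
            score = (bic(mse, n, size), size, subset)
            if best is None or score < best[0]:
                best = (score, subset, beta)
    score, subset, beta = best
    pred = (X_target[list(subset)].to_numpy() @ beta) if subset \
        else np.zeros(n)
    sst = float(np.sum(y**2))
    r2 = 1.0 - float(np.sum((y - pred) ** 2)) / sst if sst else 0.0
    retained = list(zip(subset, beta))
    return TransferResult(cluster_id=cluster_id,
                          source_terms=list(source_terms),
                          retained_terms=retained, r2=r2, bic=score[0],
                          null=not retained)


def independent_target_analysis(X_target: pd.DataFrame,
                                y_target: np.ndarray,
                                candidates: Sequence[str] | None = None,
                                cfg: SelectionConfig | None = None,
                                strata: np.ndarray | None = None,
                                seed: int | None = None) -> LinearEDEquation:
    """Single-equation model selection on the target alone: one equation
    common to all time-of-day profiles, chosen from all <=3-parameter
    regressions by BIC (no piecewise compositions)."""
    cfg = cfg or SelectionConfig()
    y = np.asarray(y_target, dtype=float)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    folds = make_folds(len(y), cfg.cv_folds, cfg.cv_repeats, rng,
                       strata=strata)
    cands = list(candidates) if candidates is not None \
        else list(X_target.columns)
    return select_equation(X_target, y, cands, cfg, folds)


class SignConstrainedTransferRegressor(BaseEstimator, RegressorMixin):
    """Sign-constrained transfer of a fitted source equation, fit-shaped.

    Construct with the source terms; ``fit(X, y)`` runs the subset search
    on the target.  Fitted attributes: ``result_`` (TransferResult),
    ``retained_terms_``, ``r2_``, ``null_``.
    """

    def __init__(self, source_terms: Sequence[tuple[str, float]] = (),
                 cv_folds: int = 5, cv_repeats: int = 5,
                 random_state: int = 0):
        self.source_terms = source_terms
        self.cv_folds = cv_folds
        self.cv_repeats = cv_repeats
        self.random_state = random_state

    def fit(self, X, y, strata: np.ndarray | None = None):
        cfg = SelectionConfig(cv_folds=self.cv_folds,
                              cv_repeats=self.cv_repeats,
                              seed=self.random_state)
        self.result_ = transfer_model(list(self.source_terms),
                                      pd.DataFrame(X),
                                      np.asarray(y, dtype=float),
                                      cfg=cfg, strata=strata)
        self.retained_terms_ = self.result_.retained_terms
        self.r2_ = self.result_.r2
        self.null_ = self.result_.null
        return self

    def predict(self, X):
        check_is_fitted(self, "result_")
        X = pd.DataFrame(X)
        out = np.zeros(len(X))
        for pid, coef in self.retained_terms_:
            out += coef * X[pid].to_numpy()
        return out
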