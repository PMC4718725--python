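"""Counts-to-analysis preprocessing.

Stages, in fixed order: median-of-ratios size factors, detection filter on
genotype x season subsets, log2(x+1), replicate averaging, CV and mean
filters, per-genotype/season centering and per-gene whole-profile scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

STAGES = ("counts", "normalized", "log", "replicate-averaged",
          "centered", "scaled")

REQUIRED_META = ("season", "field", "genotype", "replicate",
                 "timepoint", "timestamp")


class CannotNormalizeError(ValueError):
    """No gene has positive counts in every sample."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample metadata.

    ``values`` is a DataFrame indexed by gene id; ``meta`` is indexed by
    sample id and aligned with the value columns.  ``stage`` tracks where
    in the fixed preprocessing order the values currently sit.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    stage: str = "counts"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if list(self.values.columns) != list(self.meta.index):
            raise ValueError("value columns do not match metadata index")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    def _advance(self, values: pd.DataFrame, meta: pd.DataFrame,
                 stage: str) -> "ExpressionMatrix":
        if STAGES.index(stage) < STAGES.index(self.stage):
            raise ValueError(
                f"stage regression: {self.stage} -> {stage}")
        return ExpressionMatrix(values=values, meta=meta, stage=stage)


def check_metadata(meta: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_META if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata lacks columns: {missing}")
    if meta[list(REQUIRED_META)].isna().any().any():
        raise ValueError("sample metadata has missing entries")


@dataclass
class FilterReport:
    """Per-stage accounting of removed genes."""

    stages: list = dc_field(default_factory=list)  # (label, removed, retained)

    def record(self, label: str, n_in: int, n_out: int) -> None:
        self.stages.append({"stage": label, "input": n_in,
                            "removed": n_in - n_out, "retained": n_out})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For genes with a positive geometric mean across samples, the factor of
    sample j is the median of counts_gj / geomean_g.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise CannotNormalizeError(
            "no gene has positive counts in every sample")
    ref = counts.loc[positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref).sub(log_geomean, axis=0)
    return np.exp(ratios.median(axis=0)).rename("size_factor")


def normalize_counts(counts: pd.DataFrame, meta: pd.DataFrame) -> ExpressionMatrix:
    factors = size_factors(counts)
    return ExpressionMatrix(values=counts / factors, meta=meta,
                            stage="normalized")


def detection_filter(em: ExpressionMatrix, max_undetected: int = 40,
                     report: FilterReport | None = None) -> ExpressionMatrix:
    """Keep genes detected (value > 0) in enough samples of every
    genotype x season subset; a gene undetected in more than
    ``max_undetected`` samples of any subset is removed."""
    check_metadata(em.meta)
    keep = pd.Series(True, index=em.values.index)
    for _, subset in em.meta.groupby(["genotype", "season"], observed=True):
        undetected = (em.values[subset.index] <= 0).sum(axis=1)
        keep &= undetected <= max_undetected
    out = em._advance(em.values.loc[keep], em.meta, em.stage)
    if report is not None:
        report.record("detection", len(em.values), int(keep.sum()))
    return out


def log_transform(em: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1), keeping values positive."""
    if (em.values.to_numpy() < 0).any():
        raise ValueError("negative values at log stage")
    return em._advance(np.log2(em.values + 1.0), em.meta, "log")


def average_replicates(em: ExpressionMatrix) -> ExpressionMatrix:
    """One column per (season, field, genotype, timepoint), averaging the
    biological replicates."""
    check_metadata(em.meta)
    keys = ["season", "field", "genotype", "timepoint"]
    groups = em.meta.groupby(keys, sort=False, observed=True)
    sizes = groups.size()
    if sizes.nunique() > 1:
        raise ValueError("inconsistent replicate structure: "
                         f"group sizes {sorted(sizes.unique())}")
    cols, meta_rows = [], []
    for key, subset in groups:
        cols.append(em.values[subset.index].mean(axis=1))
        row = subset.iloc[0].copy()
        row["replicate"] = 0
        row.name = ".".join(str(k) for k in key)
        meta_rows.append(row)
    values = pd.concat(cols, axis=1)
    meta = pd.DataFrame(meta_rows)
    values.columns = meta.index
    return em._advance(values, meta, "replicate-averaged")


def cv_filter(em: ExpressionMatrix, threshold: float = 0.01,
              report: FilterReport | None = None) -> ExpressionMatrix:
    """Remove stably expressed genes: coefficient of variation (sample sd
    over mean) below ``threshold`` across all retained columns."""
    mean = em.values.mean(axis=1)
    sd = em.values.std(axis=1, ddof=1)
    cv = sd / mean
    keep = cv >= threshold
    out = em._advance(em.values.loc[keep], em.meta, em.stage)
    if report is not None:
        report.record("cv", len(em.values), int(keep.sum()))
    return out


def mean_filter(em: ExpressionMatrix, threshold: float = 1.0,
                report: FilterReport | None = None) -> ExpressionMatrix:
    """Remove low-abundance genes with overall mean below ``threshold``."""
    keep = em.values.mean(axis=1) >= threshold
    out = em._advance(em.values.loc[keep], em.meta, em.stage)
    if report is not None:
        report.record("mean", len(em.values), int(keep.sum()))
    return out


def center_subsets(em: ExpressionMatrix,
                   keys: tuple = ("genotype", "season")) -> ExpressionMatrix:
    """Center each gene within every genotype x season subset, removing
    absolute level differences between subsets."""
    values = em.values.copy()
    for _, subset in em.meta.groupby(list(keys), observed=True):
        block = values[subset.index]
        values[subset.index] = block.sub(block.mean(axis=1), axis=0)
    return em._advance(values, em.meta, "centered")


def scale_genes(em: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each gene to unit standard deviation over the whole profile."""
    sd = em.values.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = em.values.index[sd == 0][:5].tolist()
        raise ValueError(f"zero-variance genes cannot be scaled: {bad}")
    return em._advance(em.values.div(sd, axis=0), em.meta, "scaled")


def average_genotypes(em: ExpressionMatrix) -> ExpressionMatrix:
    """Average the genotype axis (used in the two-season analysis, where the
    genotypes serve as biological replicates)."""
    keys = ["season", "field", "timepoint"]
    groups = em.meta.groupby(keys, sort=False, observed=True)
    cols, meta_rows = [], []
    for key, subset in groups:
        cols.append(em.values[subset.index].mean(axis=1))
        row = subset.iloc[0].copy()
        row["genotype"] = "avg"
        row.name = ".".join(str(k) for k in key)
        meta_rows.append(row)
    values = pd.concat(cols, axis=1)
    meta = pd.DataFrame(meta_rows)
    values.columns = meta.index
    return ExpressionMatrix(values=values, meta=meta, stage=em.stage)


def preprocess_counts(counts: pd.DataFrame, meta: pd.DataFrame,
                      max_undetected: int = 40, cv_threshold: float = 0.01,
                      mean_threshold: float = 1.0,
                      counts_are_continuous: bool = False,
                      ) -> tuple[ExpressionMatrix, FilterReport]:
    """Run the full preprocessing pipeline in the fixed stage order.

    With ``counts_are_continuous`` the input is taken as already normalized
    log-scale values (the generator's exact-test mode) and normalization and
    the log transform are skipped.
    """
    check_metadata(meta)
    report = FilterReport()
    if counts_are_continuous:
        em = ExpressionMatrix(values=counts, meta=meta, stage="log")
        report.record("detection", len(counts), len(counts))
    else:
        em = normalize_counts(counts, meta)
        em = detection_filter(em, max_undetected=max_undetected, report=report)
        em = log_transform(em)
    em = average_replicates(em)
    em = cv_filter(em, threshold=cv_threshold, report=report)
    em = mean_filter(em, threshold=mean_threshold, report=report)
    em = center_subsets(em)
    em = scale_genes(em)
    return em, report
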