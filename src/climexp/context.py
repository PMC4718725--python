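"""Replicability and context sensitivity of cluster means.

For each cluster: the genotype correlation (Pearson r between the two
genotype-specific sub-profiles, a replicability measure), per-season field
correlations and field mean differences (rainfed minus irrigated), and the
four-group classification by whether the field correlation clears the
cutoff in each season.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import SEASONS


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def genotype_correlation(cluster_mean: pd.Series,
                         meta: pd.DataFrame) -> float:
    """Pearson r between the two genotype sub-profiles of a cluster mean,
    aligned by (season, field, timepoint)."""
    genos = sorted(meta["genotype"].astype(str).unique())
    if len(genos) != 2:
        raise ValueError(f"need exactly 2 genotypes, found {genos}")
    key = ["season", "field", "timepoint"]
    sub = {}
    for g in genos:
        idx = meta.index[meta["genotype"].astype(str) == g]
        block = pd.DataFrame({"value": cluster_mean[idx].to_numpy()},
                             index=pd.MultiIndex.from_frame(meta.loc[idx, key]))
        sub[g] = block["value"].sort_index()
    a, b = sub[genos[0]], sub[genos[1]]
    if not a.index.equals(b.index):
        raise ValueError("genotype sub-profiles are not aligned")
    return _pearson(a.to_numpy(), b.to_numpy())


def _field_profiles(cluster_mean: pd.Series, meta: pd.DataFrame,
                    season: str) -> tuple[np.ndarray, np.ndarray]:
    season_mask = meta["season"].astype(str) == season
    out = []
    for fld in ("irrigated", "rainfed"):
        idx = meta.index[season_mask & (meta["field"].astype(str) == fld)]
        block = pd.DataFrame(
            {"value": cluster_mean[idx].to_numpy(),
             "timepoint": meta.loc[idx, "timepoint"].to_numpy()})
        # average over any remaining genotype axis
        prof = block.groupby("timepoint")["value"].mean().sort_index()
        out.append(prof.to_numpy())
    if len(out[0]) != len(out[1]):
        raise ValueError("field sub-profiles are not aligned")
    return out[0], out[1]


def field_correlation(cluster_mean: pd.Series, meta: pd.DataFrame,
                      season: str) -> float:
    """Pearson r between the irrigated and rainfed 15-point profiles within
    a season (genotypes averaged first)."""
    irr, rf = _field_profiles(cluster_mean, meta, season)
    return _pearson(irr, rf)


def field_difference(cluster_mean: pd.Series, meta: pd.DataFrame,
                     season: str) -> float:
    """Mean expression in the rainfed field minus the irrigated field,
    within a season."""
    irr, rf = _field_profiles(cluster_mean, meta, season)
    return float(rf.mean() - irr.mean())


def classify_group(field_r_dry: float, field_r_wet: float,
                   cutoff: float = 0.8) -> int:
    """Four-group classification: 1 both seasons high field correlation,
    2 wet high only, 3 dry high only, 4 both low.  r equal to the cutoff
    counts as high."""
    dry_high = field_r_dry >= cutoff
    wet_high = field_r_wet >= cutoff
    if dry_high and wet_high:
        return 1
    if wet_high:
        return 2
    if dry_high:
        return 3
    return 4


@dataclass
class ClusterContextSummary:
    cluster_id: int
    genotype_r: float | None
    field_r_dry: float
    field_r_wet: float
    field_diff_dry: float
    field_diff_wet: float
    group: int
    high_replicability: bool


def summarize_clusters(cluster_means: pd.DataFrame, meta: pd.DataFrame,
                       genotype_means: pd.DataFrame | None = None,
                       genotype_meta: pd.DataFrame | None = None,
                       genotype_r_cutoff: float = 0.9,
                       field_r_cutoff: float = 0.8) -> pd.DataFrame:
    """Per-cluster context summary table.

    ``cluster_means`` holds one row per cluster over the genotype-averaged
    design columns described by ``meta``; optional ``genotype_means`` (over
    the per-genotype columns of ``genotype_meta``) supply the genotype
    correlation.
    """
    rows = []
    for cid, mean in cluster_means.iterrows():
        geno_r = None
        if genotype_means is not None:
            geno_r = genotype_correlation(genotype_means.loc[cid],
                                          genotype_meta)
        r = {s: field_correlation(mean, meta, s) for s in SEASONS}
        d = {s: field_difference(mean, meta, s) for s in SEASONS}
        rows.append(ClusterContextSummary(
            cluster_id=cid, genotype_r=geno_r,
            field_r_dry=r["dry"], field_r_wet=r["wet"],
            field_diff_dry=d["dry"], field_diff_wet=d["wet"],
            group=classify_group(r["dry"], r["wet"], field_r_cutoff),
            high_replicability=(geno_r is not None
                                and geno_r > genotype_r_cutoff)))
    return pd.DataFrame([vars(s) for s in rows]).set_index("cluster_id")
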