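"""Plain-text readers and writers for the pipeline's stage artifacts:
weather CSV, counts TSV (or MTX triplets with sidecar name files), sample
metadata CSV, ED-parameter TSV + metadata JSON, cluster tables and JSON
reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

FLOAT_FMT = "%.10g"


def write_weather(weather, path: Path) -> None:
    frames = []
    for season, frame in weather.frames.items():
        f = frame.copy()
        f.insert(0, "season", season)
        frames.append(f)
    out = pd.concat(frames)
    out.index.name = "timestamp"
    out.to_csv(path, float_format=FLOAT_FMT)


def read_weather(path: Path, resolution_min: int = 5):
    from .simulate import WeatherSeries
    raw = pd.read_csv(path, index_col="timestamp", parse_dates=True)
    frames = {s: g.drop(columns="season").sort_index()
              for s, g in raw.groupby("season")}
    return WeatherSeries(frames=frames, resolution_min=resolution_min)


def write_counts_tsv(counts: pd.DataFrame, path: Path) -> None:
    counts.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_counts_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_mtx(counts: pd.DataFrame, prefix: Path) -> None:
    """Sparse triplet format with sidecar row / column name files."""
    from scipy import io as spio
    from scipy import sparse
    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")),
                 sparse.csr_matrix(counts.to_numpy()))
    prefix.with_suffix(".rows.txt").write_text(
        "\n".join(map(str, counts.index)) + "\n")
    prefix.with_suffix(".cols.txt").write_text(
        "\n".join(map(str, counts.columns)) + "\n")


def read_counts_mtx(prefix: Path) -> pd.DataFrame:
    from scipy import io as spio
    prefix = Path(prefix)
    mat = spio.mmread(str(prefix.with_suffix(".mtx"))).toarray()
    rows = prefix.with_suffix(".rows.txt").read_text().splitlines()
    cols = prefix.with_suffix(".cols.txt").read_text().splitlines()
    return pd.DataFrame(mat, index=rows, columns=cols)


def write_metadata(meta: pd.DataFrame, path: Path) -> None:
    meta.to_csv(path, index_label="sample_id")


def read_metadata(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id", parse_dates=["timestamp"])


def write_ed_matrix(ed, path_values: Path, path_meta: Path) -> None:
    ed.values.to_csv(path_values, sep="\t", float_format=FLOAT_FMT)
    payload = {"parameters": ed.param_meta.reset_index().to_dict("records"),
               "merge_map": dict(ed.merge_map)}
    Path(path_meta).write_text(json.dumps(payload, indent=1, sort_keys=True))


def write_json(obj, path: Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Timestamp):
        return obj.isoformat()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def equation_record(eq) -> dict:
    return {"terms": [{"parameter": pid, "coefficient": float(c)}
                      for pid, c in eq.terms],
            "cv_mse": float(eq.mse), "bic": float(eq.bic), "n": int(eq.n)}


def selection_record(result) -> dict:
    m = result.model
    return {
        "composition_id": int(m.composition_id),
        "segments": {lab: equation_record(eq)
                     for lab, eq in m.equations.items()},
        "mse": float(m.mse), "p": int(m.p), "bic": float(m.bic),
        "candidate_sets": {k: list(v)
                           for k, v in result.candidate_sets.items()},
        "composition_bics": {k: {str(c): float(b) for c, b in d.items()}
                             for k, d in result.composition_bics.items()},
        "null_model": bool(result.null_model),
        "fallback": bool(result.fallback),
    }
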