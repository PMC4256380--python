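"""Result writers: tidy CSV/JSON exports, formatted text tables, and the
run manifest.

Numbers are rendered at the reporting precision of the underlying
quantities: one decimal for percentages and years, two decimals for
annual rates.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .parameters import ModelParameters, parameters_digest

__all__ = ["write_tables", "render_outcomes", "render_validation", "write_manifest"]


def _fmt(metric: str, value: float) -> str:
    if pd.isna(value):
        return "NA"
    if metric.startswith("pct_"):
        return f"{value:.1f}"
    if metric in ("life_expectancy", "hale"):
        return f"{value:.1f}"
    return f"{value:.2f}"


def render_outcomes(df: pd.DataFrame) -> str:
    """Plain-text outcome table: one row per (stratum, horizon), one
    column per metric, cells ``mean (lower-upper)``."""
    if df.empty:
        return "(no results)\n"
    df = df.copy()
    has_ci = "lower95" in df.columns and df["lower95"].notna().any()

    def cell(row: pd.Series) -> str:
        m = _fmt(row["metric"], row["mean"])
        if has_ci and not pd.isna(row.get("lower95")):
            return f"{m} ({_fmt(row['metric'], row['lower95'])}-{_fmt(row['metric'], row['upper95'])})"
        return m

    df["cell"] = df.apply(cell, axis=1)
    index_cols = [c for c in ("scenario", "stratum", "horizon") if c in df.columns]
    wide = df.pivot_table(
        index=index_cols, columns="metric", values="cell", aggfunc="first", sort=False
    )
    ordered = [c for c in (
        "pct_recurrence", "pct_mcrpc", "pct_pca_death", "pct_overall_death",
        "life_expectancy", "hale",
    ) if c in wide.columns]
    wide = wide[ordered + [c for c in wide.columns if c not in ordered]]
    return wide.to_string() + "\n"


def render_validation(df: pd.DataFrame) -> str:
    """Plain-text validation report mirroring the pathway/predicted/
    observed/p-value layout."""
    df = df.copy()
    df["predicted"] = df["predicted"].map(lambda v: f"{v:.2f}")
    df["observed"] = df["observed"].map(lambda v: f"{v:.2f}")
    df["p_value"] = df["p_value"].map(lambda v: "NA" if pd.isna(v) else f"{v:.3g}")
    cols = ["label", "predicted", "observed", "p_value", "reference"]
    return df[cols].to_string(index=False) + "\n"


def write_tables(
    df: pd.DataFrame,
    out_dir: str | Path,
    stem: str,
    formats: Sequence[str] = ("csv",),
    renderer=render_outcomes,
) -> list[Path]:
    """Write a tidy result table in the requested formats (csv, json,
    text) with a deterministic column order; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for fmt in formats:
        path = out_dir / f"{stem}.{'txt' if fmt == 'text' else fmt}"
        if fmt == "csv":
            df.to_csv(path, index=False)
        elif fmt == "json":
            path.write_text(json.dumps(df.to_dict(orient="records"), indent=2, default=float) + "\n")
        elif fmt == "text":
            path.write_text(renderer(df))
        else:
            raise ValueError(f"unknown format {fmt!r}")
        written.append(path)
    return written


def write_manifest(
    out_dir: str | Path,
    params: ModelParameters,
    seed: int,
    n_replicates: int,
    extra: Mapping | None = None,
) -> Path:
    """Write ``manifest.json``: everything needed to reproduce the run
    exactly (parameter digest and full dump, seed, replicate count,
    package version)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    doc = {
        "package": "pcasim",
        "version": __version__,
        "seed": seed,
        "n_replicates": n_replicates,
        "cohort_size": params.cohort_size,
        "horizon": params.horizon,
        "parameters_sha256": parameters_digest(params),
        "parameters": params.to_dict(),
    }
    if extra:
        doc.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path
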