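"""Reading, writing and bundled data for occlusion time-series tables.

Two CSV schemas are understood:

summary format
    one row per paste × condition × day:
    ``paste, condition, day, mean, sd, n`` (optional ``letter``);
long format
    one row per specimen measurement:
    ``paste, condition, specimen, day, occluded_pct``.

Long tables are aggregated to per-day summaries on read.  The seven-day
brushing study that motivates the package (three pastes × two saliva
conditions × 7 specimens) ships as a bundled summary table, together with
its published superscript-letter significance pattern and the published
per-group occlusion rates used as reference truth in recovery studies.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fitting import OcclusionSeries

__all__ = [
    "PASTES",
    "CONDITIONS",
    "normalize_condition",
    "read_series_csv",
    "series_to_frame",
    "write_summary_csv",
    "bundled_fixture_table1",
    "bundled_fixture_letters",
    "reference_rates",
]

#: canonical paste labels of the bundled study
PASTES = ("EB@TiO2", "Colgate Pro-relief", "Sensodyne repair")
CONDITIONS = ("without_saliva", "with_saliva")

_CONDITION_ALIASES = {
    "ws": "without_saliva",
    "without_saliva": "without_saliva",
    "without saliva": "without_saliva",
    "s": "with_saliva",
    "with_saliva": "with_saliva",
    "with saliva": "with_saliva",
}

#: published per-day occlusion rates (per day) for the bundled study groups,
#: used as ground truth in parameter-recovery experiments
_REFERENCE_RATES = {
    ("EB@TiO2", "without_saliva"): 0.7762,
    ("EB@TiO2", "with_saliva"): 0.9500,
    ("Colgate Pro-relief", "without_saliva"): 0.4230,
    ("Colgate Pro-relief", "with_saliva"): 0.3558,
    ("Sensodyne repair", "without_saliva"): 0.2646,
    ("Sensodyne repair", "with_saliva"): 0.4635,
}


def normalize_condition(label: str) -> str:
    """Map condition aliases (``WS``/``S``, spaces) to canonical names."""
    key = str(label).strip().lower()
    if key not in _CONDITION_ALIASES:
        raise ValueError(f"unknown saliva condition label {label!r}")
    return _CONDITION_ALIASES[key]


def _parse_error(row: int, message: str) -> ValueError:
    return ValueError(f"row {row}: {message}")


def _validate_summary_frame(df: pd.DataFrame) -> None:
    dup = df.duplicated(subset=["paste", "condition", "day"])
    if dup.any():
        raise _parse_error(
            int(df.index[dup][0]) + 2, "duplicate (paste, condition, day) entry"
        )
    for idx, row in df.iterrows():
        line = int(idx) + 2  # 1-based with header
        if not float(row["day"]).is_integer() or row["day"] < 1:
            raise _parse_error(line, f"day must be an integer >= 1, got {row['day']}")
        if not 0 <= row["mean"] <= 100:
            raise _parse_error(line, f"mean {row['mean']} outside [0, 100]")
        if row["sd"] < 0:
            raise _parse_error(line, f"sd {row['sd']} must be >= 0")
        if row["n"] < 1:
            raise _parse_error(line, f"n {row['n']} must be >= 1")


def _summary_frame_to_series(df: pd.DataFrame) -> list[OcclusionSeries]:
    paste_order = {p: i for i, p in enumerate(PASTES)}
    cond_order = {c: i for i, c in enumerate(CONDITIONS)}
    out = []
    for (paste, cond), grp in df.groupby(["paste", "condition"], sort=False):
        grp = grp.sort_values("day")
        ns = grp["n"].unique()
        if len(ns) != 1:
            raise ValueError(
                f"{paste} / {cond}: group size varies across days ({sorted(ns)}); "
                "one n per series is required"
            )
        out.append(
            OcclusionSeries(
                paste=paste,
                condition=cond,
                days=grp["day"].to_numpy(dtype=float),
                means=grp["mean"].to_numpy(dtype=float),
                sds=grp["sd"].to_numpy(dtype=float),
                n=int(ns[0]),
            )
        )
    out.sort(
        key=lambda s: (
            paste_order.get(s.paste, len(PASTES)),
            s.paste,
            cond_order.get(s.condition, 9),
        )
    )
    return out


def _aggregate_long(df: pd.DataFrame) -> pd.DataFrame:
    dup = df.duplicated(subset=["paste", "condition", "specimen", "day"])
    if dup.any():
        raise _parse_error(
            int(df.index[dup][0]) + 2,
            "duplicate (paste, condition, specimen, day) entry",
        )
    for idx, row in df.iterrows():
        line = int(idx) + 2
        if not 0 <= row["occluded_pct"] <= 100:
            raise _parse_error(
                line, f"occluded_pct {row['occluded_pct']} outside [0, 100]"
            )
        if not float(row["day"]).is_integer() or row["day"] < 1:
            raise _parse_error(line, f"day must be an integer >= 1, got {row['day']}")
    agg = (
        df.groupby(["paste", "condition", "day"], sort=False)["occluded_pct"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="count")
        .reset_index()
    )
    return agg


def read_series_csv(path, format: str = "auto") -> list[OcclusionSeries]:
    """Read an occlusion table (long or summary CSV) into series objects.

    ``format`` is ``"long"``, ``"summary"`` or ``"auto"`` (detected from the
    header).  Long tables are aggregated to per-day mean/SD/n.  Validation
    failures name the offending CSV row.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if format == "auto":
        if {"specimen", "occluded_pct"} <= cols:
            format = "long"
        elif {"mean", "sd", "n"} <= cols:
            format = "summary"
        else:
            raise ValueError(
                f"cannot detect schema from columns {sorted(cols)}; expected a "
                "long table (paste, condition, specimen, day, occluded_pct) or a "
                "summary table (paste, condition, day, mean, sd, n)"
            )
    required = (
        {"paste", "condition", "specimen", "day", "occluded_pct"}
        if format == "long"
        else {"paste", "condition", "day", "mean", "sd", "n"}
    )
    missing = required - cols
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = df.copy()
    df["condition"] = df["condition"].map(normalize_condition)
    if format == "long":
        df = _aggregate_long(df)
    else:
        _validate_summary_frame(df)
    return _summary_frame_to_series(df)


def series_to_frame(table: Iterable[OcclusionSeries]) -> pd.DataFrame:
    """Summary-format DataFrame (one row per paste × condition × day)."""
    rows = []
    for s in table:
        for d, m, sd in zip(s.days, s.means, s.sds):
            rows.append(
                {
                    "paste": s.paste,
                    "condition": s.condition,
                    "day": int(d),
                    "mean": float(m),
                    "sd": float(sd),
                    "n": s.n,
                }
            )
    return pd.DataFrame(rows)


def write_summary_csv(table: Iterable[OcclusionSeries], path) -> None:
    """Write series in the summary CSV schema."""
    series_to_frame(table).to_csv(path, index=False)


def _fixture_frame() -> pd.DataFrame:
    with resources.as_file(
        resources.files("occlufit") / "data" / "table1.csv"
    ) as p:
        return pd.read_csv(p)


def bundled_fixture_table1() -> list[OcclusionSeries]:
    """The bundled seven-day brushing study: 3 pastes × 2 conditions × 7 days.

    Per-day mean ± SD of the % occluded tubule area over n = 7 dentin
    specimens per group, as published for the study this package models.
    """
    df = _fixture_frame()
    df["condition"] = df["condition"].map(normalize_condition)
    _validate_summary_frame(df)
    return _summary_frame_to_series(df)


def bundled_fixture_letters() -> dict[tuple[str, int], bool]:
    """Published per-day significance pattern of the bundled study.

    Maps ``(paste, day)`` to True when the published table marks the two
    saliva conditions with different superscript letters (significant at
    the 5 % level).
    """
    df = _fixture_frame()
    df["condition"] = df["condition"].map(normalize_condition)
    out: dict[tuple[str, int], bool] = {}
    for (paste, day), grp in df.groupby(["paste", "day"]):
        letters = set(grp["letter"])
        out[(paste, int(day))] = len(letters) > 1
    return out


def reference_rates() -> dict[tuple[str, str], float]:
    """Published occlusion rates (per day) for the six bundled study groups."""
    return dict(_REFERENCE_RATES)
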