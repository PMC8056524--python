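"""CSV input/output and validation.

File dialects are comma-separated, UTF-8, '.' decimal, header required.
Trajectory times are in years, TAC frame times in minutes.  The bundled
``oasis3_published_rates.csv`` carries the published group-level annualized
% change summaries (mean, SD, n per stratum x population x metric x ROI) of
the OASIS-3 cognitively-unimpaired PIB cohort; it is the input of the
"table-only" mode, which recomputes trial sample sizes directly from
published summaries without any simulation.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .trajectory import GroupRateSummary, LongitudinalSeries

__all__ = [
    "read_metric_table",
    "read_group_summaries",
    "write_group_summaries",
    "load_published_rates",
    "SchemaError",
]

METRIC_COLUMNS = ("subject_id", "session", "time_yr", "region", "metric", "value")
SUMMARY_COLUMNS = ("stratum", "population", "metric", "roi", "n", "mean_pct", "sd_pct")


class SchemaError(ValueError):
    """A CSV is missing required columns or holds invalid records."""


def _require_columns(frame: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def read_metric_table(path) -> pd.DataFrame:
    """Validated long-format metric table (one row per session x region x metric).

    Raises :class:`SchemaError` naming the offending data row (1-based, header
    excluded) for non-positive or non-finite values.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    _require_columns(frame, METRIC_COLUMNS, path)
    values = pd.to_numeric(frame["value"], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(values) | (values <= 0))
    if bad.size:
        raise SchemaError(
            f"{path}: non-positive or unparseable value in data row(s) "
            f"{', '.join(str(i + 1) for i in bad[:5])}"
        )
    frame["value"] = values
    frame["time_yr"] = pd.to_numeric(frame["time_yr"])
    return frame


def metric_series(frame: pd.DataFrame, metric: str, roi: str) -> list[LongitudinalSeries]:
    from .trajectory import series_from_frame

    return series_from_frame(frame, metric, roi)


def read_group_summaries(path) -> list[GroupRateSummary]:
    """Group-level annualized % change summaries from a Table-1-shaped CSV."""
    path = Path(path)
    frame = pd.read_csv(path)
    _require_columns(frame, SUMMARY_COLUMNS, path)
    out = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            out.append(
                GroupRateSummary(
                    stratum=str(row.stratum),
                    population=str(row.population),
                    metric=str(row.metric),
                    roi=str(row.roi),
                    n=int(row.n),
                    mean_pct=float(row.mean_pct),
                    sd_pct=float(row.sd_pct),
                )
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: invalid record in data row {i + 1}: {exc}") from exc
    return out


def write_group_summaries(summaries, path) -> None:
    rows = [
        {
            "stratum": g.stratum,
            "population": g.population,
            "metric": g.metric,
            "roi": g.roi,
            "n": g.n,
            "mean_pct": g.mean_pct,
            "sd_pct": g.sd_pct,
            "effect_size": g.effect_size,
        }
        for g in summaries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_published_rates() -> list[GroupRateSummary]:
    """The bundled published group-rate summaries (48 records)."""
    with resources.as_file(
        resources.files("amytrial.data") / "oasis3_published_rates.csv"
    ) as p:
        return read_group_summaries(p)
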