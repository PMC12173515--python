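"""Weekly percentile growth charts for fetal biometry.

A :class:`PercentileChart` holds, for one reference population ("dataset"),
the published 10th / 50th / 90th percentile of each biometric parameter at
each covered gestational week.  The 10th and 90th percentiles define the
per-week sampling bounds used by the sensitivity engine; the 50th is used
for perturbation analyses and may be absent.

Charts are exchanged as long-format delimited text with columns
``dataset_id, week, parameter, p10, p50, p90`` (units cm; an optional
``units`` column with value ``mm`` converts a row at load time).  Long
format accommodates heterogeneous week coverage across datasets without
sparse tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .exceptions import ChartFormatError, NoDataError, ValidationError
from .formulas import PARAMETERS

WEEK_MIN, WEEK_MAX = 10, 44

_REQUIRED_COLS = ("dataset_id", "week", "parameter", "p10", "p50", "p90")


@dataclass(frozen=True)
class ParameterBounds:
    """Per-parameter (lower, upper) sampling interval for one week, in cm."""

    week: int
    bounds: Mapping[str, Tuple[float, float]]

    def __post_init__(self):
        for p, (lo, hi) in self.bounds.items():
            if not (lo < hi):
                raise ValidationError(
                    f"week {self.week}, {p}: lower bound {lo} is not < upper {hi}"
                )

    def __getitem__(self, param: str) -> Tuple[float, float]:
        return self.bounds[param]

    @property
    def parameters(self) -> Tuple[str, ...]:
        return tuple(p for p in PARAMETERS if p in self.bounds)


@dataclass
class PercentileChart:
    """One dataset's weekly 10th/50th/90th percentile records.

    ``records`` maps ``(week, parameter)`` to ``(p10, p50, p90)`` with
    ``p50`` possibly None.  Invariants: 0 < p10 < p90, p10 < p50 < p90 when
    p50 is present, weeks integral in [10, 44].
    """

    dataset_id: str
    records: Dict[Tuple[int, str], Tuple[float, Optional[float], float]] = field(
        default_factory=dict
    )
    source_meta: str = ""

    def __post_init__(self):
        for (week, param), (p10, p50, p90) in self.records.items():
            self._check_record(week, param, p10, p50, p90)

    @staticmethod
    def _check_record(week, param, p10, p50, p90, where: str = ""):
        if param not in PARAMETERS:
            raise ValidationError(f"{where}unknown parameter {param!r}")
        if not (WEEK_MIN <= week <= WEEK_MAX) or int(week) != week:
            raise ValidationError(
                f"{where}week must be an integer in [{WEEK_MIN}, {WEEK_MAX}], got {week!r}"
            )
        if not (0 < p10 < p90):
            raise ValidationError(
                f"{where}{param} week {week}: requires 0 < p10 < p90, got ({p10}, {p90})"
            )
        if p50 is not None and not (p10 < p50 < p90):
            raise ValidationError(
                f"{where}{param} week {week}: p50={p50} outside (p10, p90)=({p10}, {p90})"
            )

    def add_record(self, week: int, param: str, p10: float, p50: Optional[float], p90: float):
        self._check_record(week, param, p10, p50, p90)
        self.records[(int(week), param)] = (float(p10), None if p50 is None else float(p50), float(p90))

    @property
    def weeks(self) -> Tuple[int, ...]:
        return tuple(sorted({w for w, _ in self.records}))

    def parameters_at(self, week: int) -> Tuple[str, ...]:
        return tuple(p for p in PARAMETERS if (week, p) in self.records)

    def percentiles(self, week: int, param: str) -> Tuple[float, Optional[float], float]:
        try:
            return self.records[(week, param)]
        except KeyError:
            raise NoDataError(
                f"dataset {self.dataset_id!r}: no data for {param} at week {week}"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "dataset_id": self.dataset_id,
                "week": w,
                "parameter": p,
                "p10": v[0],
                "p50": v[1],
                "p90": v[2],
            }
            for (w, p), v in sorted(self.records.items())
        ]
        return pd.DataFrame(rows, columns=list(_REQUIRED_COLS))


def bounds_for(chart: PercentileChart, week: int, params: Iterable[str]) -> ParameterBounds:
    """The (p10, p90) sampling box at one week for the requested parameters.

    Raises :class:`NoDataError` (callers skip the (dataset, week) pair) if the
    week or any requested parameter is uncovered.
    """
    params = tuple(params)
    if not params:
        raise ValidationError("params must be non-empty")
    bounds = {}
    for p in params:
        p10, _, p90 = chart.percentiles(week, p)
        bounds[p] = (p10, p90)
    return ParameterBounds(week=week, bounds=bounds)


def read_chart_csv(path, units: str = "cm") -> PercentileChart:
    """Read a long-format chart file into a validated chart.

    ``units`` sets the default length unit (``cm`` or ``mm``); a per-row
    ``units`` column overrides it.  Any invalid row aborts the read with a
    message naming the row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as e:  # malformed delimiter/encoding
        raise ChartFormatError(f"{path}: unreadable chart file ({e})") from e
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ChartFormatError(f"{path}: malformed header, missing columns {missing}")
    if df.empty:
        raise ChartFormatError(f"{path}: chart file has no records")
    ids = df["dataset_id"].unique()
    if len(ids) != 1:
        raise ChartFormatError(f"{path}: expected a single dataset_id, found {list(ids)}")
    chart = PercentileChart(dataset_id=str(ids[0]))
    for i, row in df.iterrows():
        where = f"{path} row {i + 2}: "  # +2: header line + 1-based numbering
        row_units = str(row["units"]) if "units" in df.columns and not pd.isna(row.get("units")) else units
        if row_units not in ("cm", "mm"):
            raise ChartFormatError(f"{where}unknown units {row_units!r}")
        scale = 0.1 if row_units == "mm" else 1.0
        try:
            week = int(row["week"])
            p10 = float(row["p10"]) * scale
            p90 = float(row["p90"]) * scale
            p50 = None if pd.isna(row["p50"]) else float(row["p50"]) * scale
        except (TypeError, ValueError) as e:
            raise ChartFormatError(f"{where}non-numeric cell ({e})") from e
        if np.isnan(p10) or np.isnan(p90):
            raise ChartFormatError(f"{where}p10/p90 must both be present")
        try:
            chart.add_record(week, str(row["parameter"]), p10, p50, p90)
        except ValidationError as e:
            raise ChartFormatError(f"{where}{e}") from e
    return chart


def write_chart_csv(chart: PercentileChart, path) -> None:
    """Write a chart in the long schema; round-trips through read_chart_csv."""
    chart.to_frame().to_csv(path, index=False)


def aggregate_charts(charts: Sequence[PercentileChart]) -> pd.DataFrame:
    """Across-dataset medians of each percentile column per (week, parameter).

    Datasets lacking a (week, parameter) record are excluded from that
    median; even counts use the midpoint of the central order statistics.
    Returns a frame with columns week, parameter, n_datasets, p10, p50, p90
    (a p50 median is reported only over datasets that publish p50).
    """
    if not charts:
        raise ValidationError("aggregate_charts requires at least one chart")
    keys: Set[Tuple[int, str]] = set()
    for c in charts:
        keys.update(c.records)
    rows = []
    for week, param in sorted(keys):
        p10s, p50s, p90s = [], [], []
        for c in charts:
            rec = c.records.get((week, param))
            if rec is None:
                continue
            p10s.append(rec[0])
            p90s.append(rec[2])
            if rec[1] is not None:
                p50s.append(rec[1])
        rows.append(
            {
                "week": week,
                "parameter": param,
                "n_datasets": len(p10s),
                "p10": float(np.median(p10s)),
                "p50": float(np.median(p50s)) if p50s else np.nan,
                "p90": float(np.median(p90s)),
            }
        )
    return pd.DataFrame(rows, columns=["week", "parameter", "n_datasets", "p10", "p50", "p90"])


def load_reference_week38_chart() -> PercentileChart:
    """The packaged week-38 INTERGROWTH-21st reference chart.

    10th/50th/90th percentile values of BPD, HC, AC and FL at gestational
    week 38 for the INTERGROWTH-21st international fetal growth standards,
    reconstructed at high precision from published EFW reference
    computations on that chart (10th percentiles by symmetry of the centile
    model).  Used by the worked examples and their tests.
    """
    from importlib import resources

    with resources.as_file(
        resources.files("efwsens.data").joinpath("intergrowth21_week38.csv")
    ) as p:
        return read_chart_csv(p)
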