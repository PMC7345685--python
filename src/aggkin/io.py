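"""Readers and writers for observable series, fit reports and run configs.

Time-series files are two-column CSV ``time,value`` with a header row;
size-distribution snapshots use long format ``time,size,value``.  Numbers
are written in scientific notation with 12 significant digits so that a
write/read round trip is faithful.  Time units are metadata only: the tool
never converts between seconds and minutes, it carries the unit through.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import FitResult, aic
from .observables import ObservableSeries

FLOAT_FMT = "%.12e"


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def read_timeseries(path: str | Path, observable: str,
                    weight_rule: str = "half") -> ObservableSeries:
    """Read a CSV observable file and validate it.

    Two-column files (time,value) for scalar observables; long-format
    (time,size,value) for ``size_distribution``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.empty:
        raise ParseError(f"{path}: no data rows")

    if observable == "size_distribution":
        required = ["time", "size", "value"]
        if list(df.columns[:3]) != required:
            raise ParseError(f"{path}: expected columns {required}")
        for col in required:
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            if bad.any():
                line = int(bad.idxmax()) + 2  # header + 1-based
                raise ParseError(f"{path}: non-numeric {col!r} at line {line}")
            df[col] = pd.to_numeric(df[col])
        wide = df.pivot(index="time", columns="size", values="value").sort_index()
        times = wide.index.to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ParseError(f"{path}: duplicated or decreasing time stamps")
        return ObservableSeries(
            name=observable, times=times, values=wide.to_numpy(dtype=float),
            weight_rule=weight_rule, meta={"path": str(path)},
        )

    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (time, value)")
    df = df.iloc[:, :2]
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise ParseError(f"{path}: non-numeric value at line {line}")
    times = pd.to_numeric(df.iloc[:, 0]).to_numpy(dtype=float)
    values = pd.to_numeric(df.iloc[:, 1]).to_numpy(dtype=float)
    order = np.argsort(times, kind="stable")
    times, values = times[order], values[order]
    dup = np.where(np.diff(times) == 0)[0]
    if dup.size:
        line = int(order[dup[0] + 1]) + 2
        raise ParseError(f"{path}: duplicated time stamp at line {line}")
    return ObservableSeries(
        name=observable, times=times, values=values,
        weight_rule=weight_rule, meta={"path": str(path)},
    )


def write_timeseries(series: ObservableSeries, path: str | Path) -> None:
    path = Path(path)
    if series.name == "size_distribution":
        n_times, N = series.values.shape
        rows = {
            "time": np.repeat(series.times, N),
            "size": np.tile(np.arange(1, N + 1), n_times),
            "value": series.values.ravel(),
        }
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame({"time": series.times, "value": series.values})
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_fit_report(result: FitResult, path: str | Path) -> None:
    """Structured JSON fit report with the AIC recomputed for consistency."""
    path = Path(path)
    report = result.to_dict()
    report["aic_recomputed"] = aic(result.K, result.n_obs, result.rss)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_fit_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


@dataclass
class RunConfig:
    """On-disk run configuration; round-trips losslessly through YAML."""

    variant: str = "aggregation"
    N: int = 10
    params_file: str | None = None
    constraints: list[str] = field(default_factory=list)
    rtol: float = 1e-8
    atol: float = 1e-10
    seed: int = 0
    out: str | None = None
    log_level: str = "INFO"
    time_unit: str = "s"

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def read_params_file(path: str | Path):
    """Kinetic parameters from a YAML/JSON mapping file."""
    from .params import KineticParams

    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return KineticParams.from_dict(data)
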