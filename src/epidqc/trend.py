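"""Baseline presets, tolerance comparison, and temporal trend tracking.

Daily or monthly QA compares each analyzed image against an imager-specific
baseline: a preset value and a tolerance per parameter.  The convention
here is two-level: a deviation within the tolerance passes, within twice
the tolerance warns, beyond that fails; the overall status is the worst
parameter.  The first accepted analysis of an imager typically becomes its
baseline, with the shipped default tolerances (editable opinions, not
vendor numbers): rotation 0.5 degrees, linearity and local-linearity
deviation 2 percentage points, mean SNR 10 %, MTF(0.5) 10 %.

Series are stored append-only as newline-delimited JSON per imager
identity, which keeps the QA audit trail diff-able.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from .errors import ConfigurationError, InsufficientDataError

__all__ = [
    "ToleranceSpec",
    "Baseline",
    "DEFAULT_TOLERANCES",
    "baseline_from_summary",
    "save_baseline",
    "load_baseline",
    "compare",
    "ComparisonResult",
    "TrendSeries",
    "TrendDatabase",
    "TrendStats",
    "trend_stats",
]

_STATUS_ORDER = {"pass": 0, "warn": 1, "fail": 2}

#: default (tolerance, mode) per summary parameter; mode "abs" interprets
#: the tolerance in the parameter's own units, "percent" relative to the
#: preset value
DEFAULT_TOLERANCES: dict[str, tuple[float, str]] = {
    "rotation_deg": (0.5, "abs"),
    "linearity_max_deviation_pct": (2.0, "abs"),
    "local_linearity_worst_pct": (2.0, "abs"),
    "mean_snr": (10.0, "percent"),
    "mtf50_in_plane": (10.0, "percent"),
    "mtf50_cross_plane": (10.0, "percent"),
}


@dataclass(frozen=True)
class ToleranceSpec:
    preset: float
    tolerance: float
    mode: str = "abs"          # "abs" | "percent"

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.mode not in ("abs", "percent"):
            raise ValueError(f"unknown tolerance mode {self.mode!r}")

    @property
    def absolute_tolerance(self) -> float:
        if self.mode == "abs":
            return self.tolerance
        return abs(self.preset) * self.tolerance / 100.0

    def status(self, value: float | None) -> str:
        """pass / warn / fail for one measured value (warn if missing)."""
        if value is None:
            return "warn"
        dev = abs(value - self.preset)
        tol = self.absolute_tolerance
        if dev <= tol:
            return "pass"
        if dev <= 2.0 * tol:
            return "warn"
        return "fail"


@dataclass(frozen=True)
class Baseline:
    imager_id: str
    parameters: dict[str, ToleranceSpec]

    def __post_init__(self):
        if not self.parameters:
            raise ValueError("baseline must define at least one parameter")


def baseline_from_summary(summary: dict, imager_id: str,
                          tolerances: dict[str, tuple[float, str]] | None = None
                          ) -> Baseline:
    """Turn an accepted QAResult summary into a baseline with default
    tolerances; parameters whose value is missing are skipped."""
    tolerances = tolerances or DEFAULT_TOLERANCES
    params = {}
    for name, (tol, mode) in tolerances.items():
        value = summary.get(name)
        if value is None:
            continue
        params[name] = ToleranceSpec(preset=float(value), tolerance=tol, mode=mode)
    return Baseline(imager_id=imager_id, parameters=params)


def save_baseline(baseline: Baseline, path) -> None:
    data = {"imager_id": baseline.imager_id,
            "parameters": {k: dataclasses.asdict(v)
                           for k, v in baseline.parameters.items()}}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_baseline(path) -> Baseline:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"baseline file {path} does not exist")
    data = yaml.safe_load(path.read_text())
    return Baseline(
        imager_id=data["imager_id"],
        parameters={k: ToleranceSpec(**v) for k, v in data["parameters"].items()},
    )


@dataclass(frozen=True)
class ComparisonResult:
    per_parameter: dict[str, str]
    overall: str


def compare(summary: dict, baseline: Baseline | None) -> ComparisonResult:
    """Compare a QAResult summary against a baseline.

    Raises :class:`ConfigurationError` when no baseline is defined.
    The check is symmetric in the deviation sign.
    """
    if baseline is None:
        raise ConfigurationError("no baseline defined for this imager")
    per = {name: spec.status(summary.get(name))
           for name, spec in baseline.parameters.items()}
    overall = max(per.values(), key=_STATUS_ORDER.get) if per else "pass"
    return ComparisonResult(per_parameter=per, overall=overall)


# --------------------------------------------------------------------------
# temporal series
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendSeries:
    imager_id: str
    records: tuple[tuple[str, dict], ...]   # (ISO timestamp, summary)

    def times_days(self) -> np.ndarray:
        """Days elapsed since the first record."""
        ts = [datetime.fromisoformat(t) for t, _ in self.records]
        t0 = ts[0]
        return np.array([(t - t0).total_seconds() / 86400.0 for t in ts])

    def values(self, parameter: str) -> np.ndarray:
        out = []
        for _, summary in self.records:
            v = summary.get(parameter)
            out.append(np.nan if v is None else float(v))
        return np.asarray(out)


class TrendDatabase:
    """Append-only newline-delimited JSON store, one file per imager."""

    def __init__(self, root):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    def _path(self, imager_id: str) -> Path:
        safe = "".join(ch if ch.isalnum() or ch in "-_." else "_"
                       for ch in imager_id)
        return self.root / f"{safe}.jsonl"

    def add_record(self, imager_id: str, timestamp: str, summary: dict) -> None:
        """Append one record; timestamps must be strictly increasing."""
        datetime.fromisoformat(timestamp)       # validate format
        series = self.load_series(imager_id, missing_ok=True)
        if series.records and timestamp <= series.records[-1][0]:
            raise ValueError(
                f"timestamp {timestamp} not after last record "
                f"{series.records[-1][0]} for {imager_id}")
        line = json.dumps({"timestamp": timestamp, "summary": summary})
        with open(self._path(imager_id), "a") as fh:
            fh.write(line + "\n")

    def load_series(self, imager_id: str, missing_ok: bool = False) -> TrendSeries:
        path = self._path(imager_id)
        if not path.exists():
            if missing_ok:
                return TrendSeries(imager_id=imager_id, records=())
            raise ConfigurationError(f"no stored results for {imager_id!r}")
        records = []
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            d = json.loads(line)
            records.append((d["timestamp"], d["summary"]))
        return TrendSeries(imager_id=imager_id, records=tuple(records))

    def imagers(self) -> list[str]:
        return sorted(p.stem for p in self.root.glob("*.jsonl"))


@dataclass(frozen=True)
class TrendStats:
    parameter: str
    n: int
    mean: float
    sd: float
    slope_per_day: float
    slope_stderr: float
    slope_ci95: tuple[float, float]
    out_of_tolerance: int | None          # None without a baseline
    projected_out_of_tolerance: bool | None


def trend_stats(series: TrendSeries, parameter: str,
                window: int | None = None,
                baseline: Baseline | None = None,
                horizon_days: float = 30.0) -> TrendStats:
    """Mean, SD, OLS drift slope (per day) and tolerance flags for one
    parameter of a stored series.

    ``window`` restricts the fit to the most recent N records.  With a
    baseline, counts records outside tolerance and flags a drift whose
    linear projection ``horizon_days`` past the last record would leave
    tolerance.  Raises :class:`InsufficientDataError` below 2 records.
    """
    t = series.times_days()
    v = series.values(parameter)
    if window is not None:
        t, v = t[-window:], v[-window:]
    keep = np.isfinite(v)
    t, v = t[keep], v[keep]
    if v.size < 2:
        raise InsufficientDataError(
            f"trend of {parameter!r} needs >= 2 records, got {v.size}")
    if np.ptp(t) == 0:
        raise InsufficientDataError("all records share one timestamp")
    fit = stats.linregress(t, v)
    stderr = float(fit.stderr) if np.isfinite(fit.stderr) else 0.0
    tcrit = stats.t.ppf(0.975, df=max(v.size - 2, 1))
    ci = (float(fit.slope - tcrit * stderr), float(fit.slope + tcrit * stderr))

    out_count, projected = None, None
    spec = baseline.parameters.get(parameter) if baseline else None
    if spec is not None:
        tol = spec.absolute_tolerance
        out_count = int(np.sum(np.abs(v - spec.preset) > tol))
        future = fit.intercept + fit.slope * (t[-1] + horizon_days)
        projected = bool(abs(future - spec.preset) > tol)
    return TrendStats(
        parameter=parameter, n=int(v.size),
        mean=float(v.mean()), sd=float(v.std(ddof=1) if v.size > 1 else 0.0),
        slope_per_day=float(fit.slope), slope_stderr=stderr, slope_ci95=ci,
        out_of_tolerance=out_count, projected_out_of_tolerance=projected,
    )
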