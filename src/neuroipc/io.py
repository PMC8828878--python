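"""Readers and writers for the on-disk formats.

Conventions: tab-separated files with a header row, '.' decimal, UTF-8;
floats preserved to 12 significant digits; times in seconds with t = 0 at the
first acquired volume of a run; events follow the BIDS events layout
(onset, duration, trial_type) plus a ``run`` column.  Every writer places the
provenance (seed, TR, units) in a JSON sidecar next to the data file.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import FitResult
from .paradigm import Paradigm
from .timeseries import SampledBOLD, TimeSeries

__all__ = [
    "ParseError",
    "write_timeseries_tsv",
    "read_timeseries_tsv",
    "write_bold_tsv",
    "read_bold_tsv",
    "write_events_tsv",
    "read_events_tsv",
    "write_json",
    "read_json",
    "fit_result_to_dict",
]

_FLOAT_FMT = "%.12g"


class ParseError(ValueError):
    """Raised for malformed tabular input; carries the offending line number."""


def _check_numeric(df: pd.DataFrame, cols: list, path) -> pd.DataFrame:
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: header line plus 1-based indexing
            line = int(bad.idxmax()) + 2
            raise ParseError(f"{path}: non-numeric value in column {col!r} at line {line}")
        df[col] = coerced
    return df


def write_timeseries_tsv(path, ts: TimeSeries, value_col: str = "value") -> None:
    df = pd.DataFrame({"time_s": ts.times, value_col: ts.values})
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_timeseries_tsv(path, value_col: str = "value") -> TimeSeries:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = _check_numeric(df, ["time_s", value_col], path)
    return TimeSeries.from_times(df["time_s"].to_numpy(), df[value_col].to_numpy())


def write_bold_tsv(path, bold: SampledBOLD, meta: dict | None = None) -> None:
    """Write BOLD as (time_s, bold) TSV with a JSON sidecar for metadata."""
    df = pd.DataFrame({"time_s": bold.times, "bold": bold.values})
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    sidecar = {"tr": bold.tr, "t0": bold.t0, "units": "arbitrary"}
    sidecar.update(meta or {})
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_bold_tsv(path) -> SampledBOLD:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = _check_numeric(df, ["time_s", "bold"], path)
    ts = TimeSeries.from_times(df["time_s"].to_numpy(), df["bold"].to_numpy())
    return SampledBOLD(tr=ts.dt, values=ts.values, t0=ts.t0)


def write_events_tsv(path, paradigm: Paradigm, duration_s: float | None = None) -> None:
    """Write the schedule as a BIDS-style events table plus a design sidecar."""
    dur = paradigm.tr if duration_s is None else duration_s
    rows = [
        {"onset": onset, "duration": dur, "trial_type": cond, "run": run}
        for run, onset, cond in paradigm.onsets
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    sidecar = {
        "n_runs": paradigm.n_runs,
        "volumes_per_run": paradigm.volumes_per_run,
        "tr": paradigm.tr,
        "baseline_s": paradigm.baseline_s,
        "trials_per_condition_per_run": paradigm.trials_per_condition_per_run,
        "conditions": list(paradigm.conditions),
        "seed": paradigm.seed,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_events_tsv(path) -> Paradigm:
    """Read a BIDS-style events table (with its design sidecar) back."""
    df = pd.read_csv(path, sep="\t", dtype={"trial_type": str})
    df = _check_numeric(df, ["onset", "run"], path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise ParseError(f"missing design sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    onsets = [
        (int(r), float(o), str(c))
        for r, o, c in zip(df["run"], df["onset"], df["trial_type"])
    ]
    return Paradigm(
        n_runs=int(meta["n_runs"]),
        volumes_per_run=int(meta["volumes_per_run"]),
        tr=float(meta["tr"]),
        baseline_s=float(meta["baseline_s"]),
        trials_per_condition_per_run=int(meta["trials_per_condition_per_run"]),
        conditions=tuple(meta["conditions"]),
        onsets=onsets,
        seed=int(meta["seed"]),
    )


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, allow_nan=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def fit_result_to_dict(fit: FitResult) -> dict:
    """Serializable summary of a fit (parameters, derived quantities, MSE)."""
    out = {
        "params": _jsonable(fit.params),
        "derived": _jsonable(fit.derived),
        "mse": fit.mse,
        "hrf_used": _jsonable(fit.hrf_used) if fit.hrf_used else None,
        "diagnostics": _jsonable(
            {k: v for k, v in fit.diagnostics.items() if k != "xspace_params"}
        ),
    }
    xs = fit.diagnostics.get("xspace_params")
    if xs is not None:
        out["diagnostics"]["xspace_params"] = _jsonable(xs)
    return out
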