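"""Group-level aggregation and comparative capacity summaries.

For an "overall brain performance" view, region/subject BOLD series are
averaged pointwise *before* fitting (fit-the-average, not average-the-fits).
The capacity table collects, per (group, condition) cell, the fitted relative
processing capacity p/alpha, relative storage capacity m/alpha, time constant
T_c = m/p, amplitude ratio and BOLD time-to-peak; when behavioral response
times T_r are available it also reports the T_r / T_c ratio and the
descending ordering of time constants across cells.

The report deliberately never emits absolute p, m or alpha: with impulse
information arrival only their ratios are identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimation import FitResult
from .timeseries import GridError, SampledBOLD

__all__ = ["GroupSpec", "average_series", "capacity_table"]

#: a cell whose fitted peak activity is below this fraction of the maximum
#: across cells is annotated as low-activity (interpretation caution)
_LOW_ACTIVITY_FRAC = 0.5


@dataclass
class GroupSpec:
    """A named group of datasets with an optional mean behavioral response time."""

    label: str
    members: list = field(default_factory=list)
    mean_rt: float | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.label!r} has no members")
        if self.mean_rt is not None and self.mean_rt <= 0:
            raise ValueError("mean_rt must be positive when present")


def average_series(members: list) -> SampledBOLD:
    """Pointwise mean of BOLD series on identical grids."""
    if not members:
        raise ValueError("need at least one series to average")
    first = members[0]
    for m in members[1:]:
        if len(m) != len(first) or not np.isclose(m.tr, first.tr) or not np.isclose(m.t0, first.t0):
            raise GridError("all members must share the same sampling grid")
    vals = np.mean([m.values for m in members], axis=0)
    return SampledBOLD(tr=first.tr, values=vals, t0=first.t0)


def capacity_table(
    fits: dict,
    rts: dict | None = None,
    expected_order: list | None = None,
) -> dict:
    """Tabulate relative capacities per (group, condition) cell.

    Parameters
    ----------
    fits : dict
        Maps cell keys (e.g. ``("old", "IC")``) to :class:`FitResult`; a
        missing/None cell is reported as absent, not fatal.
    rts : dict, optional
        Maps group labels to mean behavioral response times T_r (s); when
        given, each cell also reports T_r / T_c.
    expected_order : list, optional
        Cell keys in the expected descending order of T_c; the report flags
        whether the fitted ordering matches.

    Returns
    -------
    dict with keys ``cells`` (per-cell quantities), ``ordering`` (cells by
    descending fitted T_c), ``ordering_matches_expectation`` (bool or None)
    and ``markdown`` (a rendered table).
    """
    cells = {}
    peaks = {}
    for key, fit in fits.items():
        if fit is None:
            cells[key] = None
            continue
        d = fit.derived
        row = {
            "rel_processing": d.rel_processing,
            "rel_storage": d.rel_storage,
            "t_const": d.t_const,
            "amp_ratio": d.amp_ratio,
            "t_peak": d.t_peak,
            "mse": fit.mse,
        }
        group = key[0] if isinstance(key, tuple) else key
        if rts and group in rts:
            row["rt"] = rts[group]
            row["rt_over_tc"] = rts[group] / d.t_const
        cells[key] = row
        peaks[key] = fit.params.a

    fitted = {k: v for k, v in cells.items() if v is not None}
    ordering = sorted(fitted, key=lambda k: -fitted[k]["t_const"]) if len(fitted) > 1 else []
    matches = None
    if expected_order is not None and ordering:
        matches = list(ordering) == list(expected_order)

    low_activity = []
    if peaks:
        top = max(peaks.values())
        low_activity = [k for k, a in peaks.items() if a < _LOW_ACTIVITY_FRAC * top]

    lines = ["| cell | p/alpha | m/alpha | T_c (s) | t_peak (s) | T_r/T_c | MSE |",
             "|---|---|---|---|---|---|---|"]
    for key in fits:
        row = cells.get(key)
        if row is None:
            lines.append(f"| {key} | absent | | | | | |")
            continue
        rt_tc = f"{row['rt_over_tc']:.3g}" if "rt_over_tc" in row else "-"
        lines.append(
            f"| {key} | {row['rel_processing']:.4g} | {row['rel_storage']:.4g} "
            f"| {row['t_const']:.4g} | {row['t_peak']:.3g} | {rt_tc} | {row['mse']:.3g} |"
        )
    if ordering:
        lines.append("")
        lines.append("Descending T_c ordering: " + " >= ".join(str(k) for k in ordering))
        if matches is not None:
            lines.append(f"Matches expected ordering: {matches}")
    for k in low_activity:
        lines.append(
            f"Note: cell {k} shows anomalously low fitted activity relative to the other "
            "cells; low neuronal activity does not by itself imply higher processing "
            "capacity — interpret its relative capacities with caution."
        )

    return {
        "cells": cells,
        "ordering": ordering,
        "ordering_matches_expectation": matches,
        "low_activity_cells": low_activity,
        "markdown": "\n".join(lines),
    }
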