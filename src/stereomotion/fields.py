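"""Prediction vector fields over an orientation-disparity grid.

For a fixed viewing geometry and trajectory, the stimulus line's orientation
disparity is swept over a grid (default -6 to +6 deg in 0.1 deg steps) and
each selected strategy's predicted velocity is tabulated in both cartesian
and spherical form. The table is deterministic: regenerating it yields
byte-identical output.
"""
from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .spherical import to_spherical
from .stimulus import (
    DegenerateStimulusError,
    StimulusSpec,
    ViewingGeometry,
    make_motion_event,
)
from . import strategies as _strat

COLUMNS = (
    "delta_deg",
    "strategy",
    "status",
    "vx",
    "vy",
    "vz",
    "azimuth_deg",
    "elevation_deg",
    "speed",
)

_RUNNERS = {
    _strat.VN: _strat.vn_predict,
    _strat.CA: _strat.ca_predict,
    _strat.IOVD: _strat.iovd_predict,
    _strat.CDOT: _strat.cdot_predict,
}


@dataclass(frozen=True)
class FieldRow:
    """One grid cell: orientation disparity, strategy, and its prediction in
    cartesian (cm/unit time) and spherical (deg) form; velocity fields are
    NaN when the prediction is not status ``ok``."""

    delta_deg: float
    strategy: str
    status: str
    vx: float
    vy: float
    vz: float
    azimuth_deg: float
    elevation_deg: float
    speed: float


def delta_grid(
    d_min: float = -6.0,
    d_max: float = 6.0,
    step: float = 0.1,
    endpoint: str = "inclusive",
) -> np.ndarray:
    """Orientation-disparity grid in degrees.

    ``inclusive`` keeps both endpoints (121 points for the default range);
    ``drop-last`` omits the final one (120 points).
    """
    if step <= 0 or d_max < d_min:
        raise ValueError("require step > 0 and d_max >= d_min")
    n = int(round((d_max - d_min) / step))
    vals = d_min + step * np.arange(n + 1)
    if endpoint == "drop-last":
        return vals[:-1]
    if endpoint != "inclusive":
        raise ValueError("endpoint must be 'inclusive' or 'drop-last'")
    return vals


def _row(delta: float, strategy: str, pred) -> FieldRow:
    if pred is not None and pred.status == "ok":
        sph = to_spherical(pred.velocity)
        return FieldRow(
            delta_deg=float(delta),
            strategy=strategy,
            status=pred.status,
            vx=float(pred.velocity[0]),
            vy=float(pred.velocity[1]),
            vz=float(pred.velocity[2]),
            azimuth_deg=sph.azimuth_deg,
            elevation_deg=sph.elevation_deg,
            speed=sph.speed,
        )
    status = "undefined" if pred is None else pred.status
    nan = math.nan
    return FieldRow(float(delta), strategy, status, nan, nan, nan, nan, nan, nan)


def prediction_field(
    g: ViewingGeometry,
    base_spec: StimulusSpec,
    deltas,
    strategies=(_strat.VN, _strat.CA),
) -> list[FieldRow]:
    """One FieldRow per (orientation disparity, strategy), sorted by
    (strategy, disparity). Degenerate disparities are recorded with status
    ``undefined`` rather than aborting the sweep."""
    deltas = list(deltas)
    strategies = list(strategies)
    if not deltas:
        raise ValueError("disparity grid must be nonempty")
    if not strategies:
        raise ValueError("at least one strategy is required")
    unknown = set(strategies) - set(_RUNNERS)
    if unknown:
        raise ValueError(f"unknown strategies: {sorted(unknown)}")

    rows: list[FieldRow] = []
    for delta in deltas:
        try:
            event = make_motion_event(g, base_spec.with_disparity(delta))
        except DegenerateStimulusError:
            event = None
        for strat in strategies:
            pred = None if event is None else _RUNNERS[strat](event)
            rows.append(_row(delta, strat, pred))
    rows.sort(key=lambda r: (r.strategy, r.delta_deg))
    return rows


def field_frame(rows: list[FieldRow]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in rows], columns=list(COLUMNS))


def write_field(rows: list[FieldRow], path, fmt: str = "csv") -> None:
    """Write a field table as CSV (comma-separated, '.' decimal, LF line
    endings) or as JSON records; identical rows produce identical bytes."""
    frame = field_frame(rows)
    if fmt == "csv":
        frame.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")
    elif fmt == "json":
        frame.to_json(path, orient="records", double_precision=12)
    else:
        raise ValueError("fmt must be 'csv' or 'json'")
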