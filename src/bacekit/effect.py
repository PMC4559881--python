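"""Pharmacodynamic effect summaries.

Normalization of biomarker time courses to predose baseline, area under
the effect curve (AUEC) over a dosing interval expressed as a
time-averaged percent reduction, and signed group percent-change
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

NORMALIZATIONS = ("raw", "pct_predose", "pct_vehicle", "pct_reduction")


class EffectError(ValueError):
    pass


@dataclass(frozen=True)
class EffectSeries:
    """A biomarker effect time course.

    times are hours (negative = predose); values are analyte units when
    ``normalization == 'raw'`` and dimensionless percents otherwise.
    ``predose_mean`` records the baseline used by a predose
    normalization, enabling an exact round trip back to raw values.
    """

    times: np.ndarray
    values: np.ndarray
    normalization: str = "raw"
    predose_mean: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.shape != t.shape:
            raise EffectError("times and values must be 1-d and equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise EffectError("times must be strictly increasing")
        if np.any(v < 0):
            raise EffectError("values must be >= 0")
        if self.normalization not in NORMALIZATIONS:
            raise EffectError(f"unknown normalization {self.normalization!r}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


def normalize_to_predose(series: EffectSeries, predose_times) -> EffectSeries:
    """Express values as percent of the mean of the named predose samples.

    Every requested predose time must be present in the series; the
    predose mean must be positive.  Applying the normalization to an
    already percent-of-predose series whose baseline samples sit at
    100 % is idempotent.
    """
    predose_times = np.asarray(predose_times, dtype=float)
    idx = []
    for pt in predose_times:
        hits = np.flatnonzero(np.isclose(series.times, pt))
        if hits.size == 0:
            raise EffectError(f"missing predose sample at t = {pt} h")
        idx.append(hits[0])
    baseline = float(series.values[idx].mean())
    if baseline <= 0:
        raise EffectError("predose mean must be > 0")
    return replace(
        series,
        values=100.0 * series.values / baseline,
        normalization="pct_predose",
        predose_mean=baseline,
    )


def denormalize_from_predose(series: EffectSeries) -> EffectSeries:
    """Invert :func:`normalize_to_predose` using the stored baseline."""
    if series.normalization != "pct_predose" or series.predose_mean is None:
        raise EffectError("series is not predose-normalized")
    return replace(
        series,
        values=series.values * series.predose_mean / 100.0,
        normalization="raw",
        predose_mean=None,
    )


def auec_reduction(timepoints, reductions, window: tuple[float, float]) -> float:
    """Time-averaged percent reduction over a dosing interval.

    Linear-trapezoid area of the reduction-vs-time curve over
    ``window``, divided by the window length.  Endpoints must be covered
    by the supplied timepoints (values at interior window endpoints are
    linearly interpolated, making the average invariant under insertion
    of collinear points).
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(reductions, dtype=float)
    if t.ndim != 1 or y.shape != t.shape:
        raise EffectError("timepoints and reductions must be 1-d and equal length")
    if np.any(np.diff(t) <= 0):
        raise EffectError("timepoints must be strictly increasing")
    a, b = float(window[0]), float(window[1])
    if b <= a:
        raise EffectError("window end must exceed its start")
    if a < t[0] - 1e-12 or b > t[-1] + 1e-12:
        raise EffectError(f"window [{a}, {b}] h not covered by timepoints")
    inside = (t > a) & (t < b)
    if t[(t >= a) & (t <= b)].size < 2:
        raise EffectError("need >= 2 timepoints inside the window")
    grid = np.concatenate(([a], t[inside], [b]))
    vals = np.concatenate(([np.interp(a, t, y)], y[inside], [np.interp(b, t, y)]))
    return float(np.trapezoid(vals, grid) / (b - a))


def auec_24h_steady_state(reduction_4h: float, reduction_24h: float) -> float:
    """AUEC over 0–24 h from the 4 h and 24 h reductions at once-daily steady state.

    At steady state the effect at t = 0 (immediately before the dose)
    equals the trough effect at t = 24 h, so the curve is assembled from
    the points (0, r24), (4, r4), (24, r24).
    """
    return auec_reduction(
        [0.0, 4.0, 24.0], [reduction_24h, reduction_4h, reduction_24h], (0.0, 24.0)
    )


def group_percent_change(group_mean: float, reference_mean: float) -> float:
    """Signed percent change of a group mean versus a reference mean.

    100 × (group − reference)/reference; negative values are reductions.
    Satisfies change = −percent_inhibition for the same pair.
    """
    if reference_mean <= 0:
        raise EffectError("reference mean must be > 0")
    return 100.0 * (group_mean - reference_mean) / reference_mean
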