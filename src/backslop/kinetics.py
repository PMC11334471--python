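"""Acidification-parameter extraction from pH time courses.

Three parameters are extracted per fermentation curve:

* **MAR** (maximum acidification rate): the lowest slope among ordinary
  least-squares lines fitted on a sliding window of ``window_points``
  consecutive samples (20 by default; 95 min at 5-min logging).  Stored
  signed, so acidifying curves give negative values.
* **lag time**: intersection of the MAR regression line with the horizontal
  line at the curve's first pH value — the time before the pH drop begins.
* **final pH**: an OLS line over the curve's last ``window_points`` samples,
  evaluated at the step's nominal horizon (24 h for F1, 18 h for F2..F6).

All fits use the actual timestamps, so irregularly spaced logs are handled;
for uniform spacing this is identical to index-based fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import PHTimeCourse, PipelineConfig

__all__ = [
    "WindowModel",
    "AcidificationParams",
    "sliding_window_slopes",
    "max_acidification_rate",
    "lag_time",
    "final_ph",
    "extract_params",
    "delta_params",
]


@dataclass(frozen=True)
class WindowModel:
    """OLS line over one window: ``ph ~ intercept + slope * t`` (t in hours)."""

    start_index: int
    slope: float
    intercept: float


@dataclass(frozen=True)
class AcidificationParams:
    """Extracted parameters for one curve; NaN fields mean 'undefined'."""

    lineage_id: str
    step: str
    lag_h: float
    mar: float  # pH / h, signed (negative = acidifying)
    final_ph: float
    mar_window_start_index: int
    mar_intercept: float
    eligible: bool
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def acidifying(self) -> bool:
        return self.eligible and np.isfinite(self.mar) and self.mar < 0


def _window_fits(times: np.ndarray, ph: np.ndarray, window_points: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-window OLS slopes and intercepts (intercept at t = 0)."""
    tw = np.lib.stride_tricks.sliding_window_view(times, window_points)
    yw = np.lib.stride_tricks.sliding_window_view(ph, window_points)
    tmean = tw.mean(axis=1, keepdims=True)
    ymean = yw.mean(axis=1, keepdims=True)
    tc = tw - tmean
    slopes = (tc * yw).sum(axis=1) / (tc * tc).sum(axis=1)
    intercepts = ymean[:, 0] - slopes * tmean[:, 0]
    return slopes, intercepts


def sliding_window_slopes(curve: PHTimeCourse, window_points: int = 20) -> list[WindowModel]:
    """All OLS lines on windows of ``window_points`` consecutive samples.

    Returns ``len(curve) - window_points + 1`` models (one per start index),
    or an empty list when the curve is shorter than one window.
    """
    if len(curve) < window_points:
        return []
    slopes, intercepts = _window_fits(curve.times, curve.ph, window_points)
    return [
        WindowModel(start_index=i, slope=float(s), intercept=float(b))
        for i, (s, b) in enumerate(zip(slopes, intercepts))
    ]


def max_acidification_rate(
    curve: PHTimeCourse, window_points: int = 20
) -> tuple[float, WindowModel]:
    """Lowest window slope (most negative = fastest acidification).

    Ties are broken toward the earliest window.  Raises ``ValueError`` on a
    curve shorter than one window; use :func:`extract_params` for the
    flag-propagating batch behaviour.
    """
    if len(curve) < window_points:
        raise ValueError(
            f"curve {curve.lineage_id}/{curve.step} shorter than one window"
        )
    slopes, intercepts = _window_fits(curve.times, curve.ph, window_points)
    # earliest-window tie-break: slopes within a few ulps of the minimum are
    # exact ties up to round-off (e.g. every window on a noiseless line)
    smin = float(np.min(slopes))
    tol = 64 * np.finfo(float).eps * max(1.0, abs(smin))
    i = int(np.argmax(slopes <= smin + tol))
    model = WindowModel(start_index=i, slope=float(slopes[i]), intercept=float(intercepts[i]))
    return model.slope, model


def lag_time(curve: PHTimeCourse, mar_model: WindowModel) -> tuple[float, tuple[str, ...]]:
    """Time at which the MAR line crosses the initial-pH horizontal.

    Solves ``intercept + slope * t = ph[0]``.  A negative intersection (seen
    on noisy curves whose steepest window starts immediately) is clamped to 0
    with a ``lag_clamped`` flag; a non-negative MAR slope means the curve
    never acidified and the lag is undefined (NaN, ``non_acidifying``).
    """
    # slopes within round-off of zero (constant curves) are not acidification
    if not np.isfinite(mar_model.slope) or mar_model.slope >= -1e-12:
        return float("nan"), ("non_acidifying",)
    t_star = (curve.ph[0] - mar_model.intercept) / mar_model.slope
    if t_star < 0:
        return 0.0, ("lag_clamped",)
    return float(t_star), ()


def final_ph(
    curve: PHTimeCourse, horizon_h: float, window_points: int = 20
) -> tuple[float, tuple[str, ...]]:
    """OLS line over the last ``window_points`` samples, evaluated at the horizon.

    Performed whether the horizon lies before (interpolation) or after the
    last timestamp; extrapolating more than 2 h past the curve end is flagged
    ``long_extrapolation``.
    """
    if len(curve) < window_points:
        return float("nan"), ("ineligible",)
    t = curve.times[-window_points:]
    y = curve.ph[-window_points:]
    tc = t - t.mean()
    slope = float((tc * y).sum() / (tc * tc).sum())
    intercept = float(y.mean() - slope * t.mean())
    value = intercept + slope * horizon_h
    flags: tuple[str, ...] = ()
    if horizon_h > curve.times[-1] + 2.0:
        flags = ("long_extrapolation",)
    return value, flags


def extract_params(
    curve: PHTimeCourse,
    config: PipelineConfig | None = None,
    horizon_h: float | None = None,
) -> AcidificationParams:
    """Compose MAR, lag and final-pH extraction for one curve.

    Deterministic for fixed input and config.  Ineligible curves (shorter
    than two windows) and non-acidifying curves produce flagged NaN fields
    rather than raising, so batch runs never abort.
    """
    config = config or PipelineConfig()
    w = config.window_points
    if horizon_h is None:
        horizon_h = config.horizons.get(curve.step, 18.0)
    if not curve.is_eligible(w):
        return AcidificationParams(
            lineage_id=curve.lineage_id,
            step=curve.step,
            lag_h=float("nan"),
            mar=float("nan"),
            final_ph=float("nan"),
            mar_window_start_index=-1,
            mar_intercept=float("nan"),
            eligible=False,
            flags=("ineligible",),
        )
    mar, model = max_acidification_rate(curve, w)
    lag, lag_flags = lag_time(curve, model)
    fph, fph_flags = final_ph(curve, horizon_h, w)
    return AcidificationParams(
        lineage_id=curve.lineage_id,
        step=curve.step,
        lag_h=lag,
        mar=mar,
        final_ph=fph,
        mar_window_start_index=model.start_index,
        mar_intercept=model.intercept,
        eligible=True,
        flags=tuple(lag_flags) + tuple(fph_flags),
    )


def delta_params(params_by_step: dict[str, AcidificationParams]) -> list[dict]:
    """Adjacent-step parameter differences over F2..F6.

    For each adjacent pair (n, n+1) present and eligible, returns a record
    with signed deltas (value at n+1 minus value at n) and their absolute
    values.  Pairs with a missing or ineligible member are omitted.
    Individual deltas are NaN when a component (e.g. an undefined lag) is.
    """
    from .io_formats import DYNAMICS_STEPS

    out: list[dict] = []
    for a, b in zip(DYNAMICS_STEPS, DYNAMICS_STEPS[1:]):
        pa, pb = params_by_step.get(a), params_by_step.get(b)
        if pa is None or pb is None or not (pa.eligible and pb.eligible):
            continue
        rec = {
            "step_pair": f"{a}-{b}",
            "d_lag_h": pb.lag_h - pa.lag_h,
            "d_mar": pb.mar - pa.mar,
            "d_final_ph": pb.final_ph - pa.final_ph,
        }
        rec.update({f"abs_{k}": abs(v) for k, v in list(rec.items())[1:]})
        out.append(rec)
    return out
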