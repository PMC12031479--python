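"""The twelve stance-phase parameters.

Landmark indices are detected on the filtered signal but every force value
is read off the unfiltered, interpolated, normalized signal to avoid
over-smoothing of magnitudes.  Parameters fall into three families:

* force read-offs: F_total_max (always available) and F_mean_TP;
* trendline parameters: slope / MAE / RMSE of the least-squares line
  through the unfiltered forces between the two maxima (inter-max) or
  between the enclosing turning points (inter-TP);
* timing parameters: absolute seconds and %-of-stance-duration between the
  maxima or the turning points.

The inter-max family requires more than one surviving maximum and is
absent otherwise; the inter-TP family is absent when fewer than two
inflection points exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional, Tuple

import numpy as np

from .data import PARAMETER_NAMES, NormalizedStance
from .landmarks import LandmarkSet


@dataclass(frozen=True)
class StrideParameters:
    """Parameter values of one stance phase; ``None`` marks absence."""

    F_mean_TP: Optional[float]
    F_total_max: float
    F_trendline_max_slope: Optional[float]
    F_trendline_TP_slope: Optional[float]
    L1_trendline_max: Optional[float]
    L1_trendline_TP: Optional[float]
    L2_trendline_max: Optional[float]
    L2_trendline_TP: Optional[float]
    Time_inter_max: Optional[float]
    Time_inter_max_normalized: Optional[float]
    Time_inter_TP: Optional[float]
    Time_inter_TP_normalized: Optional[float]

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}


def trendline(y: np.ndarray, i_from: int, i_to: int) -> Tuple[float, float, float, float]:
    """Least-squares line through ``y[i_from..i_to]`` (inclusive).

    The regressor is the array index, so the slope is in signal units per
    index step — on the 100-sample grid, per percent of stance duration.
    Returns (slope, intercept, MAE, RMSE) of the residuals.
    """
    if i_to <= i_from:
        raise ValueError("trendline needs at least 2 points (i_to > i_from)")
    t = np.arange(i_from, i_to + 1, dtype=float)
    seg = np.asarray(y, dtype=float)[i_from : i_to + 1]
    tc = t - t.mean()
    slope = float(np.dot(tc, seg) / np.dot(tc, tc))
    intercept = float(seg.mean() - slope * t.mean())
    resid = seg - (slope * t + intercept)
    mae = float(np.mean(np.abs(resid)))
    rmse = float(math.sqrt(np.mean(resid**2)))
    return slope, intercept, mae, rmse


def compute_parameters(
    ns: NormalizedStance,
    lm: LandmarkSet,
    *,
    strict_table1_denominator: bool = False,
) -> StrideParameters:
    """Compute all available parameters for one stance.

    ``strict_table1_denominator`` switches F_mean_TP from the mean over
    the inclusive sample count (default) to the literal span denominator
    ``i_tp2 - i_tp1``.

    Timing parameters use the absolute-time map
    ``abs(i) = stance_start_s + (i/99) * duration_s`` and are reported as
    positive magnitudes; normalized timings are index spans on the
    100-sample grid, i.e. percent of stance duration.
    """
    y = ns.y_unfiltered
    f_total_max = float(np.max(y))

    f_mean_tp = f_tl_tp_slope = l1_tp = l2_tp = None
    t_tp = t_tp_norm = None
    if lm.i_tp1 is not None and lm.i_tp2 is not None:
        seg_sum = float(np.sum(y[lm.i_tp1 : lm.i_tp2 + 1]))
        denom = (lm.i_tp2 - lm.i_tp1) if strict_table1_denominator else (lm.i_tp2 - lm.i_tp1 + 1)
        f_mean_tp = seg_sum / denom
        f_tl_tp_slope, _, l1_tp, l2_tp = trendline(y, lm.i_tp1, lm.i_tp2)
        # |abs(i2) - abs(i1)| reduces to the index span over the duration,
        # which is exactly invariant to the recording's time offset
        t_tp = abs(lm.i_tp2 - lm.i_tp1) / 99.0 * ns.duration_s
        t_tp_norm = abs(lm.i_tp2 - lm.i_tp1) / 100.0 * 100.0

    f_tl_max_slope = l1_max = l2_max = None
    t_max = t_max_norm = None
    if lm.has_multiple_maxima:
        f_tl_max_slope, _, l1_max, l2_max = trendline(y, lm.i_max_first, lm.i_max_last)
        t_max = abs(lm.i_max_last - lm.i_max_first) / 99.0 * ns.duration_s
        t_max_norm = abs(lm.i_max_last - lm.i_max_first) / 100.0 * 100.0

    return StrideParameters(
        F_mean_TP=f_mean_tp,
        F_total_max=f_total_max,
        F_trendline_max_slope=f_tl_max_slope,
        F_trendline_TP_slope=f_tl_tp_slope,
        L1_trendline_max=l1_max,
        L1_trendline_TP=l1_tp,
        L2_trendline_max=l2_max,
        L2_trendline_TP=l2_tp,
        Time_inter_max=t_max,
        Time_inter_max_normalized=t_max_norm,
        Time_inter_TP=t_tp,
        Time_inter_TP_normalized=t_tp_norm,
    )
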