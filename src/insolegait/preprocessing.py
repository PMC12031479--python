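"""Smoothing, bodyweight normalization and duration normalization.

The order of operations matters: the Gaussian filter (sigma = 4 samples,
i.e. 40 ms at 100 Hz) runs on the raw uniform grid where sigma has physical
meaning, and only then is the stance resampled with a natural cubic spline
to 100 equidistant samples.  Both a filtered and an unfiltered variant are
produced: shape landmarks are found on the filtered signal, force values
are read off the unfiltered one to avoid over-smoothing of magnitudes.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter1d

from .data import GRAVITY, NormalizedStance, StanceEvent

DEFAULT_SIGMA = 4.0
N_NORMALIZED = 100


def gaussian_smooth(y: np.ndarray, sigma: float = DEFAULT_SIGMA) -> np.ndarray:
    """Gaussian low-pass filter with reflect boundary handling.

    ``sigma`` is in samples.  The kernel is truncated at 4 sigma; output
    length equals input length.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("gaussian_smooth needs at least 2 samples")
    return gaussian_filter1d(y, sigma=sigma, mode="reflect", truncate=4.0)


def to_percent_bodyweight(y: np.ndarray, body_mass_kg: float) -> np.ndarray:
    """Convert newtons to percent of body weight (mass * g, g = 9.81)."""
    if not body_mass_kg > 0:
        raise ValueError(f"body_mass_kg must be > 0, got {body_mass_kg}")
    return 100.0 * np.asarray(y, dtype=float) / (body_mass_kg * GRAVITY)


def resample_to_100(y: np.ndarray, n_out: int = N_NORMALIZED) -> np.ndarray:
    """Natural cubic spline resampling to ``n_out`` equidistant samples.

    The spline interpolates (i, y_i) with natural boundary conditions
    (zero second derivative at both ends) and is evaluated on a uniform
    grid spanning the full input; endpoints are reproduced exactly.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 4:
        raise ValueError("resample_to_100 needs at least 4 samples")
    x = np.arange(y.size, dtype=float)
    spline = CubicSpline(x, y, bc_type="natural")
    return spline(np.linspace(0.0, y.size - 1.0, n_out))


def preprocess_stance(ev: StanceEvent) -> NormalizedStance:
    """Turn a stance event into its 100-sample %bodyweight representation.

    Produces the filtered variant (smooth -> resample) and the unfiltered
    variant (resample only), both normalized to percent bodyweight.
    """
    rec = ev.source
    pbw = to_percent_bodyweight(ev.samples, rec.body_mass_kg)
    y_unfiltered = resample_to_100(pbw)
    y_filtered = resample_to_100(gaussian_smooth(pbw))
    return NormalizedStance(
        y_unfiltered=y_unfiltered,
        y_filtered=y_filtered,
        duration_s=ev.duration_ms / 1000.0,
        stance_start_s=ev.start_time_s,
        subject_id=rec.subject_id,
        side=rec.side,
        side_role=rec.side_role,
        days_after_surgery=rec.days_after_surgery,
    )
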