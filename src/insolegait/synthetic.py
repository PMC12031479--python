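"""Seeded synthetic insole recordings and longitudinal cohorts.

Patient recordings of this kind cannot be shared publicly, so every
pipeline stage is exercised on synthetic 100 Hz bilateral force traces
with known ground truth.  The generator emulates the characteristic
recovery morphology after a tibial fracture: early stances are flat and
plateau-like (careful foot placement without heel-to-toe roll), and over
recovery the curve morphs back to the healthy M-shape with two pronounced
maxima.  Sensor dropout faults and Gaussian noise are applied last.

Stance bumps are built from raised-cosine (cosine-eased) segments between
control points, so the true extremum positions are known in closed form —
the derivative vanishes exactly at each control point.

A cohort draws, per subject and visit, a stride count in 8..15 (a ~9 m
straight walk), a regular/non-regular label per stride with probability
p(d) = min(1, exp(a + b * d)) of being regular at d days after surgery,
and per-stride shape parameters from per-subject recovery trends.  The
defaults for (a, b) are the log-linear ratio models reported for healthy
(-3.18, 0.02) and injured (-2.38, 0.014) sides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import GRAVITY, RawRecording, Side, SideRole, write_recording

MAX_STUDY_DAY = 175


@dataclass
class CurveSpec:
    """Recipe for one synthetic stance curve (heights in %bodyweight)."""

    shape: str = "m_shape"  # m_shape | plateau | single_hump
    peak1_height: float = 110.0
    peak2_height: float = 105.0
    valley_depth: float = 80.0
    peak_positions: Tuple[float, float] = (0.25, 0.75)
    duration_s: float = 1.0
    noise_sd: float = 0.0  # %BW
    dropout_prob: float = 0.0
    body_mass_kg: float = 75.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("m_shape", "plateau", "single_hump"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if not 0.3 <= self.duration_s <= 3.5:
            raise ValueError("duration_s must lie within the stance bounds [0.3, 3.5] s")
        if self.shape == "m_shape":
            if not (self.peak1_height > self.valley_depth and self.peak2_height > self.valley_depth):
                raise ValueError("m_shape requires peaks above the valley")
        p1, p2 = self.peak_positions
        if not 0.0 < p1 < p2 < 1.0:
            raise ValueError("peak_positions must satisfy 0 < p1 < p2 < 1")


def _cosine_ease(t: np.ndarray, points: Sequence[Tuple[float, float]]) -> np.ndarray:
    """Piecewise raised-cosine interpolation through (t, y) control points.

    Each segment eases from one control value to the next with zero slope
    at both ends, so control points are exact local extrema.
    """
    t = np.asarray(t, dtype=float)
    y = np.empty_like(t)
    for (t0, y0), (t1, y1) in zip(points[:-1], points[1:]):
        m = (t >= t0) & (t <= t1)
        u = (t[m] - t0) / (t1 - t0)
        y[m] = y0 + (y1 - y0) * (1.0 - np.cos(np.pi * u)) / 2.0
    return y


def make_stance_curve(spec: CurveSpec) -> np.ndarray:
    """Generate one stance as a raw 100 Hz force sequence in newtons.

    Deterministic for a fixed seed.  Missing samples (dropout) are NaN.
    """
    rng = np.random.default_rng(spec.seed)
    n = max(4, round(spec.duration_s * 100))
    t = np.arange(n) / (n - 1)
    p1, p2 = spec.peak_positions
    if spec.shape == "m_shape":
        pts = [(0.0, 0.0), (p1, spec.peak1_height),
               ((p1 + p2) / 2.0, spec.valley_depth),
               (p2, spec.peak2_height), (1.0, 0.0)]
        pbw = _cosine_ease(t, pts)
    elif spec.shape == "single_hump":
        pts = [(0.0, 0.0), (0.5, spec.peak1_height), (1.0, 0.0)]
        pbw = _cosine_ease(t, pts)
    else:  # plateau: trapezoid with linear ramps and a flat top
        h = spec.peak1_height
        pbw = np.interp(t, [0.0, 0.15, 0.85, 1.0], [0.0, h, h, 0.0])
    if spec.noise_sd > 0:
        pbw = pbw + rng.normal(0.0, spec.noise_sd, size=n)
    force = np.clip(pbw, 0.0, None) / 100.0 * spec.body_mass_kg * GRAVITY
    if spec.dropout_prob > 0:
        force[rng.random(n) < spec.dropout_prob] = np.nan
    return force


@dataclass
class CohortSpec:
    """Study-scale longitudinal cohort with known recovery trends.

    The regular-stride probability follows p(d) = min(1, exp(a + b d))
    per side; per-parameter morphology trends move the stance shape from
    plateau-like to M-shaped over ``max_day`` days.
    """

    n_subjects: int = 13
    visits_range: Tuple[int, int] = (3, 7)
    max_day: int = MAX_STUDY_DAY
    ratio_intercepts: Dict[str, float] = field(
        default_factory=lambda: {"healthy": -3.18, "injured": -2.38})
    ratio_slopes: Dict[str, float] = field(
        default_factory=lambda: {"healthy": 0.02, "injured": 0.014})
    strides_range: Tuple[int, int] = (8, 15)
    noise_sd: float = 3.0  # %BW
    dropout_prob: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        for side, b in self.ratio_slopes.items():
            if b < 0:
                raise ValueError(f"ratio slope for {side} must be >= 0")

    def p_regular(self, role: str, day: float) -> float:
        return min(1.0, math.exp(self.ratio_intercepts[role] + self.ratio_slopes[role] * day))


def _visit_days(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw a subject's visit schedule: an early post-op visit plus later
    follow-ups spread over the study window, all distinct."""
    n_visits = int(rng.integers(spec.visits_range[0], spec.visits_range[1] + 1))
    days = {int(rng.integers(3, 11))}
    while len(days) < n_visits:
        days.add(int(rng.integers(14, spec.max_day + 1)))
    return np.array(sorted(days))


def _stride_curve_spec(spec: CohortSpec, role: str, day: float, regular: bool,
                       mass: float, rng: np.random.Generator) -> CurveSpec:
    """Draw the shape recipe for a single stride at ``day`` days post-op."""
    frac = day / spec.max_day
    jitter = lambda s: 1.0 + rng.normal(0.0, s)
    seed = int(rng.integers(0, 2**31 - 1))
    if regular:
        if role == "injured":
            base = 72.0 + 38.0 * frac
            vdiff = 8.0 + 12.0 * frac
            duration = 1.1 - 0.3 * frac
        else:
            base = 105.0 + 8.0 * frac
            vdiff = 18.0 + 4.0 * frac
            duration = 0.8
        peak1 = base * jitter(0.04)
        peak2 = (base - 4.0) * jitter(0.04)
        valley = min(peak1, peak2) - vdiff * jitter(0.1)
        return CurveSpec(
            shape="m_shape",
            peak1_height=peak1,
            peak2_height=peak2,
            valley_depth=max(valley, 20.0),
            peak_positions=(0.25 + rng.normal(0, 0.02), 0.75 + rng.normal(0, 0.02)),
            duration_s=float(np.clip(duration * jitter(0.06), 0.5, 2.0)),
            noise_sd=spec.noise_sd,
            dropout_prob=spec.dropout_prob,
            body_mass_kg=mass,
            seed=seed,
        )
    if role == "injured":
        height = (45.0 + 40.0 * frac) * jitter(0.06)
        duration = 1.5 - 0.4 * frac
    else:
        height = (85.0 + 10.0 * frac) * jitter(0.06)
        duration = 1.0
    shape = "single_hump" if rng.random() < 0.3 else "plateau"
    return CurveSpec(
        shape=shape,
        peak1_height=height + (10.0 if shape == "single_hump" else 0.0),
        duration_s=float(np.clip(duration * jitter(0.06), 0.5, 2.5)),
        noise_sd=spec.noise_sd,
        dropout_prob=spec.dropout_prob,
        body_mass_kg=mass,
        seed=seed,
    )


def make_cohort(spec: CohortSpec) -> Tuple[List[RawRecording], pd.DataFrame]:
    """Generate the cohort's recordings and the per-visit ground truth.

    Returns one :class:`RawRecording` per (subject, visit, side) and a
    truth table holding, per visit and side, the regular-stride
    probability used, the labels actually drawn, and the morphology trend
    values — enough to compute every stage's expected output without
    re-running the generator.
    """
    rng = np.random.default_rng(spec.seed)
    recordings: List[RawRecording] = []
    truth_rows: List[dict] = []
    for si in range(spec.n_subjects):
        subject_id = f"S{si + 1:02d}"
        mass = float(np.clip(rng.normal(75.0, 12.0), 50.0, 110.0))
        injured_side = Side.LEFT if rng.random() < 0.5 else Side.RIGHT
        days = _visit_days(spec, rng)
        for day in days:
            for side in (Side.LEFT, Side.RIGHT):
                role = SideRole.INJURED if side == injured_side else SideRole.HEALTHY
                p_reg = spec.p_regular(role.value, day)
                n_strides = int(rng.integers(spec.strides_range[0], spec.strides_range[1] + 1))
                pieces = [np.zeros(int(rng.integers(30, 60)))]
                n_regular = 0
                for _ in range(n_strides):
                    regular = bool(rng.random() < p_reg)
                    n_regular += regular
                    cs = _stride_curve_spec(spec, role.value, day, regular, mass, rng)
                    pieces.append(make_stance_curve(cs))
                    pieces.append(np.zeros(int(rng.integers(30, 80))))
                rec = RawRecording(
                    subject_id=subject_id,
                    side=side,
                    side_role=role,
                    body_mass_kg=mass,
                    days_after_surgery=int(day),
                    forces=np.concatenate(pieces),
                )
                recordings.append(rec)
                frac = day / spec.max_day
                truth_rows.append({
                    "subject_id": subject_id,
                    "side": side.value,
                    "side_role": role.value,
                    "days_after_surgery": int(day),
                    "body_mass_kg": mass,
                    "p_regular": p_reg,
                    "n_strides": n_strides,
                    "n_regular_drawn": n_regular,
                    "m_peak_base": (72.0 + 38.0 * frac) if role == SideRole.INJURED
                                   else (105.0 + 8.0 * frac),
                    "plateau_height": (45.0 + 40.0 * frac) if role == SideRole.INJURED
                                      else (85.0 + 10.0 * frac),
                })
    return recordings, pd.DataFrame(truth_rows)


def write_cohort(recordings: Sequence[RawRecording], truth: pd.DataFrame,
                 out_dir: str | Path) -> None:
    """Write a cohort in the per-foot CSV dialect plus ground_truth.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        name = f"{rec.subject_id}_d{rec.days_after_surgery:03d}_{rec.side.value}.csv"
        write_recording(rec, out_dir / name)
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
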