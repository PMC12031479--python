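"""Shared fixtures: analytic stance curves with closed-form landmarks."""

from __future__ import annotations

import numpy as np
import pytest

from insolegait.data import GRAVITY, RawRecording, Side, SideRole


def two_bump_cos(n: int = 100, base: float = 50.0, amp: float = 30.0) -> np.ndarray:
    """The analytic two-bump curve y_i = base - amp*cos(4*pi*i/(n-1)).

    Maxima near i = (n-1)/4 and 3(n-1)/4, a central minimum plateau, and
    inflection points near (n-1)/8 and 7(n-1)/8.
    """
    i = np.arange(n)
    return base - amp * np.cos(4.0 * np.pi * i / (n - 1))


def pbw_to_newtons(pbw: np.ndarray, body_mass_kg: float) -> np.ndarray:
    return np.asarray(pbw, dtype=float) / 100.0 * body_mass_kg * GRAVITY


def curve_recording(pbw: np.ndarray, *, body_mass_kg: float = 75.0, pad: int = 40,
                    days: int = 30, side_role: str = "healthy",
                    start_index: int = 0) -> RawRecording:
    """Embed a %BW stance curve in a zero-padded 100 Hz recording."""
    forces = np.concatenate([np.zeros(pad), pbw_to_newtons(pbw, body_mass_kg), np.zeros(pad)])
    return RawRecording(
        subject_id="T01", side=Side.LEFT, side_role=SideRole(side_role),
        body_mass_kg=body_mass_kg, days_after_surgery=days, forces=forces,
        start_index=start_index)


@pytest.fixture
def cos_curve() -> np.ndarray:
    return two_bump_cos()


@pytest.fixture
def cos_recording(cos_curve) -> RawRecording:
    return curve_recording(cos_curve)
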