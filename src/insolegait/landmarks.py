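"""Landmark detection and regular / non-regular stance classification.

The healthy vertical ground-reaction-force curve is M-shaped: a loading
maximum, a mid-stance minimum, and a push-off maximum.  After lower-limb
fracture this shape degrades to a plateau, so the classical two-maxima
landmarks become ambiguous.  Two complementary landmark families are used:

* the classical extrema (first/last maximum, in-between minimum), with a
  disambiguation cascade for noisy or ambiguous candidate sets;
* the *enclosing turning points* TP1/TP2 — the first and last inflection
  points of the curve (sign changes of the discrete second derivative) —
  which exist even for heavily altered, plateau-like stances.

A stance is labelled ``regular`` only when an unequivocal M-shape is found:
two unambiguous local maxima with a single local minimum in between.

All detection runs on the filtered 100-sample signal; force values are
read off the unfiltered signal elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .data import NormalizedStance

REGULAR = "regular"
NON_REGULAR = "non_regular"

#: "within 5% of the overall time span" on the 100-sample grid
CLUSTER_WINDOW = 5
#: dominance factor for strategy (ii)
DOMINANCE_FACTOR = 1.05
#: "5% of the overall duration in both directions" for the monotony check
MONOTONY_WINDOW = 5


@dataclass(frozen=True)
class LandmarkSet:
    """Detected landmark indices (0..99) and the regularity label.

    ``None`` marks an absent landmark.  ``i_max_first``/``i_max_last`` are
    set whenever at least two maxima survive disambiguation (also for
    non-regular stances, so the inter-max parameter family follows the
    more-than-one-maximum rule); ``i_min`` only for regular stances.
    Candidate sets are retained for audit dumps.
    """

    i_tp1: Optional[int]
    i_tp2: Optional[int]
    i_max_first: Optional[int]
    i_max_last: Optional[int]
    i_min: Optional[int]
    n_maxima_raw: int
    label: str
    maxima_raw: Tuple[int, ...] = ()
    minima_raw: Tuple[int, ...] = ()
    maxima_final: Tuple[int, ...] = ()
    minima_final: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.label not in (REGULAR, NON_REGULAR):
            raise ValueError(f"bad label {self.label!r}")
        if self.i_tp1 is not None and self.i_tp2 is not None and not self.i_tp1 < self.i_tp2:
            raise ValueError("i_tp1 must precede i_tp2")
        if self.label == REGULAR:
            if None in (self.i_max_first, self.i_min, self.i_max_last):
                raise ValueError("regular stance requires all three extremum landmarks")
            if not self.i_max_first < self.i_min < self.i_max_last:
                raise ValueError("regular stance requires max < min < max ordering")

    @property
    def is_regular(self) -> bool:
        return self.label == REGULAR

    @property
    def has_multiple_maxima(self) -> bool:
        """True when the inter-max parameter family can be computed."""
        return self.i_max_first is not None and self.i_max_last is not None \
            and self.i_max_first < self.i_max_last

    def to_dict(self) -> dict:
        return {
            "i_tp1": self.i_tp1,
            "i_tp2": self.i_tp2,
            "i_max_first": self.i_max_first,
            "i_max_last": self.i_max_last,
            "i_min": self.i_min,
            "n_maxima_raw": self.n_maxima_raw,
            "label": self.label,
            "maxima_raw": list(self.maxima_raw),
            "minima_raw": list(self.minima_raw),
            "maxima_final": list(self.maxima_final),
            "minima_final": list(self.minima_final),
        }


def find_local_extrema(y: np.ndarray) -> Tuple[List[int], List[int]]:
    """Strict interior local extrema by first-difference sign change.

    A plateau of equal neighbours yields its centre index once (floor of
    the midpoint for even plateaus).  Endpoints are never extrema.
    """
    y = np.asarray(y, dtype=float)
    d = np.diff(y)
    nz = np.flatnonzero(d != 0.0)
    maxima: List[int] = []
    minima: List[int] = []
    for k in range(len(nz) - 1):
        a, b = nz[k], nz[k + 1]
        if d[a] > 0 and d[b] < 0:
            maxima.append(int((a + 1 + b) // 2))
        elif d[a] < 0 and d[b] > 0:
            minima.append(int((a + 1 + b) // 2))
    return maxima, minima


def find_enclosing_turning_points(y: np.ndarray) -> Tuple[Optional[int], Optional[int]]:
    """First and last inflection points of the 100-sample curve.

    The central second difference d2_i = y_{i+1} - 2 y_i + y_{i-1} is
    computed for interior indices; a turning point lies between two
    interior points of opposite d2 sign and is reported at whichever of
    the two has the smaller curvature magnitude (nearest the zero
    crossing).  Returns ``(None, None)`` when fewer than two sign changes
    exist (e.g. an affine signal).
    """
    y = np.asarray(y, dtype=float)
    d2 = y[2:] - 2.0 * y[1:-1] + y[:-2]  # index k -> interior point k + 1
    # curvature below float noise of the signal scale counts as zero, so an
    # affine signal (d2 analytically 0) yields no spurious crossings
    tol = 1e-9 * max(1.0, float(np.max(np.abs(y))))
    s = np.sign(d2)
    s[np.abs(d2) <= tol] = 0
    nz = np.flatnonzero(s != 0)
    crossings: List[int] = []
    for k in range(len(nz) - 1):
        a, b = nz[k], nz[k + 1]
        if s[a] != s[b]:
            pick = a if abs(d2[a]) <= abs(d2[b]) else b
            crossings.append(int(pick) + 1)
    if len(crossings) < 2:
        return None, None
    return crossings[0], crossings[-1]


def _cluster_select(candidates: Sequence[int], y: np.ndarray, keep_highest: bool,
                    window: int = CLUSTER_WINDOW) -> List[int]:
    """Strategy (i): merge candidates within the 5%-of-span window.

    Candidates are chained into clusters (consecutive gaps <= window); the
    highest (maxima) or lowest (minima) member of each cluster survives.
    """
    if not candidates:
        return []
    clusters: List[List[int]] = [[candidates[0]]]
    for c in candidates[1:]:
        if c - clusters[-1][-1] <= window:
            clusters[-1].append(c)
        else:
            clusters.append([c])
    pick = max if keep_highest else min
    return [pick(cl, key=lambda i: y[i]) for cl in clusters]


def _dominance_select(candidates: Sequence[int], y: np.ndarray, keep_highest: bool,
                      factor: float = DOMINANCE_FACTOR) -> List[int]:
    """Strategy (ii): per half of the stance, a candidate dominating all
    others in that half by the 1.05 factor (inclusive) suppresses them."""
    out: List[int] = []
    for lo, hi in ((0, 50), (50, 100)):
        half = [c for c in candidates if lo <= c < hi]
        if len(half) <= 1:
            out.extend(half)
            continue
        vals = np.array([y[c] for c in half])
        if keep_highest:
            best = int(np.argmax(vals))
            others = np.delete(vals, best)
            dominant = np.all(others > 0) and np.all(vals[best] >= factor * others)
        else:
            best = int(np.argmin(vals))
            others = np.delete(vals, best)
            dominant = vals[best] > 0 and np.all(others >= factor * vals[best])
        out.extend([half[best]] if dominant else half)
    return sorted(out)


def _monotony_select(candidates: Sequence[int], y: np.ndarray, is_maximum: bool,
                     window: int = MONOTONY_WINDOW) -> List[int]:
    """Strategy (iii): keep candidates with weakly monotone flanks over the
    5-sample window on both sides (clamped at the array bounds)."""
    out: List[int] = []
    n = y.size
    for c in candidates:
        lo = max(0, c - window)
        hi = min(n - 1, c + window)
        left = np.diff(y[lo : c + 1])
        right = np.diff(y[c : hi + 1])
        if is_maximum:
            ok = np.all(left >= 0) and np.all(right <= 0)
        else:
            ok = np.all(left <= 0) and np.all(right >= 0)
        if ok:
            out.append(c)
    return out


def _m_criterion(maxima: Sequence[int], minima: Sequence[int],
                 y: np.ndarray) -> Optional[Tuple[int, int, int]]:
    """Test the M-shape criterion on a candidate set.

    Requires exactly two maxima and, strictly between them, exactly one
    minimum candidate which is also the lowest filtered value of the open
    interval.  For the maxima to count as *unambiguous*, each must exceed
    that minimum by the same 1.05 factor the disambiguation cascade uses
    as its ambiguity threshold — a flat plateau whose noise ripples differ
    from their valley by a couple of percent is not an M-shape.  Returns
    (i_max_first, i_min, i_max_last) or ``None``.
    """
    if len(maxima) != 2:
        return None
    m1, m2 = maxima
    if m2 - m1 < 2:
        return None
    between = [c for c in minima if m1 < c < m2]
    if len(between) != 1:
        return None
    interval = y[m1 + 1 : m2]
    lowest = m1 + 1 + int(np.argmin(interval))
    if between[0] != lowest:
        return None
    v = y[lowest]
    if v > 0 and (y[m1] < DOMINANCE_FACTOR * v or y[m2] < DOMINANCE_FACTOR * v):
        return None
    return m1, lowest, m2


@dataclass(frozen=True)
class DisambiguationResult:
    resolved: Optional[Tuple[int, int, int]]  # (i_max_first, i_min, i_max_last)
    maxima: Tuple[int, ...]
    minima: Tuple[int, ...]
    stage: str  # which stage resolved: none/raw/cluster/dominance/monotony


def disambiguate(maxima: Sequence[int], minima: Sequence[int],
                 y: np.ndarray) -> DisambiguationResult:
    """Apply the disambiguation cascade to the extremum candidates.

    The M-criterion is tested on the raw candidates first; on failure the
    strategies are applied in order — (i) 5%-window cluster merge,
    (ii) 1.05-factor dominance per stance half, (iii) 5-sample monotony
    elimination — re-testing the criterion after each stage and stopping
    early once it holds.  Both maxima and minima are subject to every
    strategy.  ``resolved`` is ``None`` when the cascade ends unresolved.
    """
    y = np.asarray(y, dtype=float)
    maxima = sorted(int(c) for c in maxima)
    minima = sorted(int(c) for c in minima)

    triple = _m_criterion(maxima, minima, y)
    if triple is not None:
        return DisambiguationResult(triple, tuple(maxima), tuple(minima), "raw")

    maxima = _cluster_select(maxima, y, keep_highest=True)
    minima = _cluster_select(minima, y, keep_highest=False)
    triple = _m_criterion(maxima, minima, y)
    if triple is not None:
        return DisambiguationResult(triple, tuple(maxima), tuple(minima), "cluster")

    maxima = _dominance_select(maxima, y, keep_highest=True)
    minima = _dominance_select(minima, y, keep_highest=False)
    triple = _m_criterion(maxima, minima, y)
    if triple is not None:
        return DisambiguationResult(triple, tuple(maxima), tuple(minima), "dominance")

    maxima = _monotony_select(maxima, y, is_maximum=True)
    minima = _monotony_select(minima, y, is_maximum=False)
    triple = _m_criterion(maxima, minima, y)
    stage = "monotony" if triple is not None else "none"
    return DisambiguationResult(triple, tuple(maxima), tuple(minima), stage)


def classify_stance(ns: NormalizedStance) -> LandmarkSet:
    """Detect all landmarks on the filtered signal and label the stance.

    Landmark indices only are stored; force read-off happens downstream on
    the unfiltered signal.  Classification is deterministic.
    """
    y = ns.y_filtered
    maxima_raw, minima_raw = find_local_extrema(y)
    res = disambiguate(maxima_raw, minima_raw, y)
    i_tp1, i_tp2 = find_enclosing_turning_points(y)

    if res.resolved is not None:
        i_max_first, i_min, i_max_last = res.resolved
        label = REGULAR
    else:
        i_min = None
        label = NON_REGULAR
        if len(res.maxima) >= 2:
            i_max_first, i_max_last = res.maxima[0], res.maxima[-1]
        else:
            i_max_first = i_max_last = None
    return LandmarkSet(
        i_tp1=i_tp1,
        i_tp2=i_tp2,
        i_max_first=i_max_first,
        i_max_last=i_max_last,
        i_min=i_min,
        n_maxima_raw=len(maxima_raw),
        label=label,
        maxima_raw=tuple(maxima_raw),
        minima_raw=tuple(minima_raw),
        maxima_final=res.maxima,
        minima_final=res.minima,
    )


def regular_ratio(labels: Sequence[str]) -> float:
    """Fraction of stances labelled regular within one measurement."""
    if len(labels) == 0:
        raise ValueError("regular_ratio of an empty label sequence is undefined")
    return sum(1 for lb in labels if lb == REGULAR) / len(labels)
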