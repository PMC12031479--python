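"""Per-visit aggregation and longitudinal trend regression.

Stride-level parameters are aggregated per measurement (visit) and leg
side by the arithmetic mean; parameters absent on a stride (single-maximum
omission rule, failed turning-point detection) simply do not enter the
mean.  To compare across subjects, each parameter is Min-Max normalized
within subject over all of that subject's measurements (both sides
pooled).  The normalized values are then regressed against days after
surgery under four candidate relations — linear, square, cubic,
logarithmic — each reduced to a single-regressor transform so that the
null hypothesis "slope = 0" can be tested with a Wald t-test (df = n - 2).
Non-significant relations (p >= 0.05) are discarded and the best remaining
relation per parameter-side pair is the one with the lowest residual sum
of squares (ties broken by higher R^2).

The regular-stride ratio gets its own protocol: ordinary least squares of
ln(ratio) on days after surgery, per side, with zero-ratio visits excluded
by default (an epsilon offset is available by configuration).

The whole protocol is wrapped statsmodels-style:
``RecoveryTrendModel(table).fit()`` returns a
:class:`RecoveryTrendResults` with a ``summary()`` table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .data import PARAMETER_NAMES, SideRole
from .landmarks import REGULAR, regular_ratio
from .parameters import StrideParameters

logger = logging.getLogger(__name__)

RELATIONS = ("linear", "square", "cubic", "logarithmic")
DEFAULT_ALPHA = 0.05
MAX_FIT_ATTEMPTS = 500


@dataclass
class VisitAggregate:
    """Per-visit, per-side arithmetic means of the stride parameters."""

    subject_id: str
    side_role: SideRole
    days_after_surgery: int
    param_means: Dict[str, Optional[float]]
    regular_ratio: float
    n_strides: int

    def __post_init__(self) -> None:
        self.side_role = SideRole(self.side_role)
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")
        if not 0.0 <= self.regular_ratio <= 1.0:
            raise ValueError("regular_ratio must lie in [0, 1]")

    def to_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "side_role": self.side_role.value,
            "days_after_surgery": self.days_after_surgery,
            "n_strides": self.n_strides,
            "regular_ratio": self.regular_ratio,
        }
        for name in PARAMETER_NAMES:
            row[name] = self.param_means.get(name)
        return row


@dataclass(frozen=True)
class RelationFit:
    """A fitted candidate relation y = b0 + b1 * g(x) with its Wald test."""

    parameter: str
    side_role: Optional[SideRole]
    relation: str
    beta0: float
    beta1: float
    r_squared: float
    t_stat: float
    df: int
    p_value: float
    fit_error: float  # residual sum of squares
    n: int

    def to_row(self) -> dict:
        return {
            "parameter": self.parameter,
            "side": self.side_role.value if self.side_role else None,
            "relation": self.relation,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "r_squared": self.r_squared,
            "t": self.t_stat,
            "df": self.df,
            "p": self.p_value,
            "rss": self.fit_error,
            "n": self.n,
        }


# ---------------------------------------------------------------------------
# aggregation & normalization
# ---------------------------------------------------------------------------

def aggregate_visit(
    params: Sequence[StrideParameters],
    labels: Sequence[str],
    *,
    subject_id: str,
    side_role: SideRole | str,
    days_after_surgery: int,
) -> VisitAggregate:
    """Arithmetic-mean aggregation of one measurement's strides.

    Each parameter is averaged over the strides where it is present; a
    parameter present on no stride is absent in the aggregate.
    """
    if len(params) == 0:
        raise ValueError("cannot aggregate zero strides")
    if len(params) != len(labels):
        raise ValueError("params and labels must align")
    means: Dict[str, Optional[float]] = {}
    for name in PARAMETER_NAMES:
        vals = [getattr(p, name) for p in params if getattr(p, name) is not None]
        means[name] = float(np.mean(vals)) if vals else None
    return VisitAggregate(
        subject_id=subject_id,
        side_role=SideRole(side_role),
        days_after_surgery=days_after_surgery,
        param_means=means,
        regular_ratio=regular_ratio(labels),
        n_strides=len(params),
    )


def aggregates_to_frame(aggregates: Iterable[VisitAggregate]) -> pd.DataFrame:
    rows = [a.to_row() for a in aggregates]
    if not rows:
        raise ValueError("no aggregates")
    return pd.DataFrame(rows)


def minmax_normalize(
    table: pd.DataFrame,
    parameters: Sequence[str] = PARAMETER_NAMES,
    *,
    scope: str = "pooled",
) -> pd.DataFrame:
    """Within-subject Min-Max normalization of the parameter columns.

    ``scope='pooled'`` (default) pools both sides of a subject when taking
    the min/max over all measurements; ``scope='per_side'`` scales each
    side separately (sensitivity option).  A subject whose values are
    constant for a parameter is excluded for that parameter (set to NaN)
    and logged.
    """
    if scope not in ("pooled", "per_side"):
        raise ValueError(f"unknown scope {scope!r}")
    keys = ["subject_id"] if scope == "pooled" else ["subject_id", "side_role"]
    out = table.copy()
    for name in parameters:
        if name not in out.columns:
            continue
        col = out[name].astype(float)
        for key, idx in out.groupby(keys, sort=False).groups.items():
            vals = col.loc[idx]
            vmin, vmax = vals.min(), vals.max()
            if not np.isfinite(vmin) or not np.isfinite(vmax):
                out.loc[idx, name] = np.nan
                continue
            if vmax == vmin:
                logger.info("minmax_normalize: %s constant for subject %s; excluded", name, key)
                out.loc[idx, name] = np.nan
                continue
            out.loc[idx, name] = (vals - vmin) / (vmax - vmin)
    return out


# ---------------------------------------------------------------------------
# relation fitting
# ---------------------------------------------------------------------------

def relation_transform(relation: str, x: np.ndarray) -> np.ndarray:
    """Single-regressor transform g(x) for each candidate relation."""
    x = np.asarray(x, dtype=float)
    if relation == "linear":
        return x
    if relation == "square":
        return x**2
    if relation == "cubic":
        return x**3
    if relation == "logarithmic":
        if np.any(x < 1):
            raise ValueError("logarithmic relation requires all x >= 1")
        return np.log(x)
    raise ValueError(f"unknown relation {relation!r}")


def fit_relation(
    x: np.ndarray,
    y: np.ndarray,
    relation: str,
    *,
    parameter: str = "",
    side_role: Optional[SideRole] = None,
    max_attempts: int = MAX_FIT_ATTEMPTS,
) -> Optional[RelationFit]:
    """Least-squares fit of ``y = b0 + b1 * g(x)`` for one relation.

    The optimizer is iterative and capped at ``max_attempts`` parameter
    alterations; a fit that has not converged within the cap is discarded
    (returns ``None``).  A converged fit carries RSS, R^2 and the Wald
    slope test (t, df = n - 2, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("fit_relation needs >= 3 aligned points")
    g = relation_transform(relation, x)

    def residual(beta: np.ndarray) -> np.ndarray:
        return beta[0] + beta[1] * g - y

    sol = least_squares(residual, x0=np.zeros(2), max_nfev=max_attempts, method="lm")
    if not sol.success or sol.nfev >= max_attempts:
        logger.info("fit_relation: %s/%s discarded after %d attempts", parameter, relation, sol.nfev)
        return None
    beta0, beta1 = float(sol.x[0]), float(sol.x[1])
    resid = residual(sol.x)
    rss = float(np.dot(resid, resid))
    sst = float(np.dot(y - y.mean(), y - y.mean()))
    r2 = 1.0 - rss / sst if sst > 0 else (1.0 if rss == 0 else 0.0)
    t, df, p = wald_slope_test_xy(g, y)
    return RelationFit(
        parameter=parameter,
        side_role=side_role,
        relation=relation,
        beta0=beta0,
        beta1=beta1,
        r_squared=r2,
        t_stat=t,
        df=df,
        p_value=p,
        fit_error=rss,
        n=int(x.size),
    )


def wald_slope_test_xy(g: np.ndarray, y: np.ndarray) -> Tuple[float, int, float]:
    """Wald t-test of zero slope for the OLS of ``y`` on a regressor ``g``.

    t = b1 / SE(b1) with SE from the residual variance on df = n - 2;
    two-sided p from the t distribution.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    n = g.size
    if n < 3:
        raise ValueError("wald test needs >= 3 points")
    gc = g - g.mean()
    sgg = float(np.dot(gc, gc))
    if sgg == 0:
        raise ValueError("zero variance in the transformed regressor")
    b1 = float(np.dot(gc, y) / sgg)
    b0 = float(y.mean() - b1 * g.mean())
    resid = y - (b0 + b1 * g)
    df = n - 2
    s2 = float(np.dot(resid, resid)) / df
    se = math.sqrt(s2 / sgg)
    if se == 0:
        t = math.inf if b1 != 0 else 0.0
        p = 0.0 if b1 != 0 else 1.0
    else:
        t = b1 / se
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, df, p


def wald_slope_test(fit: RelationFit, x: np.ndarray, y: np.ndarray) -> Tuple[float, int, float]:
    """Wald slope test for an already-fitted relation on its data."""
    g = relation_transform(fit.relation, np.asarray(x, dtype=float))
    return wald_slope_test_xy(g, np.asarray(y, dtype=float))


def select_best(fits: Sequence[RelationFit]) -> Optional[RelationFit]:
    """Best relation = lowest fitting error; ties -> higher R^2.

    ``fits`` should already contain only significant relations; an empty
    input yields ``None`` (the parameter-side pair goes unreported).
    """
    if not fits:
        return None
    return min(fits, key=lambda f: (f.fit_error, -f.r_squared))


def regular_ratio_regression(
    days: np.ndarray,
    ratios: np.ndarray,
    *,
    side_role: Optional[SideRole] = None,
    zero_policy: str = "exclude",
    epsilon: float = 1e-3,
) -> RelationFit:
    """OLS of ln(regular ratio) on days after surgery for one side.

    ``zero_policy='exclude'`` drops zero-ratio visits (ln 0 undefined);
    ``'epsilon'`` adds a small offset instead.  Requires >= 3 usable
    points.
    """
    days = np.asarray(days, dtype=float)
    ratios = np.asarray(ratios, dtype=float)
    if zero_policy == "exclude":
        mask = ratios > 0
        days, ratios = days[mask], ratios[mask]
    elif zero_policy == "epsilon":
        ratios = ratios + epsilon
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    if days.size < 3:
        raise ValueError("regular_ratio_regression needs >= 3 usable points")
    fit = fit_relation(days, np.log(ratios), "linear",
                       parameter="log_regular_ratio", side_role=side_role)
    assert fit is not None  # linear OLS on finite data always converges
    return fit


# ---------------------------------------------------------------------------
# statsmodels-style wrapper
# ---------------------------------------------------------------------------

class RecoveryTrendModel:
    """Longitudinal trend model over a per-visit parameter table.

    Parameters
    ----------
    table:
        One row per (subject, visit, side) with columns ``subject_id``,
        ``side_role``, ``days_after_surgery``, ``regular_ratio``,
        ``n_strides`` and the twelve parameter columns (absent values as
        NaN) — the frame written by :func:`insolegait.data.write_parameter_table`.
    relations:
        Candidate relations to try (default: all four).
    alpha:
        Two-sided significance level for the Wald slope test.
    normalize:
        Apply within-subject Min-Max normalization before fitting.
    minmax_scope:
        ``'pooled'`` or ``'per_side'``.
    zero_ratio_policy:
        ``'exclude'`` or ``'epsilon'`` for the log-ratio regression.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        *,
        relations: Sequence[str] = RELATIONS,
        alpha: float = DEFAULT_ALPHA,
        normalize: bool = True,
        minmax_scope: str = "pooled",
        zero_ratio_policy: str = "exclude",
    ) -> None:
        required = {"subject_id", "side_role", "days_after_surgery", "regular_ratio"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"table lacks required columns: {sorted(missing)}")
        self.table = table.reset_index(drop=True)
        self.relations = tuple(relations)
        self.alpha = alpha
        self.normalize = normalize
        self.minmax_scope = minmax_scope
        self.zero_ratio_policy = zero_ratio_policy

    @classmethod
    def from_aggregates(cls, aggregates: Iterable[VisitAggregate], **kwargs) -> "RecoveryTrendModel":
        return cls(aggregates_to_frame(aggregates), **kwargs)

    def fit(self) -> "RecoveryTrendResults":
        table = self.table
        norm = minmax_normalize(table, scope=self.minmax_scope) if self.normalize else table
        all_fits: List[RelationFit] = []
        best: Dict[Tuple[str, str], Optional[RelationFit]] = {}
        for role in (SideRole.HEALTHY, SideRole.INJURED):
            side = norm[norm["side_role"] == role.value]
            for name in PARAMETER_NAMES:
                if name not in side.columns:
                    continue
                sub = side[["days_after_surgery", name]].dropna()
                if len(sub) < 3:
                    best[(name, role.value)] = None
                    continue
                x = sub["days_after_surgery"].to_numpy(float)
                y = sub[name].to_numpy(float)
                candidates: List[RelationFit] = []
                for rel in self.relations:
                    if rel == "logarithmic" and np.any(x < 1):
                        continue
                    f = fit_relation(x, y, rel, parameter=name, side_role=role)
                    if f is not None:
                        candidates.append(f)
                all_fits.extend(candidates)
                significant = [f for f in candidates if f.p_value < self.alpha]
                best[(name, role.value)] = select_best(significant)

        ratio_fits: Dict[str, Optional[RelationFit]] = {}
        for role in (SideRole.HEALTHY, SideRole.INJURED):
            side = table[table["side_role"] == role.value]
            try:
                ratio_fits[role.value] = regular_ratio_regression(
                    side["days_after_surgery"].to_numpy(float),
                    side["regular_ratio"].to_numpy(float),
                    side_role=role,
                    zero_policy=self.zero_ratio_policy,
                )
            except ValueError:
                ratio_fits[role.value] = None
        return RecoveryTrendResults(self, best, all_fits, ratio_fits)


class RecoveryTrendResults:
    """Fitted recovery trends: best relation per parameter-side pair plus
    the log regular-ratio regressions per side."""

    def __init__(
        self,
        model: RecoveryTrendModel,
        best_fits: Mapping[Tuple[str, str], Optional[RelationFit]],
        all_fits: Sequence[RelationFit],
        ratio_fits: Mapping[str, Optional[RelationFit]],
    ) -> None:
        self.model = model
        self.best_fits = dict(best_fits)
        self.all_fits = list(all_fits)
        self.ratio_fits = dict(ratio_fits)

    def to_frame(self) -> pd.DataFrame:
        """Significant best fits, one row per parameter-side pair."""
        rows = [f.to_row() for f in self.best_fits.values() if f is not None]
        cols = ["parameter", "side", "relation", "beta0", "beta1",
                "r_squared", "t", "df", "p", "rss", "n"]
        return pd.DataFrame(rows, columns=cols)

    def summary(self) -> str:
        lines = ["Recovery trend analysis", "=" * 70]
        lines.append(f"{'Parameter':<28}{'Side':<9}{'Relation':<13}{'R2':>6}{'p':>9}  t (df)")
        lines.append("-" * 70)
        any_row = False
        for (name, side), f in self.best_fits.items():
            if f is None:
                continue
            any_row = True
            p_str = "<0.001" if f.p_value < 0.001 else f"{f.p_value:.3f}"
            lines.append(
                f"{name:<28}{side:<9}{f.relation:<13}{f.r_squared:>6.3f}{p_str:>9}"
                f"  {f.t_stat:.2f} ({f.df})"
            )
        if not any_row:
            lines.append("(no significant parameter-side pair)")
        lines.append("-" * 70)
        for side, f in self.ratio_fits.items():
            if f is None:
                lines.append(f"log(regular_ratio_{side}): not estimable")
            else:
                lines.append(
                    f"log(regular_ratio_{side}) = {f.beta0:.2f} + {f.beta1:.4f} * days"
                    f"  (R2 = {f.r_squared:.3f}, p = {f.p_value:.3g}, t{f.df} = {f.t_stat:.2f})"
                )
        return "\n".join(lines)
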