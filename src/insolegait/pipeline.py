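"""End-to-end pipeline: segment -> preprocess -> classify -> params -> regress.

Two surfaces are provided:

* :func:`analyze_recordings` — in-memory analysis of a set of recordings,
  returning the per-visit parameter table and the fitted trend results;
* :func:`run_pipeline` — file-based staged execution where every stage
  communicates with the next only through its declared artifact file
  (events.json, stances.json, landmarks.json, params.csv, fits.json), for
  auditability and CLI use.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import segmentation
from .cohort import (DEFAULT_ALPHA, RELATIONS, RecoveryTrendModel,
                     RecoveryTrendResults, aggregate_visit, aggregates_to_frame)
from .data import (RawRecording, RecordingError, Side, SideRole,
                   read_recording_with_sidecar, write_parameter_table)
from .landmarks import classify_stance
from .parameters import compute_parameters
from .preprocessing import preprocess_stance

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable constants of the pipeline; defaults are the published
    protocol values."""

    threshold_n: float = 30.0
    gap_samples: int = 3
    min_ms: float = 300.0
    max_ms: float = 3500.0
    sigma: float = 4.0
    n_out: int = 100
    alpha: float = DEFAULT_ALPHA
    relations: Tuple[str, ...] = RELATIONS
    minmax_scope: str = "pooled"
    zero_ratio_policy: str = "exclude"
    strict_table1_denominator: bool = False
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "relations" in raw:
            raw["relations"] = tuple(raw["relations"])
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["relations"] = list(d["relations"])
        Path(path).write_text(json.dumps(d, indent=1), encoding="utf-8")


# ---------------------------------------------------------------------------
# in-memory analysis
# ---------------------------------------------------------------------------

def analyze_recording(rec: RawRecording, config: PipelineConfig | None = None):
    """Segment, preprocess, classify and parameterize one recording.

    Returns (stances, landmark_sets, stride_parameters); stances too short
    for spline resampling are dropped and logged.
    """
    config = config or PipelineConfig()
    events = segmentation.detect_stance_events(
        rec, threshold_n=config.threshold_n, gap_samples=config.gap_samples,
        min_ms=config.min_ms, max_ms=config.max_ms)
    stances, lms, params = [], [], []
    for ev in events:
        try:
            ns = preprocess_stance(ev)
        except ValueError as exc:
            logger.info("stance at %d dropped: %s", ev.start_index, exc)
            continue
        lm = classify_stance(ns)
        sp = compute_parameters(
            ns, lm, strict_table1_denominator=config.strict_table1_denominator)
        stances.append(ns)
        lms.append(lm)
        params.append(sp)
    return stances, lms, params


def build_parameter_table(recordings: Iterable[RawRecording],
                          config: PipelineConfig | None = None) -> pd.DataFrame:
    """Per-visit parameter table over a set of recordings.

    Each recording is one measurement of one foot; recordings yielding no
    usable stance are skipped with a log entry.
    """
    config = config or PipelineConfig()
    aggregates = []
    for rec in recordings:
        _, lms, params = analyze_recording(rec, config)
        if not params:
            logger.info("recording %s/%s d%d: no usable stance",
                        rec.subject_id, rec.side.value, rec.days_after_surgery)
            continue
        aggregates.append(aggregate_visit(
            params, [lm.label for lm in lms],
            subject_id=rec.subject_id, side_role=rec.side_role,
            days_after_surgery=rec.days_after_surgery))
    if not aggregates:
        raise ValueError("no recording produced a usable stance")
    return aggregates_to_frame(aggregates)


def analyze_recordings(recordings: Iterable[RawRecording],
                       config: PipelineConfig | None = None
                       ) -> Tuple[pd.DataFrame, RecoveryTrendResults]:
    """Full in-memory analysis: parameter table plus fitted recovery trends."""
    config = config or PipelineConfig()
    table = build_parameter_table(recordings, config)
    model = RecoveryTrendModel(
        table, relations=config.relations, alpha=config.alpha,
        minmax_scope=config.minmax_scope, zero_ratio_policy=config.zero_ratio_policy)
    return table, model.fit()


# ---------------------------------------------------------------------------
# file-based stages
# ---------------------------------------------------------------------------

def _load_input_dir(input_dir: str | Path) -> List[RawRecording]:
    input_dir = Path(input_dir)
    recs = []
    for path in sorted(input_dir.glob("*.csv")):
        if path.name == "ground_truth.csv":
            continue
        recs.append(read_recording_with_sidecar(path))
    if not recs:
        raise RecordingError(f"no recordings found in {input_dir}")
    return recs


def _event_meta(rec: RawRecording) -> dict:
    return {
        "subject_id": rec.subject_id,
        "side": rec.side.value,
        "side_role": rec.side_role.value,
        "body_mass_kg": rec.body_mass_kg,
        "days_after_surgery": rec.days_after_surgery,
    }


def stage_segment(input_dir: str | Path, events_path: str | Path,
                  config: PipelineConfig) -> int:
    """Detect stance events in every recording of ``input_dir``."""
    out = []
    for rec in _load_input_dir(input_dir):
        events = segmentation.detect_stance_events(
            rec, threshold_n=config.threshold_n, gap_samples=config.gap_samples,
            min_ms=config.min_ms, max_ms=config.max_ms)
        for ev in events:
            out.append({**_event_meta(rec),
                        "start_index": ev.start_index,
                        "end_index": ev.end_index,
                        "samples": [round(float(v), 6) for v in ev.samples]})
    Path(events_path).write_text(json.dumps(out), encoding="utf-8")
    return len(out)


def stage_preprocess(events_path: str | Path, stances_path: str | Path,
                     config: PipelineConfig) -> int:
    """Normalize every stance event to its 100-sample representation."""
    events = json.loads(Path(events_path).read_text(encoding="utf-8"))
    out = []
    for ev in events:
        rec = RawRecording(
            subject_id=ev["subject_id"], side=ev["side"], side_role=ev["side_role"],
            body_mass_kg=ev["body_mass_kg"], days_after_surgery=ev["days_after_surgery"],
            forces=np.asarray(ev["samples"], dtype=float),
            start_index=ev["start_index"])
        from .data import StanceEvent
        event = StanceEvent(source=rec, start_index=ev["start_index"],
                            end_index=ev["end_index"],
                            samples=np.asarray(ev["samples"], dtype=float))
        try:
            ns = preprocess_stance(event)
        except ValueError as exc:
            logger.info("stance at %d dropped: %s", event.start_index, exc)
            continue
        out.append({
            "subject_id": ns.subject_id, "side": ns.side.value,
            "side_role": ns.side_role.value,
            "days_after_surgery": ns.days_after_surgery,
            "duration_s": ns.duration_s, "stance_start_s": ns.stance_start_s,
            "y_unfiltered": [round(float(v), 6) for v in ns.y_unfiltered],
            "y_filtered": [round(float(v), 6) for v in ns.y_filtered]})
    Path(stances_path).write_text(json.dumps(out), encoding="utf-8")
    return len(out)


def _load_stances(stances_path: str | Path):
    from .data import NormalizedStance
    raw = json.loads(Path(stances_path).read_text(encoding="utf-8"))
    return [NormalizedStance(
        y_unfiltered=np.asarray(s["y_unfiltered"]), y_filtered=np.asarray(s["y_filtered"]),
        duration_s=s["duration_s"], stance_start_s=s["stance_start_s"],
        subject_id=s["subject_id"], side=Side(s["side"]),
        side_role=SideRole(s["side_role"]),
        days_after_surgery=s["days_after_surgery"]) for s in raw]


def stage_classify(stances_path: str | Path, landmarks_path: str | Path,
                   config: PipelineConfig) -> int:
    """Landmark detection + regular/non-regular annotation per stance."""
    stances = _load_stances(stances_path)
    out = [classify_stance(ns).to_dict() for ns in stances]
    Path(landmarks_path).write_text(json.dumps(out), encoding="utf-8")
    return len(out)


def stage_params(stances_path: str | Path, landmarks_path: str | Path,
                 params_path: str | Path, config: PipelineConfig) -> pd.DataFrame:
    """Compute stride parameters and aggregate them per visit and side."""
    from .landmarks import LandmarkSet
    stances = _load_stances(stances_path)
    lm_dicts = json.loads(Path(landmarks_path).read_text(encoding="utf-8"))
    if len(stances) != len(lm_dicts):
        raise ValueError("stances and landmarks artifacts do not align")
    groups: Dict[tuple, list] = {}
    for ns, d in zip(stances, lm_dicts):
        lm = LandmarkSet(
            i_tp1=d["i_tp1"], i_tp2=d["i_tp2"], i_max_first=d["i_max_first"],
            i_max_last=d["i_max_last"], i_min=d["i_min"],
            n_maxima_raw=d["n_maxima_raw"], label=d["label"])
        sp = compute_parameters(
            ns, lm, strict_table1_denominator=config.strict_table1_denominator)
        key = (ns.subject_id, ns.days_after_surgery, ns.side_role, ns.side)
        groups.setdefault(key, []).append((sp, lm.label))
    aggregates = []
    for (subject_id, days, role, _side), items in sorted(
            groups.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].value)):
        aggregates.append(aggregate_visit(
            [sp for sp, _ in items], [lb for _, lb in items],
            subject_id=subject_id, side_role=role, days_after_surgery=days))
    table = aggregates_to_frame(aggregates)
    write_parameter_table(table, params_path)
    return table


def stage_regress(params_path: str | Path, fits_path: str | Path,
                  config: PipelineConfig,
                  plots_dir: Optional[str | Path] = None) -> RecoveryTrendResults:
    """Fit the longitudinal trend model from the parameter table artifact."""
    from .data import read_parameter_table
    table = read_parameter_table(params_path)
    model = RecoveryTrendModel(
        table, relations=config.relations, alpha=config.alpha,
        minmax_scope=config.minmax_scope, zero_ratio_policy=config.zero_ratio_policy)
    results = model.fit()
    payload = {
        "best_fits": [f.to_row() for f in results.best_fits.values() if f is not None],
        "ratio_fits": {side: (f.to_row() if f is not None else None)
                       for side, f in results.ratio_fits.items()},
    }
    Path(fits_path).write_text(json.dumps(payload, indent=1), encoding="utf-8")
    if plots_dir is not None:
        plot_results(table, results, plots_dir)
    return results


def plot_results(table: pd.DataFrame, results: RecoveryTrendResults,
                 plots_dir: str | Path) -> List[Path]:
    """Scatter + fitted-relation plot per significant parameter-side pair."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .cohort import minmax_normalize, relation_transform
    plots_dir = Path(plots_dir)
    plots_dir.mkdir(parents=True, exist_ok=True)
    norm = minmax_normalize(table, scope=results.model.minmax_scope) \
        if results.model.normalize else table
    written = []
    for (name, side), fit in results.best_fits.items():
        if fit is None:
            continue
        sub = norm[norm["side_role"] == side][["days_after_surgery", name]].dropna()
        x = sub["days_after_surgery"].to_numpy(float)
        y = sub[name].to_numpy(float)
        xs = np.linspace(max(x.min(), 1.0), x.max(), 200)
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(x, y, s=12, alpha=0.7)
        ax.plot(xs, fit.beta0 + fit.beta1 * relation_transform(fit.relation, xs),
                color="C1",
                label=f"{fit.relation} (R$^2$={fit.r_squared:.2f})")
        ax.set_xlabel("days after surgery")
        ax.set_ylabel(f"{name} (min-max)")
        ax.set_title(f"{name} — {side}", fontsize=9)
        ax.legend(fontsize=7)
        fig.tight_layout()
        out = plots_dir / f"{name}_{side}.png"
        fig.savefig(out, dpi=110)
        plt.close(fig)
        written.append(out)
    return written


def run_pipeline(input_dir: str | Path, out_dir: str | Path,
                 config: PipelineConfig | None = None,
                 *, plots: bool = False) -> RecoveryTrendResults:
    """Run every stage file-to-file and return the fitted trend results.

    Deterministic given the inputs and config.  Artifacts written:
    config.json, events.json, stances.json, landmarks.json, params.csv,
    fits.json, summary.txt (and plots/ when requested).
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_json(out_dir / "config.json")
    n_events = stage_segment(input_dir, out_dir / "events.json", config)
    logger.info("segment: %d stance events", n_events)
    if n_events == 0:
        # graceful empty report rather than an error: nothing crossed the
        # contact threshold, which is a valid (if uninformative) outcome
        (out_dir / "summary.txt").write_text(
            "No stance events detected; nothing to analyze.\n", encoding="utf-8")
        return None
    stage_preprocess(out_dir / "events.json", out_dir / "stances.json", config)
    stage_classify(out_dir / "stances.json", out_dir / "landmarks.json", config)
    stage_params(out_dir / "stances.json", out_dir / "landmarks.json",
                 out_dir / "params.csv", config)
    results = stage_regress(out_dir / "params.csv", out_dir / "fits.json", config,
                            plots_dir=(out_dir / "plots") if plots else None)
    (out_dir / "summary.txt").write_text(results.summary() + "\n", encoding="utf-8")
    return results
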