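"""Synchronization measures, peak-centred period indices and seizure records.

Four connectivity measures are tracked per analysis window, each the mean
of pairwise h2 values over a fixed pair set:

* global  — all available region pairs;
* th      — pairs containing the thalamus (thalamo-cortical);
* mt      — pairs of a mesial structure with any non-mesial region
            (neocortex or thalamus); mesial-mesial pairs are excluded;
* thmt    — thalamus with a mesial structure.

A period's synchronization index is the measure averaged across a 3 s span
centred on that measure's own peak within the period (ties to the earliest
window, truncation at period edges). Periods of interest are 15 s long:
seizure onset (SO) runs from 5 s before to 10 s after the appearance of
the tonic discharge, end of seizure (ES) covers the last 15 s of the
discharge, and seizure duration runs from the beginning of SO to the end
of ES.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, AnalysisConfig
from .graphnet import (
    WindowGraph,
    degree_series,
    period_degree_summary,
    window_graph_series,
)
from .io import SO_PRE_S, RegionRecording, SeizureAnnotation
from .regions import MESIAL_ROLES, RegionRole

__all__ = [
    "MEASURES",
    "MeasureTimecourse",
    "SeizureIndexRecord",
    "measure_timecourses",
    "period_index",
    "seizure_duration",
    "so_interval",
    "es_interval",
    "build_index_table",
    "records_to_frame",
    "PipelineFailure",
]

MEASURES = ("global", "th", "mt", "thmt")

#: Seconds of the SO period preceding the tonic discharge.
SO_POST_S = 10.0


def _in_pair_set(measure: str, a: RegionRole, b: RegionRole) -> bool:
    if measure == "global":
        return True
    if measure == "th":
        return RegionRole.Th in (a, b)
    if measure == "mt":
        return (a in MESIAL_ROLES) != (b in MESIAL_ROLES)
    if measure == "thmt":
        return bool({a, b} & MESIAL_ROLES) and RegionRole.Th in (a, b)
    raise KeyError(f"unknown measure {measure!r}")


@dataclass
class MeasureTimecourse:
    """The four connectivity measures as functions of window time.

    A measure whose pair set is empty for the available roles is undefined:
    its values are NaN and its name is listed in ``undefined``.
    """

    t_centers: np.ndarray
    values: dict[str, np.ndarray]
    undefined: tuple[str, ...] = ()

    def __getitem__(self, measure: str) -> np.ndarray:
        return self.values[measure]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"t_center": self.t_centers})
        for m in MEASURES:
            frame[f"{m}_h2"] = self.values[m]
        return frame


@dataclass
class SeizureIndexRecord:
    """One seizure's durations, pattern, indices and ES degree measures."""

    seizure_id: str
    patient_id: str
    pattern: str
    duration_s: float
    so_indices: dict[str, float]
    es_indices: dict[str, float]
    degrees: dict[str, float]
    notes: list[str] = field(default_factory=list)

    def to_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {
            "patient": self.patient_id,
            "seizure": self.seizure_id,
            "pattern": self.pattern,
            "duration_s": self.duration_s,
        }
        for m in MEASURES:
            row[f"es_{m}"] = self.es_indices.get(m, float("nan"))
        for m in MEASURES:
            row[f"so_{m}"] = self.so_indices.get(m, float("nan"))
        for d in ("th_out", "th_in", "mt_out", "mt_in"):
            row[d] = self.degrees.get(d, float("nan"))
        return row


def measure_timecourses(graphs: list[WindowGraph]) -> MeasureTimecourse:
    """Average edge h2 over each measure's pair set, per window."""
    if not graphs:
        raise ValueError("measure time courses need at least one window graph")
    t = np.array([g.t_center for g in graphs])
    values = {m: np.full(len(graphs), np.nan) for m in MEASURES}
    undefined: list[str] = []
    for m in MEASURES:
        any_pairs = False
        for w, g in enumerate(graphs):
            vals = [e.h2 for e in g.edges if _in_pair_set(m, *e.pair)]
            if vals:
                any_pairs = True
                values[m][w] = float(np.mean(vals))
        if not any_pairs:
            undefined.append(m)
    return MeasureTimecourse(t_centers=t, values=values, undefined=tuple(undefined))


def period_index(
    tc: MeasureTimecourse, measure: str, cfg: AnalysisConfig = DEFAULT_CONFIG
) -> float:
    """Average a measure across the 3 s span centred on its peak.

    The peak is the earliest window maximizing the measure within the
    period; the average runs over windows whose centres fall within
    +/- peak_avg_s/2 of it, truncated at the period edges (an interior peak
    at the default 1 s step averages three window values). NaN when the
    measure is undefined for the available roles.
    """
    if measure in tc.undefined:
        return float("nan")
    v = tc[measure]
    t = tc.t_centers
    peak = int(np.nanargmax(v))  # argmax takes the first maximum: earliest tie
    half = cfg.peak_avg_s / 2.0
    sel = np.abs(t - t[peak]) <= half + 1e-9
    return float(np.nanmean(v[sel]))


def so_interval(ann: SeizureAnnotation) -> tuple[float, float]:
    """Seizure-onset period: 5 s before to 10 s after the tonic discharge."""
    return (ann.t_onset - SO_PRE_S, ann.t_onset + SO_POST_S)


def es_interval(ann: SeizureAnnotation) -> tuple[float, float]:
    """End-of-seizure period: the last 15 s of the discharge."""
    return (ann.t_end - DEFAULT_CONFIG.period_len_s, ann.t_end)


def seizure_duration(ann: SeizureAnnotation) -> tuple[float, bool]:
    """Seizure duration (s) from the beginning of SO to the end of ES.

    Returns ``(duration, overlap)``; ``overlap`` is True when the SO and ES
    periods overlap (duration < 30 s) — both periods are still analysed.
    """
    duration = ann.t_end - (ann.t_onset - SO_PRE_S)
    return duration, duration < 2 * DEFAULT_CONFIG.period_len_s


class PipelineFailure(RuntimeError):
    """A per-seizure analysis failure, carrying the seizure id."""


def analyze_seizure(
    rec: RegionRecording,
    ann: SeizureAnnotation,
    cfg: AnalysisConfig = DEFAULT_CONFIG,
) -> SeizureIndexRecord:
    """Run the full per-seizure pipeline: periods, graphs, indices, degrees."""
    duration, overlap = seizure_duration(ann)
    notes = []
    if overlap:
        notes.append("SO and ES periods overlap (duration < 30 s)")
    so_graphs = window_graph_series(rec, so_interval(ann), cfg)
    es_graphs = window_graph_series(rec, es_interval(ann), cfg)
    so_tc = measure_timecourses(so_graphs)
    es_tc = measure_timecourses(es_graphs)
    summary = period_degree_summary(
        degree_series(es_graphs, threshold=cfg.h2_threshold)
    )
    notes.extend(summary.notes)
    return SeizureIndexRecord(
        seizure_id=ann.seizure_id,
        patient_id=ann.patient_id,
        pattern=ann.pattern,
        duration_s=duration,
        so_indices={m: period_index(so_tc, m, cfg) for m in MEASURES},
        es_indices={m: period_index(es_tc, m, cfg) for m in MEASURES},
        degrees={
            "th_out": summary.th_out,
            "th_in": summary.th_in,
            "mt_out": summary.mt_out,
            "mt_in": summary.mt_in,
        },
        notes=notes,
    )


def build_index_table(
    seizures: list[tuple[RegionRecording, SeizureAnnotation]],
    cfg: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[list[SeizureIndexRecord], list[tuple[str, str]]]:
    """Analyse a cohort of seizures into per-seizure index records.

    Per-seizure failures are isolated: surviving seizures are still
    emitted, and failures are returned as (seizure_id, reason) pairs.
    """
    records, failures = [], []
    for rec, ann in seizures:
        try:
            records.append(analyze_seizure(rec, ann, cfg))
        except Exception as exc:  # noqa: BLE001 - isolate per-seizure faults
            failures.append((ann.seizure_id, f"{type(exc).__name__}: {exc}"))
    return records, failures


def records_to_frame(records: list[SeizureIndexRecord]) -> pd.DataFrame:
    """Index records as a table in the per-seizure column layout."""
    return pd.DataFrame([r.to_row() for r in records])
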