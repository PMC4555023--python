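"""Sliding-window connectivity graphs and in/out degree measures.

Each 2 s analysis window (sliding in 1 s steps, fully contained in the
period of interest) yields one directed graph over the available regions:
every pair carries the larger of its two directed h2 maxima, the winning
delay, and a direction. Degrees count, per window and per region, the
directed edges whose h2 exceeds the 0.4 threshold — undirected edges carry
connectivity weight for the synchronization measures but no direction, so
they are excluded from degrees entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import floor

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, AnalysisConfig
from .h2core import DirectedEdgeEstimate, Direction, directed_pair_estimate
from .io import RegionRecording
from .regions import MESIAL_ROLES, RegionRole, role_pairs

__all__ = [
    "WindowGraph",
    "DegreeSeries",
    "PeriodDegreeSummary",
    "window_graph_series",
    "degree_series",
    "period_degree_summary",
    "window_count",
    "edges_frame",
]


@dataclass
class WindowGraph:
    """Directed connectivity graph for one analysis window."""

    t_center: float
    edges: list[DirectedEdgeEstimate]
    available_roles: list[RegionRole]

    def edge(self, a: RegionRole, b: RegionRole) -> DirectedEdgeEstimate:
        for e in self.edges:
            if e.pair in ((a, b), (b, a)):
                return e
        raise KeyError(f"no edge between {a} and {b}")


@dataclass
class DegreeSeries:
    """Per-window, per-role counts of supra-threshold directed edges.

    ``out`` and ``inn`` are (n_windows, n_roles) integer arrays aligned
    with ``roles`` and ``t_centers``.
    """

    roles: list[RegionRole]
    t_centers: np.ndarray
    out: np.ndarray
    inn: np.ndarray

    def role_out(self, role: RegionRole) -> np.ndarray:
        return self.out[:, self.roles.index(role)]

    def role_in(self, role: RegionRole) -> np.ndarray:
        return self.inn[:, self.roles.index(role)]

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"t_center": self.t_centers}
        for i, r in enumerate(self.roles):
            cols[f"{r}_out"] = self.out[:, i]
            cols[f"{r}_in"] = self.inn[:, i]
        return pd.DataFrame(cols)


@dataclass
class PeriodDegreeSummary:
    """Mean degrees over a period's windows.

    ``th_*`` average the thalamus row; ``mt_*`` additionally average over
    the available mesial roles (amygdala, hippocampus, entorhinal cortex).
    ``th_defined`` is False when the thalamus was not recorded.
    """

    th_out: float
    th_in: float
    mt_out: float
    mt_in: float
    th_defined: bool = True
    mt_defined: bool = True
    notes: list[str] = field(default_factory=list)


def window_count(length_s: float, cfg: AnalysisConfig = DEFAULT_CONFIG) -> int:
    """Number of whole windows inside a period: floor((L - w)/step) + 1."""
    if length_s + 1e-9 < cfg.window_s:
        return 0
    return floor((length_s - cfg.window_s) / cfg.step_s + 1e-9) + 1


def window_graph_series(
    rec: RegionRecording,
    interval: tuple[float, float],
    cfg: AnalysisConfig = DEFAULT_CONFIG,
) -> list[WindowGraph]:
    """Directed pairwise estimates over sliding windows in an interval.

    Windows are anchored at the interval start and must lie fully inside it
    (a 15 s period yields 14 windows at the default 2 s / 1 s geometry), so
    ictal and surrounding signal never mix within one window. A time t maps
    to sample floor(t * rate).
    """
    t0, t1 = interval
    if t0 < -1e-9 or t1 > rec.duration_s + 1e-9:
        raise ValueError(
            f"interval [{t0}, {t1}] outside recording of {rec.duration_s:.2f} s"
        )
    n_win = window_count(t1 - t0, cfg)
    if n_win == 0:
        raise ValueError(
            f"interval of {t1 - t0:.2f} s is shorter than one {cfg.window_s} s window"
        )
    if len(rec.roles) < 2:
        raise ValueError("at least two mapped regions are required")
    pairs = role_pairs(rec.roles)
    win_len = int(round(cfg.window_s * rec.rate))
    graphs = []
    for k in range(n_win):
        start = t0 + k * cfg.step_s
        i0 = floor(start * rec.rate + 1e-9)
        sl = slice(i0, i0 + win_len)
        edges = [
            directed_pair_estimate(
                rec.signal(a)[sl], rec.signal(b)[sl], cfg, pair=(a, b), rate=rec.rate
            )
            for a, b in pairs
        ]
        graphs.append(
            WindowGraph(
                t_center=start + cfg.window_s / 2,
                edges=edges,
                available_roles=list(rec.roles),
            )
        )
    return graphs


def degree_series(
    graphs: list[WindowGraph], threshold: float = DEFAULT_CONFIG.h2_threshold
) -> DegreeSeries:
    """Count supra-threshold directed connections per window and region.

    An edge adds one to its source's out-degree and one to its target's
    in-degree iff h2 > threshold and the edge is directed.
    """
    if not graphs:
        raise ValueError("degree series needs at least one window graph")
    roles = list(graphs[0].available_roles)
    idx = {r: i for i, r in enumerate(roles)}
    out = np.zeros((len(graphs), len(roles)), dtype=int)
    inn = np.zeros_like(out)
    for w, g in enumerate(graphs):
        for e in g.edges:
            if e.h2 <= threshold or e.direction is Direction.UNDIRECTED:
                continue
            a, b = e.pair
            src, dst = (a, b) if e.direction is Direction.X_TO_Y else (b, a)
            out[w, idx[src]] += 1
            inn[w, idx[dst]] += 1
    return DegreeSeries(
        roles=roles,
        t_centers=np.array([g.t_center for g in graphs]),
        out=out,
        inn=inn,
    )


def period_degree_summary(series: DegreeSeries) -> PeriodDegreeSummary:
    """Average thalamic and mesio-temporal degrees over a period's windows.

    Degrees are raw counts over the available edges (not rescaled when
    roles are missing); the availability is recorded in ``notes``.
    """
    notes = []
    if RegionRole.Th in series.roles:
        th_out = float(series.role_out(RegionRole.Th).mean())
        th_in = float(series.role_in(RegionRole.Th).mean())
        th_defined = True
    else:
        th_out = th_in = float("nan")
        th_defined = False
        notes.append("thalamus not recorded: Th degrees undefined")
    mesial = [r for r in series.roles if r in MESIAL_ROLES]
    if mesial:
        mt_out = float(np.mean([series.role_out(r) for r in mesial]))
        mt_in = float(np.mean([series.role_in(r) for r in mesial]))
        mt_defined = True
        if len(mesial) < 3:
            notes.append(
                f"only {len(mesial)}/3 mesial roles available for MT degrees"
            )
    else:
        mt_out = mt_in = float("nan")
        mt_defined = False
        notes.append("no mesial roles recorded: MT degrees undefined")
    return PeriodDegreeSummary(
        th_out=th_out, th_in=th_in, mt_out=mt_out, mt_in=mt_in,
        th_defined=th_defined, mt_defined=mt_defined, notes=notes,
    )


def edges_frame(graphs: list[WindowGraph]) -> pd.DataFrame:
    """Flatten window graphs into a per-edge table for text output."""
    rows = []
    for g in graphs:
        for e in g.edges:
            a, b = e.pair
            if e.direction is Direction.Y_TO_X:
                a, b = b, a
            rows.append(
                (g.t_center, str(a), str(b), e.h2, e.delay_s, e.direction.value)
            )
    return pd.DataFrame(
        rows, columns=["t_center", "source", "target", "h2", "delay_s", "direction"]
    )
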