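"""Nonparametric group statistics over per-seizure index records.

The comparisons mirror the study design: paired Wilcoxon signed-rank tests
of each synchronization index between the seizure-onset and end-of-seizure
periods; Spearman rank correlations of the end-of-seizure indices with
seizure duration (plus an ordinary least-squares R-squared for the
thalamic index); and Mann-Whitney rank-sum contrasts of the spike-wave
pattern group (A) against the remaining seizures (B) for the four indices
and the four degree measures.

Seizures are treated as independent observations, including multiple
seizures from one patient; an optional per-patient aggregation averages
each patient's seizures first. All p-values are two-sided, and no
multiple-testing correction is applied — the report carries the number of
tests performed so callers can apply their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .indices import MEASURES, SeizureIndexRecord

__all__ = [
    "TestResult",
    "StatsReport",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "spearman_corr",
    "linear_r2",
    "group_stats_report",
]

DEGREE_MEASURES = ("th_out", "th_in", "mt_out", "mt_in")


class DegenerateTestError(ValueError):
    """The data admit no informative test (e.g. all differences zero)."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    name: str
    statistic: float
    pvalue: float
    n: int
    group_sizes: tuple[int, ...] = ()
    method: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.pvalue) or 0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"p-value {self.pvalue} outside [0, 1]")


def wilcoxon_signed_rank(paired_a, paired_b) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (their count is reported). The exact null
    distribution is used for n <= 25 with no zero differences; otherwise
    the normal approximation with tie correction.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    n_zero = int(np.sum(d == 0))
    n = int(np.sum(d != 0))
    if n == 0:
        raise DegenerateTestError("all paired differences are zero")
    if n < 5:
        raise DegenerateTestError(
            f"only {n} non-zero differences; at least 5 required"
        )
    exact = a.size <= 25 and n_zero == 0
    res = sps.wilcoxon(
        a, b, zero_method="wilcox", method="exact" if exact else "approx",
        correction=False, alternative="two-sided",
    )
    return TestResult(
        name="wilcoxon_signed_rank",
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n=n,
        method="exact" if exact else "normal approximation, tie-corrected",
        extra={"n_zero_dropped": n_zero},
    )


def mann_whitney_u(group_a, group_b, method: str = "asymptotic") -> TestResult:
    """Two-sided Mann-Whitney U rank-sum test on two independent groups.

    The default is the tie-corrected normal approximation without
    continuity correction. ``method="exact"`` enumerates the null
    distribution and is available for min(n) <= 8 with no ties;
    ``method="auto"`` picks the exact path when it is available.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if method == "auto":
        method = "exact" if (min(a.size, b.size) <= 8 and not ties) else "asymptotic"
    if method == "exact":
        if ties:
            raise ValueError("exact Mann-Whitney enumeration requires tie-free data")
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        note = "exact enumeration"
    elif method == "asymptotic":
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        note = "normal approximation, tie-corrected, no continuity correction"
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(
        name="mann_whitney_u",
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n=a.size + b.size,
        group_sizes=(a.size, b.size),
        method=note,
    )


def spearman_corr(x, y) -> TestResult:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Ties receive average ranks; the p-value uses the t-distribution on
    n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 5:
        raise ValueError("at least 5 observations required")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateTestError("constant input has no rank correlation")
    res = sps.spearmanr(x, y)
    return TestResult(
        name="spearman",
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n=x.size,
        method="t-approximation on n-2 d.f.",
    )


def linear_r2(x, y) -> TestResult:
    """Ordinary least-squares simple regression: R-squared and slope sign."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.all(x == x[0]):
        raise DegenerateTestError("constant predictor admits no regression")
    res = sps.linregress(x, y)
    return TestResult(
        name="ols_r2",
        statistic=float(res.rvalue**2),
        pvalue=float(res.pvalue),
        n=x.size,
        method="ordinary least squares",
        extra={"slope": float(res.slope), "intercept": float(res.intercept)},
    )


@dataclass
class StatsReport:
    """All group comparisons of the study design, over one index table."""

    so_vs_es: dict[str, TestResult]
    duration_spearman: dict[str, TestResult]
    th_duration_ols: TestResult
    pattern_indices: dict[str, TestResult | None]
    pattern_degrees: dict[str, TestResult | None]
    n_seizures: int
    n_pattern: dict[str, int]
    n_tests: int
    per_patient: bool = False
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []

        def add(family: str, key: str, r: TestResult | None) -> None:
            if r is None:
                rows.append((family, key, "", np.nan, np.nan, np.nan, "insufficient groups"))
            else:
                rows.append(
                    (family, key, r.name, r.statistic, r.pvalue, r.n, r.method)
                )

        for m, r in self.so_vs_es.items():
            add("es_vs_so", m, r)
        for m, r in self.duration_spearman.items():
            add("es_index_vs_duration", m, r)
        add("es_index_vs_duration_ols", "th", self.th_duration_ols)
        for m, r in self.pattern_indices.items():
            add("pattern_a_vs_b_index", m, r)
        for m, r in self.pattern_degrees.items():
            add("pattern_a_vs_b_degree", m, r)
        return pd.DataFrame(
            rows,
            columns=["family", "measure", "test", "statistic", "pvalue", "n", "method"],
        )

    def summary(self) -> str:
        lines = [
            f"Group statistics over {self.n_seizures} seizures "
            f"(pattern A: {self.n_pattern.get('A', 0)}, "
            f"B: {self.n_pattern.get('B', 0)}); "
            f"{self.n_tests} tests, no multiplicity correction.",
            "",
            "End-of-seizure vs seizure-onset indices (Wilcoxon signed-rank):",
        ]
        for m, r in self.so_vs_es.items():
            lines.append(f"  {m:>6} index: W={r.statistic:g}, p={r.pvalue:.2g}")
        lines.append("ES index vs seizure duration (Spearman):")
        for m, r in self.duration_spearman.items():
            lines.append(
                f"  {m:>6} index: rho={r.statistic:+.3f}, p={r.pvalue:.3f}"
            )
        o = self.th_duration_ols
        lines.append(
            f"ES th index vs duration (OLS): R2={o.statistic:.2f}, "
            f"slope={o.extra['slope']:+.2g}, p={o.pvalue:.3f}"
        )
        lines.append("Pattern A vs B (Mann-Whitney):")
        for m, r in {**self.pattern_indices, **self.pattern_degrees}.items():
            if r is None:
                lines.append(f"  {m:>6}: insufficient groups")
            else:
                lines.append(f"  {m:>6}: U={r.statistic:g}, p={r.pvalue:.4f}")
        for f in self.flags:
            lines.append(f"note: {f}")
        return "\n".join(lines)


def _aggregate_per_patient(frame: pd.DataFrame) -> pd.DataFrame:
    """Average each patient's seizures (per pattern) into one observation."""
    value_cols = [c for c in frame.columns if c not in ("patient", "seizure", "pattern")]
    out = (
        frame.groupby(["patient", "pattern"], as_index=False)[value_cols]
        .mean()
        .assign(seizure=lambda f: f["patient"].astype(str) + "/" + f["pattern"])
    )
    return out


def group_stats_report(
    records: list[SeizureIndexRecord], per_patient: bool = False
) -> StatsReport:
    """Run every group comparison of the study design on an index table."""
    if len(records) < 2:
        raise ValueError("at least two seizures are required")
    frame = pd.DataFrame([r.to_row() for r in records])
    flags: list[str] = []
    if per_patient:
        frame = _aggregate_per_patient(frame)
        flags.append("per-patient aggregation: seizures averaged within patient")
    required = (
        ["pattern", "duration_s"]
        + [f"{p}_{m}" for p in ("es", "so") for m in MEASURES]
        + list(DEGREE_MEASURES)
    )
    for col in required:
        if col not in frame.columns:
            raise KeyError(f"index table lacks required column {col!r}")

    so_vs_es = {
        m: wilcoxon_signed_rank(frame[f"es_{m}"], frame[f"so_{m}"]) for m in MEASURES
    }
    duration_spearman = {
        m: spearman_corr(frame[f"es_{m}"], frame["duration_s"]) for m in MEASURES
    }
    th_duration_ols = linear_r2(frame["duration_s"], frame["es_th"])

    is_a = frame["pattern"] == "A"
    n_pattern = {"A": int(is_a.sum()), "B": int((~is_a).sum())}
    both = n_pattern["A"] > 0 and n_pattern["B"] > 0
    if not both:
        flags.append("pattern contrast skipped: need seizures of both patterns")
    pattern_indices: dict[str, TestResult | None] = {}
    for m in MEASURES:
        pattern_indices[m] = (
            mann_whitney_u(frame.loc[is_a, f"es_{m}"], frame.loc[~is_a, f"es_{m}"])
            if both
            else None
        )
    pattern_degrees: dict[str, TestResult | None] = {}
    for d in DEGREE_MEASURES:
        pattern_degrees[d] = (
            mann_whitney_u(frame.loc[is_a, d], frame.loc[~is_a, d]) if both else None
        )

    n_tests = (
        len(so_vs_es)
        + len(duration_spearman)
        + 1
        + sum(r is not None for r in pattern_indices.values())
        + sum(r is not None for r in pattern_degrees.values())
    )
    return StatsReport(
        so_vs_es=so_vs_es,
        duration_spearman=duration_spearman,
        th_duration_ols=th_duration_ols,
        pattern_indices=pattern_indices,
        pattern_degrees=pattern_degrees,
        n_seizures=len(frame),
        n_pattern=n_pattern,
        n_tests=n_tests,
        per_patient=per_patient,
        flags=flags,
    )
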