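"""Event-based scoring of detected steps against annotations.

A detected step counts as a true positive only if *both* its start and
its end lie within the allowed temporal distance of the corresponding
annotated step's start and end.  Pairing is a maximum-cardinality
one-to-one matching over the eligibility graph, with ties broken by the
smallest total |start offset| + |end offset|, so the true-positive count
never depends on list order and is never undercounted by greediness.

Precision = TP/(TP+FP), recall = TP/(TP+FN), and the F-score is their
harmonic mean.  Undefined ratios (zero denominators) are reported as an
explicit NA marker (``None``), never silently as 0.

Signed delays are detected-minus-annotated offsets of matched start and
end points (negative when detection precedes annotation).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .imu_io import StepInterval

__all__ = [
    "MatchReport",
    "EvalMetrics",
    "DelayStats",
    "harmonic_f_score",
    "match_steps",
    "metrics",
    "delay_summary",
    "tolerance_sweep",
    "DEFAULT_TOLERANCES_S",
]

DEFAULT_TOLERANCES_S: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 1.0)

#: cost assigned to ineligible pairs in the assignment problem; any
#: total of eligible costs is far below one of these, so minimising the
#: assignment cost maximises matched cardinality first.
_INELIGIBLE = 1e9


@dataclass
class MatchReport:
    """TP/FP/FN pairing of detections against annotations at one tolerance."""

    allowed_distance_s: float
    pairs: list[tuple[StepInterval, StepInterval]]
    tp: int
    fp: int
    fn: int
    start_delays_s: list[float]
    end_delays_s: list[float]


@dataclass(frozen=True)
class EvalMetrics:
    """Precision/recall/F; ``None`` marks an undefined (NA) value."""

    precision: float | None
    recall: float | None
    f_score: float | None


@dataclass(frozen=True)
class DelayStats:
    """Pooled mean and sample standard deviation of signed delays."""

    start_mean_s: float | None
    start_sd_s: float | None
    end_mean_s: float | None
    end_sd_s: float | None
    n_pairs: int


def harmonic_f_score(precision, recall):
    """Harmonic mean of precision and recall; ``None`` when undefined."""
    if precision is None or recall is None:
        return None
    if precision + recall == 0:
        return None
    return 2 * precision * recall / (precision + recall)


def match_steps(
    annotated: list[StepInterval],
    detected: list[StepInterval],
    allowed_distance_s: float,
    sample_rate_hz: float,
    strategy: str = "optimal",
) -> MatchReport:
    """Pair detected with annotated steps at the given temporal tolerance.

    ``strategy`` is ``"optimal"`` (maximum-cardinality, minimum total
    offset) or ``"greedy"`` (first-eligible in start order, kept for
    sensitivity analysis).
    """
    if allowed_distance_s < 0:
        raise ValueError("allowed distance must be non-negative")
    tol = allowed_distance_s
    rate = sample_rate_hz
    n, m = len(annotated), len(detected)

    ds = np.empty((n, m))
    de = np.empty((n, m))
    for i, a in enumerate(annotated):
        for j, d in enumerate(detected):
            ds[i, j] = (d.start - a.start) / rate
            de[i, j] = (d.end - a.end) / rate
    eligible = (np.abs(ds) <= tol) & (np.abs(de) <= tol)

    pairs_idx: list[tuple[int, int]] = []
    if n and m and eligible.any():
        if strategy == "optimal":
            cost = np.where(eligible, np.abs(ds) + np.abs(de), _INELIGIBLE)
            rows, cols = linear_sum_assignment(cost)
            pairs_idx = [
                (int(i), int(j))
                for i, j in zip(rows, cols)
                if eligible[i, j]
            ]
        elif strategy == "greedy":
            used = set()
            for i in range(n):
                for j in range(m):
                    if j not in used and eligible[i, j]:
                        pairs_idx.append((i, j))
                        used.add(j)
                        break
        else:
            raise ValueError(f"unknown matching strategy {strategy!r}")

    pairs_idx.sort()
    pairs = [(annotated[i], detected[j]) for i, j in pairs_idx]
    tp = len(pairs)
    return MatchReport(
        allowed_distance_s=tol,
        pairs=pairs,
        tp=tp,
        fp=m - tp,
        fn=n - tp,
        start_delays_s=[float(ds[i, j]) for i, j in pairs_idx],
        end_delays_s=[float(de[i, j]) for i, j in pairs_idx],
    )


def metrics(report: MatchReport) -> EvalMetrics:
    """Precision, recall, and F-score of one match report."""
    tp, fp, fn = report.tp, report.fp, report.fn
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    return EvalMetrics(precision, recall, harmonic_f_score(precision, recall))


def pool_reports(reports) -> MatchReport:
    """Sum TP/FP/FN and concatenate delays over per-profile reports."""
    reports = list(reports)
    if not reports:
        raise ValueError("no reports to pool")
    tol = reports[0].allowed_distance_s
    if any(r.allowed_distance_s != tol for r in reports):
        raise ValueError("cannot pool reports at different tolerances")
    return MatchReport(
        allowed_distance_s=tol,
        pairs=[p for r in reports for p in r.pairs],
        tp=sum(r.tp for r in reports),
        fp=sum(r.fp for r in reports),
        fn=sum(r.fn for r in reports),
        start_delays_s=[d for r in reports for d in r.start_delays_s],
        end_delays_s=[d for r in reports for d in r.end_delays_s],
    )


def delay_summary(reports) -> DelayStats:
    """Pooled mean and sample SD of start/end delays over matched pairs."""
    starts = [d for r in reports for d in r.start_delays_s]
    ends = [d for r in reports for d in r.end_delays_s]
    if not starts:
        return DelayStats(None, None, None, None, 0)

    def _sd(values):
        return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0

    return DelayStats(
        start_mean_s=float(np.mean(starts)),
        start_sd_s=_sd(starts),
        end_mean_s=float(np.mean(ends)),
        end_sd_s=_sd(ends),
        n_pairs=len(starts),
    )


def tolerance_sweep(
    annotated: list[StepInterval],
    detected: list[StepInterval],
    tolerances=DEFAULT_TOLERANCES_S,
    sample_rate_hz: float = 100.0,
    strategy: str = "optimal",
) -> pd.DataFrame:
    """Metrics at each tolerance, one row per allowed distance."""
    if any(t <= 0 for t in tolerances):
        raise ValueError("tolerances must be positive")
    if list(tolerances) != sorted(tolerances):
        raise ValueError("tolerances must be ascending")
    rows = []
    for tol in tolerances:
        report = match_steps(annotated, detected, tol, sample_rate_hz, strategy)
        m = metrics(report)
        rows.append(
            {
                "tolerance_s": tol,
                "tp": report.tp,
                "fp": report.fp,
                "fn": report.fn,
                "precision": m.precision,
                "recall": m.recall,
                "f_score": m.f_score,
            }
        )
    return pd.DataFrame(rows)
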