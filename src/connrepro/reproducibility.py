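"""Topological similarity (edge Dice) and test-retest reliability (ICC).

In a test-retest design every subject is measured twice.  Edge-wise Dice
overlap of thresholded graphs quantifies how similar two topologies are;
averaging it within subjects (session 1 vs session 2) and across subjects
separates scan-rescan stability from inter-individual variability.  The
intraclass correlation coefficient ICC = s2_bs / (s2_bs + s2_ws) — the
between-subject share of total variance — quantifies reliability of a
scalar metric, here evaluated at every point of a graph curve.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BinaryGraph, ConnectivityMatrix, threshold_to_density
from .curves import GraphCurve, ParameterGrid

#: Total-mean-square floor below which the ICC is flagged unstable.
ICC_VARIANCE_TOLERANCE = 1e-10


def edge_dice(a: BinaryGraph, b: BinaryGraph) -> float:
    """Dice overlap of two edge sets: 2 |E(a) ∩ E(b)| / (|E(a)| + |E(b)|).

    Edges are equal when they connect the same two nodes, so both graphs
    must share the node set and ordering.  Two empty edge sets are counted
    as identical topologies (Dice 1.0).
    """
    if a.node_labels != b.node_labels:
        raise ValueError("edge_dice requires identical node sets and ordering")
    shared = int((a.adjacency & b.adjacency).sum()) // 2
    total = a.n_edges + b.n_edges
    if total == 0:
        return 1.0
    return 2.0 * shared / total


@dataclass
class DiceSummary:
    """Mean intra-/inter-subject Dice per density, plus the per-pair values."""

    grid: ParameterGrid
    intra_mean: np.ndarray
    inter_mean: np.ndarray
    pairs: pd.DataFrame  # columns: density, kind, subject_a, session_a, subject_b, session_b, dice
    group: str = ""


def dice_curves(dataset: list[ConnectivityMatrix], grid: ParameterGrid) -> DiceSummary:
    """Intra- and inter-subject Dice overlap across a density grid.

    ``dataset`` must hold one group with >= 2 subjects and exactly 2
    sessions per subject.  At each density, every matrix is thresholded and
    intra_mean averages each subject's session-1-vs-session-2 Dice while
    inter_mean averages Dice over all cross-subject graph pairs (all four
    session combinations per subject pair).
    """
    if grid.kind != "density":
        raise ValueError("dice_curves requires a density grid")
    groups = {m.group for m in dataset}
    if len(groups) > 1:
        raise ValueError(f"dice_curves expects a single group, got {sorted(groups)}")
    by_subject: dict[str, dict[str, ConnectivityMatrix]] = {}
    for m in dataset:
        by_subject.setdefault(m.subject_id, {})[m.session_id] = m
    if len(by_subject) < 2:
        raise ValueError("dice_curves requires at least 2 subjects")
    for sid, sessions in by_subject.items():
        if len(sessions) != 2:
            raise ValueError(
                f"subject {sid!r} has {len(sessions)} sessions, expected exactly 2"
            )
    subjects = sorted(by_subject)
    records: list[tuple] = []
    intra_mean = np.empty(len(grid))
    inter_mean = np.empty(len(grid))
    for idx, d in enumerate(grid.values):
        thresholded = {
            (sid, ses): threshold_to_density(m, float(d))
            for sid, sessions in by_subject.items()
            for ses, m in sessions.items()
        }
        intra_vals = []
        for sid in subjects:
            s1, s2 = sorted(by_subject[sid])
            v = edge_dice(thresholded[(sid, s1)], thresholded[(sid, s2)])
            intra_vals.append(v)
            records.append((float(d), "intra", sid, s1, sid, s2, v))
        inter_vals = []
        for sa, sb in itertools.combinations(subjects, 2):
            for ses_a in sorted(by_subject[sa]):
                for ses_b in sorted(by_subject[sb]):
                    v = edge_dice(thresholded[(sa, ses_a)], thresholded[(sb, ses_b)])
                    inter_vals.append(v)
                    records.append((float(d), "inter", sa, ses_a, sb, ses_b, v))
        intra_mean[idx] = np.mean(intra_vals)
        inter_mean[idx] = np.mean(inter_vals)
    pairs = pd.DataFrame(
        records,
        columns=[
            "density",
            "kind",
            "subject_a",
            "session_a",
            "subject_b",
            "session_b",
            "dice",
        ],
    )
    return DiceSummary(
        grid=grid,
        intra_mean=intra_mean,
        inter_mean=inter_mean,
        pairs=pairs,
        group=next(iter(groups)) if groups else "",
    )


@dataclass
class ICCEstimate:
    """One-way random-effects ICC with its variance components.

    ``icc`` clamps the between-subject variance at zero; ``icc_unclamped``
    is the raw (MSB - MSW) / (MSB + (k-1) MSW) value for transparency.
    ``valid`` is False when total variance is below the stability floor.
    """

    icc: float
    valid: bool
    icc_unclamped: float
    msb: float
    msw: float


def icc_oneway(values: np.ndarray) -> ICCEstimate:
    """One-way ANOVA method-of-moments ICC on a subjects x sessions table.

    With n subjects and k sessions: MSB is the between-subject mean square,
    MSW the within-subject mean square; s2_bs = max(0, (MSB - MSW) / k) and
    ICC = s2_bs / (s2_bs + MSW).  The estimate is flagged invalid when
    MSB + MSW falls below ``ICC_VARIANCE_TOLERANCE`` (little to no variance
    makes the ratio unstable).
    """
    table = np.asarray(values, dtype=float)
    if table.ndim != 2:
        raise ValueError("icc_oneway requires a 2-D subjects x sessions table")
    n, k = table.shape
    if n < 2:
        raise ValueError(f"icc_oneway requires at least 2 subjects, got {n}")
    if k < 2:
        raise ValueError(f"icc_oneway requires at least 2 sessions, got {k}")
    if np.any(~np.isfinite(table)):
        raise ValueError("icc_oneway requires a complete (balanced) table")
    subj_means = table.mean(axis=1)
    grand = table.mean()
    msb = k * float(((subj_means - grand) ** 2).sum()) / (n - 1)
    msw = float(((table - subj_means[:, None]) ** 2).sum()) / (n * (k - 1))
    valid = (msb + msw) >= ICC_VARIANCE_TOLERANCE
    unclamped_denom = msb + (k - 1) * msw
    icc_unclamped = (msb - msw) / unclamped_denom if unclamped_denom > 0 else np.nan
    sigma_bs = max(0.0, (msb - msw) / k)
    denom = sigma_bs + msw
    icc = sigma_bs / denom if denom > 0 else np.nan
    if not valid:
        icc = np.nan
    return ICCEstimate(icc=icc, valid=valid, icc_unclamped=icc_unclamped, msb=msb, msw=msw)


@dataclass
class ICCResult:
    """Pointwise ICC along a curve grid with per-point validity flags."""

    grid: ParameterGrid
    icc: np.ndarray
    valid: np.ndarray
    n_subjects: int
    n_sessions: int
    metric_name: str = ""
    group: str = ""


def icc_curve(curves: list[GraphCurve]) -> ICCResult:
    """Pointwise test-retest ICC across a cohort of per-session curves.

    Expects one curve per subject x session on a shared grid, all from one
    group and metric.  Grid points where any curve is undefined are marked
    invalid and skipped.
    """
    if not curves:
        raise ValueError("icc_curve requires at least one curve")
    grid = curves[0].grid
    metric = curves[0].metric_name
    for c in curves[1:]:
        if c.grid != grid:
            raise ValueError("icc_curve requires a shared grid across curves")
        if c.metric_name != metric:
            raise ValueError("icc_curve requires a single metric")
    groups = {c.group for c in curves}
    if len(groups) > 1:
        raise ValueError(f"icc_curve expects a single group, got {sorted(groups)}")
    by_subject: dict[str, dict[str, GraphCurve]] = {}
    for c in curves:
        by_subject.setdefault(c.subject_id, {})[c.session_id] = c
    subjects = sorted(by_subject)
    n_sessions = {len(v) for v in by_subject.values()}
    if len(n_sessions) != 1:
        raise ValueError("all subjects must have the same number of sessions")
    k = n_sessions.pop()
    stacked = np.stack(
        [
            [by_subject[s][ses].values for ses in sorted(by_subject[s])]
            for s in subjects
        ]
    )  # (n_subjects, k, n_points)
    defined = np.stack(
        [
            [by_subject[s][ses].defined for ses in sorted(by_subject[s])]
            for s in subjects
        ]
    )
    n_points = len(grid)
    icc = np.full(n_points, np.nan)
    valid = np.zeros(n_points, dtype=bool)
    for p in range(n_points):
        if not defined[:, :, p].all():
            continue
        est = icc_oneway(stacked[:, :, p])
        icc[p] = est.icc
        valid[p] = est.valid
    return ICCResult(
        grid=grid,
        icc=icc,
        valid=valid,
        n_subjects=len(subjects),
        n_sessions=k,
        metric_name=metric,
        group=curves[0].group,
    )


def icc_category(icc: float) -> str:
    """Qualitative agreement band for an ICC value.

    Below 0.2 "poor"; up to 0.40 "fair"; up to 0.60 "moderate"; up to 0.80
    "strong"; above 0.8 "near-perfect".  Values falling in the printed gap
    (0.2, 0.21) are assigned to "fair".
    """
    if icc < 0.2:
        return "poor"
    if icc <= 0.40:
        return "fair"
    if icc <= 0.60:
        return "moderate"
    if icc <= 0.80:
        return "strong"
    return "near-perfect"
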