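"""Graph curves: a network metric as a function of a sweep parameter.

Each connectivity matrix yields, per metric, a curve of metric value vs.
graph density (thresholding at every grid density); the rich-club
coefficient is instead swept over the degree threshold k at one fixed
density.  Curves from a cohort share a grid so they can be averaged,
compared, and fed to the reliability and permutation stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ConnectivityMatrix,
    DegenerateGraphError,
    max_density,
    threshold_to_density,
)
from .metrics import DENSITY_METRICS, rich_club_coefficient


@dataclass
class ParameterGrid:
    """Strictly increasing sweep values: densities in (0, 1] or degree levels k."""

    kind: str  # "density" | "degree_k"
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("density", "degree_k"):
            raise ValueError(f"unknown grid kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("parameter grid must be nonempty")
        if np.any(np.diff(self.values) <= 0):
            raise ValueError("parameter grid values must be strictly increasing")
        if self.kind == "density" and (
            self.values[0] <= 0 or self.values[-1] > 1
        ):
            raise ValueError("density grid values must lie in (0, 1]")

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ParameterGrid)
            and self.kind == other.kind
            and np.array_equal(self.values, other.values)
        )


@dataclass
class GraphCurve:
    """Metric values aligned to a grid, with per-point defined flags.

    Undefined points (e.g. assortativity with a degenerate denominator) are
    carried as NaN with ``defined=False`` — never interpolated.
    """

    grid: ParameterGrid
    values: np.ndarray
    metric_name: str
    subject_id: str = ""
    session_id: str = ""
    group: str = ""
    defined: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.grid):
            raise ValueError(
                f"curve has {self.values.size} values for a grid of {len(self.grid)}"
            )
        if self.defined is None:
            self.defined = ~np.isnan(self.values)
        else:
            self.defined = np.asarray(self.defined, dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view: one row per grid point."""
        return pd.DataFrame(
            {
                "subject": self.subject_id,
                "session": self.session_id,
                "group": self.group,
                "metric": self.metric_name,
                "parameter_kind": self.grid.kind,
                "parameter": self.grid.values,
                "value": self.values,
                "defined": self.defined,
            }
        )


def common_density_range(
    dataset: list[ConnectivityMatrix], step: float
) -> ParameterGrid:
    """Density grid {step, 2*step, ...} up to the highest density common to all.

    The upper end is the minimum over the dataset of each matrix's maximal
    (all-positive-edge) density, inclusive when it falls on the grid.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    if step <= 0:
        raise ValueError("step must be positive")
    d_common = min(max_density(m) for m in dataset)
    n_steps = int(math.floor(d_common / step + 1e-9))
    if n_steps < 1:
        raise ValueError(
            f"no common positive density: min of maximal densities is {d_common:.6g}, "
            f"below one step of {step}"
        )
    return ParameterGrid(kind="density", values=step * np.arange(1, n_steps + 1))


def metric_curve(
    m: ConnectivityMatrix, metric_name: str, grid: ParameterGrid
) -> GraphCurve:
    """Evaluate a named metric on ``m`` thresholded at every grid density."""
    if grid.kind != "density":
        raise ValueError("metric_curve requires a density grid")
    try:
        fn = DENSITY_METRICS[metric_name]
    except KeyError:
        raise ValueError(f"unknown metric {metric_name!r}") from None
    values = np.full(len(grid), np.nan)
    defined = np.zeros(len(grid), dtype=bool)
    for idx, d in enumerate(grid.values):
        g = threshold_to_density(m, float(d))
        try:
            v = fn(g)
        except DegenerateGraphError:
            v = None
        if v is not None:
            values[idx] = v
            defined[idx] = True
    return GraphCurve(
        grid=grid,
        values=values,
        defined=defined,
        metric_name=metric_name,
        subject_id=m.subject_id,
        session_id=m.session_id,
        group=m.group,
    )


def rich_club_curve(
    m: ConnectivityMatrix, density: float, k_values: ParameterGrid
) -> GraphCurve:
    """Rich-club coefficient vs. degree threshold k at one fixed density."""
    if k_values.kind != "degree_k":
        raise ValueError("rich_club_curve requires a degree_k grid")
    g = threshold_to_density(m, density)
    values = np.full(len(k_values), np.nan)
    defined = np.zeros(len(k_values), dtype=bool)
    for idx, k in enumerate(k_values.values):
        v = rich_club_coefficient(g, int(k))
        if v is not None:
            values[idx] = v
            defined[idx] = True
    return GraphCurve(
        grid=k_values,
        values=values,
        defined=defined,
        metric_name="rich_club",
        subject_id=m.subject_id,
        session_id=m.session_id,
        group=m.group,
    )
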