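"""End-to-end orchestration: manifest in, tidy result tables out.

Runs the full reproducibility analysis — common density grid, per-session
metric and rich-club curves, intra-/inter-subject Dice, pointwise ICC, and
pairwise-group permutation tests — and writes each stage as a tidy
delimited table plus the exact resolved configuration.  Given a seed the
outputs are deterministic.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ConnectivityMatrix, degrees, threshold_to_density
from .curves import (
    GraphCurve,
    ParameterGrid,
    common_density_range,
    metric_curve,
    rich_club_curve,
)
from .fda import permutation_test_curves
from .io import load_dataset
from .metrics import DENSITY_METRICS
from .reproducibility import dice_curves, icc_category, icc_curve

logger = logging.getLogger("connrepro")


@dataclass
class PipelineConfig:
    """All tunable analysis parameters, serializable to YAML."""

    density_step: float = 0.01
    metrics: list[str] = field(default_factory=lambda: list(DENSITY_METRICS))
    rich_club_density: float = 0.15
    rich_club_density_mode: str = "fixed"  # "fixed" | "common_max"
    rich_club_k_max: int | None = None  # None: max degree at the rich-club density
    n_iterations: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.metrics) - set(DENSITY_METRICS)
        if unknown:
            raise ValueError(f"unknown metrics: {sorted(unknown)}")
        if self.rich_club_density_mode not in ("fixed", "common_max"):
            raise ValueError(
                f"unknown rich_club_density_mode {self.rich_club_density_mode!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _identity(m: ConnectivityMatrix) -> str:
    return f"(subject={m.subject_id}, session={m.session_id}, group={m.group})"


def _fda_seed(base_seed: int, index: int) -> int:
    return (base_seed * 1_000_003 + 7_919 * index + 1) % (2**31)


def run_pipeline(
    manifest: str | Path | list[ConnectivityMatrix],
    config: PipelineConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Run every analysis stage and write tidy tables into ``out_dir``.

    ``manifest`` is a manifest file path or an already-loaded dataset.
    Returns a mapping from table name to written path.  Stage failures are
    re-raised annotated with the offending (subject, session, group).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        dataset = (
            manifest
            if isinstance(manifest, list)
            else load_dataset(manifest)
        )
        logger.info(
            "loaded %d matrices; config=%s", len(dataset), dataclasses.asdict(config)
        )
        groups = sorted({m.group for m in dataset})
        grid = common_density_range(dataset, config.density_step)
        logger.info(
            "common density grid: %d points in [%g, %g]",
            len(grid),
            grid.values[0],
            grid.values[-1],
        )

        rc_density = (
            float(grid.values[-1])
            if config.rich_club_density_mode == "common_max"
            else config.rich_club_density
        )
        k_max = config.rich_club_k_max
        if k_max is None:
            k_max = 0
            for m in dataset:
                try:
                    k_max = max(
                        k_max, int(degrees(threshold_to_density(m, rc_density)).max())
                    )
                except Exception as exc:
                    raise RuntimeError(
                        f"rich-club stage failed for {_identity(m)}: {exc}"
                    ) from exc
        k_grid = ParameterGrid(kind="degree_k", values=np.arange(0, k_max + 1))
        logger.info("rich-club density %g, k grid 0..%d", rc_density, k_max)

        # --- per-session curves -------------------------------------------
        all_curves: dict[str, list[GraphCurve]] = {name: [] for name in config.metrics}
        rc_curves: list[GraphCurve] = []
        frames = []
        for m in dataset:
            try:
                for name in config.metrics:
                    c = metric_curve(m, name, grid)
                    all_curves[name].append(c)
                    frames.append(c.to_frame())
                rc = rich_club_curve(m, rc_density, k_grid)
                rc_curves.append(rc)
                frames.append(rc.to_frame())
            except Exception as exc:
                raise RuntimeError(f"curve stage failed for {_identity(m)}: {exc}") from exc
        curves_path = out_dir / "curves.csv"
        pd.concat(frames, ignore_index=True).to_csv(curves_path, index=False)
        logger.info("wrote %s", curves_path)

        # --- Dice ---------------------------------------------------------
        dice_rows, pair_frames = [], []
        intra_dice_curves: dict[str, list[GraphCurve]] = {}
        for group in groups:
            subset = [m for m in dataset if m.group == group]
            summary = dice_curves(subset, grid)
            dice_rows.append(
                pd.DataFrame(
                    {
                        "group": group,
                        "density": grid.values,
                        "intra_mean": summary.intra_mean,
                        "inter_mean": summary.inter_mean,
                    }
                )
            )
            pair_frames.append(summary.pairs.assign(group=group))
            intra = summary.pairs[summary.pairs["kind"] == "intra"]
            intra_dice_curves[group] = [
                GraphCurve(
                    grid=grid,
                    values=sub.sort_values("density")["dice"].to_numpy(),
                    metric_name="intra_dice",
                    subject_id=subject,
                    group=group,
                )
                for subject, sub in intra.groupby("subject_a")
            ]
        dice_path = out_dir / "dice.csv"
        pd.concat(dice_rows, ignore_index=True).to_csv(dice_path, index=False)
        pairs_path = out_dir / "dice_pairs.csv"
        pd.concat(pair_frames, ignore_index=True).to_csv(pairs_path, index=False)
        logger.info("wrote %s and %s", dice_path, pairs_path)

        # --- ICC ----------------------------------------------------------
        icc_rows = []
        for group in groups:
            for name in config.metrics:
                curves_g = [c for c in all_curves[name] if c.group == group]
                res = icc_curve(curves_g)
                icc_rows.append(_icc_frame(res, "density"))
            res = icc_curve([c for c in rc_curves if c.group == group])
            icc_rows.append(_icc_frame(res, "degree_k"))
        icc_path = out_dir / "icc.csv"
        pd.concat(icc_rows, ignore_index=True).to_csv(icc_path, index=False)
        logger.info("wrote %s", icc_path)

        # --- FDA permutation tests ----------------------------------------
        fda_rows = []
        comparison = 0
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                ga, gb = groups[gi], groups[gj]
                for name in config.metrics + ["intra_dice"]:
                    if name == "intra_dice":
                        curves_a = intra_dice_curves[ga]
                        curves_b = intra_dice_curves[gb]
                    else:
                        curves_a = [c for c in all_curves[name] if c.group == ga]
                        curves_b = [c for c in all_curves[name] if c.group == gb]
                    curves_ab = curves_a + curves_b
                    labels = [ga] * len(curves_a) + [gb] * len(curves_b)
                    seed = _fda_seed(config.seed, comparison)
                    comparison += 1
                    result = permutation_test_curves(
                        curves_ab, labels, n_iterations=config.n_iterations, seed=seed
                    )
                    fda_rows.append(
                        {
                            "metric": name,
                            "group_a": ga,
                            "group_b": gb,
                            "observed_area": result.observed_area,
                            "p_value": result.p_value,
                            "x_count": result.x_count,
                            "n_iterations": result.n_iterations,
                            "seed": result.seed,
                            "n_a": result.group_sizes[0],
                            "n_b": result.group_sizes[1],
                        }
                    )
        fda_path = out_dir / "fda.csv"
        fda_columns = [
            "metric", "group_a", "group_b", "observed_area", "p_value",
            "x_count", "n_iterations", "seed", "n_a", "n_b",
        ]
        pd.DataFrame(fda_rows, columns=fda_columns).to_csv(fda_path, index=False)
        logger.info("wrote %s", fda_path)

        config_path = out_dir / "config_resolved.yaml"
        config.to_yaml(config_path)
        return {
            "curves": curves_path,
            "dice": dice_path,
            "dice_pairs": pairs_path,
            "icc": icc_path,
            "fda": fda_path,
            "config": config_path,
        }
    finally:
        logger.removeHandler(handler)
        handler.close()


def _icc_frame(res, parameter_kind: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": res.group,
            "metric": res.metric_name,
            "parameter_kind": parameter_kind,
            "parameter": res.grid.values,
            "icc": res.icc,
            "valid": res.valid,
            "category": [
                icc_category(v) if ok and np.isfinite(v) else ""
                for v, ok in zip(res.icc, res.valid)
            ],
            "n_subjects": res.n_subjects,
            "n_sessions": res.n_sessions,
        }
    )
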