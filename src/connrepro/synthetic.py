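"""Synthetic test-retest connectome cohorts with known ground truth.

Emulates the design of a scan-rescan reliability study — S subjects, each
measured in 2 sessions, under G processing groups — without any imaging:
a modular population backbone defines which region pairs connect and with
what expected streamline count; per-subject and per-session multiplicative
effects on the log scale introduce controllable between- and within-subject
variability; observed counts are Poisson draws around the resulting rates.

The generator is the test bed for every pipeline stage: the variance knobs
map directly to the intra- vs inter-subject Dice ordering and to the ICC,
and a group effect on within-module connection probability injects a
topological group difference for the permutation test to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ConnectivityMatrix, validate_matrix


@dataclass
class GroupSpec:
    """A processing group: its label and multiplier on p_in."""

    name: str
    group_effect: float = 1.0


@dataclass
class SyntheticConfig:
    """Cohort design and generative parameters.

    Defaults emulate a 21-subject, 2-session cohort on 78 cortical and
    deep-gray regions with a 6-module community backbone whose expected
    maximal density falls in the 0.2-0.3 range typical of streamline-count
    connectomes, and with session (scan-rescan) variability well below
    between-subject variability.
    """

    n_nodes: int = 78
    n_subjects: int = 21
    n_sessions: int = 2
    groups: list[GroupSpec] = field(default_factory=lambda: [GroupSpec("g1", 1.0)])
    n_modules: int = 6
    p_in: float = 0.7  # within-module edge probability of the backbone
    p_out: float = 0.15  # between-module edge probability
    weight_scale: float = 30.0  # mean streamline count on backbone edges
    sigma_between: float = 0.4  # sd of per-subject log-weight effect
    sigma_within: float = 0.15  # sd of per-session log-weight effect
    seed: int = 0
    deterministic: bool = False  # emit expected counts instead of Poisson draws

    def __post_init__(self) -> None:
        self.groups = [
            g if isinstance(g, GroupSpec) else GroupSpec(*g) for g in self.groups
        ]
        if not 0 < self.p_out < self.p_in <= 1:
            raise ValueError("require p_in > p_out > 0 and p_in <= 1")
        if self.sigma_between < 0 or self.sigma_within < 0:
            raise ValueError("variance parameters must be nonnegative")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_sessions < 2:
            raise ValueError("n_sessions must be >= 2")
        if self.n_modules > self.n_nodes:
            raise ValueError(
                f"cannot split {self.n_nodes} nodes into {self.n_modules} modules"
            )
        if not self.groups:
            raise ValueError("at least one group is required")


def _module_assignment(n_nodes: int, n_modules: int) -> np.ndarray:
    """Near-equal contiguous module blocks."""
    return np.concatenate(
        [np.full(len(b), i) for i, b in enumerate(np.array_split(np.arange(n_nodes), n_modules))]
    )


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def _template_weights(config: SyntheticConfig, group_index: int) -> np.ndarray:
    """Expected backbone weight per node pair (0 where no edge), upper-tri flat."""
    effect = config.groups[group_index].group_effect
    rng = np.random.default_rng([config.seed, 104729, group_index])
    modules = _module_assignment(config.n_nodes, config.n_modules)
    rows, cols = _pair_indices(config.n_nodes)
    same = modules[rows] == modules[cols]
    p_edge = np.where(same, min(1.0, config.p_in * effect), config.p_out)
    present = rng.random(rows.size) < p_edge
    weights = np.zeros(rows.size)
    weights[present] = config.weight_scale * rng.lognormal(
        mean=0.0, sigma=1.0, size=int(present.sum())
    )
    return weights


def _to_matrix(flat: np.ndarray, n: int) -> np.ndarray:
    rows, cols = _pair_indices(n)
    m = np.zeros((n, n))
    m[rows, cols] = flat
    m[cols, rows] = flat
    return m


def generate_base_connectome(
    config: SyntheticConfig, group_index: int = 0
) -> ConnectivityMatrix:
    """Population template of expected streamline counts for one group.

    Edges exist within modules with probability ``p_in * group_effect`` and
    between modules with ``p_out``; each present edge carries expected
    weight ``weight_scale * u`` with u log-normal(0, 1).  Deterministic
    given the config seed.
    """
    weights = _to_matrix(_template_weights(config, group_index), config.n_nodes)
    return validate_matrix(
        ConnectivityMatrix(
            weights=weights, group=config.groups[group_index].name
        )
    )


def generate_testretest_dataset(config: SyntheticConfig) -> list[ConnectivityMatrix]:
    """One streamline-count matrix per subject x session x group.

    For subject s, a per-edge effect b_s ~ N(0, sigma_between^2) shifts the
    backbone log-weights; each session adds e_st ~ N(0, sigma_within^2); the
    observed count on each backbone edge is Poisson(exp(log lambda + b + e))
    (or the rate itself in deterministic mode).  Matrices are ordered
    group-major, then subject, then session.
    """
    n = config.n_nodes
    rows_cols = _pair_indices(n)
    dataset: list[ConnectivityMatrix] = []
    for gi, gspec in enumerate(config.groups):
        template = _template_weights(config, gi)
        backbone = template > 0
        log_lambda = np.zeros_like(template)
        log_lambda[backbone] = np.log(template[backbone])
        for si in range(config.n_subjects):
            rng_subj = np.random.default_rng([config.seed, 15485863, gi, si])
            b = rng_subj.normal(0.0, config.sigma_between, size=template.size)
            for ti in range(config.n_sessions):
                rng_sess = np.random.default_rng(
                    [config.seed, 32452843, gi, si, ti]
                )
                e = rng_sess.normal(0.0, config.sigma_within, size=template.size)
                rate = np.zeros_like(template)
                rate[backbone] = np.exp(log_lambda[backbone] + b[backbone] + e[backbone])
                if config.deterministic:
                    counts = rate
                else:
                    counts = rng_sess.poisson(rate).astype(float)
                weights = _to_matrix(counts, n)
                dataset.append(
                    validate_matrix(
                        ConnectivityMatrix(
                            weights=weights,
                            subject_id=f"sub-{si + 1:02d}",
                            session_id=f"ses-{ti + 1}",
                            group=gspec.name,
                        )
                    )
                )
    return dataset


def generate_gaussian_repeated_measures(
    n_subjects: int,
    n_sessions: int,
    sigma_between: float,
    sigma_within: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian subjects x sessions table with known true ICC.

    value_st = b_s + e_st with b ~ N(0, sigma_between^2) and
    e ~ N(0, sigma_within^2), so the true ICC is
    sigma_between^2 / (sigma_between^2 + sigma_within^2) by construction.
    """
    if n_subjects < 2 or n_sessions < 2:
        raise ValueError("need at least 2 subjects and 2 sessions")
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, sigma_between, size=n_subjects)
    e = rng.normal(0.0, sigma_within, size=(n_subjects, n_sessions))
    values = b[:, None] + e
    return pd.DataFrame(
        values,
        index=[f"sub-{i + 1:02d}" for i in range(n_subjects)],
        columns=[f"ses-{t + 1}" for t in range(n_sessions)],
    )
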