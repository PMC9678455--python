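"""Simulation of partially nested two-arm trial data.

A partially nested (partially clustered) design randomises subjects to a
treatment arm, where they are organised into clusters (therapy groups,
classrooms, wards), and to a control arm whose subjects are mutually
independent.  The generative model for subject ``i`` is

    Y_ij = b0 + b1 * X_ij + u_j * Z_j + e_ij

where ``X_ij`` is the treatment indicator, ``u_j ~ N(0, sigma2_U)`` is the
cluster effect (present only in the treatment arm, hence the ``Z_j``
membership indicator), and the residual ``e_ij`` is heteroscedastic across
arms: variance ``sigma2_eC`` under control and ``sigma2_eU`` under
treatment.  The treatment-arm intraclass correlation is

    rho = sigma2_U / (sigma2_U + sigma2_eU).

The default truth values emulate a small-sample behavioural trial: control
mean 2 with residual variance 0.27, treatment effect 0.5, and a total
treatment-arm variance of 0.46 split between the cluster and subject levels
according to ``rho``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NO_CLUSTER",
    "TruthParameters",
    "SimulationCondition",
    "PartiallyNestedDataset",
    "derive_variance_components",
    "generate_dataset",
    "empirical_icc",
    "canonical_grid",
    "write_dataset_csv",
    "read_dataset_csv",
]

#: Cluster label carried by control subjects, which belong to no cluster.
NO_CLUSTER = -1

PRIOR_FAMILIES = ("gamma", "uniform")


def derive_variance_components(rho: float, total_var: float) -> tuple[float, float]:
    """Split a total variance into cluster and subject-level components.

    Parameters
    ----------
    rho
        Intraclass correlation in ``[0, 1)``.
    total_var
        Total (cluster + subject) variance, ``>= 0``.

    Returns
    -------
    (sigma2_U, sigma2_eU)
        Cluster-level variance ``rho * total_var`` and subject-level
        variance ``total_var - sigma2_U``; the two sum to ``total_var``
        exactly in floating point.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must lie in [0, 1), got {rho!r}")
    if total_var < 0.0:
        raise ValueError(f"total_var must be non-negative, got {total_var!r}")
    sigma2_u = rho * total_var
    sigma2_eu = total_var - sigma2_u
    return sigma2_u, sigma2_eu


@dataclass(frozen=True)
class TruthParameters:
    """Generative constants of the partially nested truth model.

    ``sigma2_U`` and ``sigma2_eU`` are derived from ``rho`` and
    ``total_treatment_var`` so that they always sum to the total exactly.
    """

    b0: float = 2.0
    b1: float = 0.5
    sigma2_eC: float = 0.27
    total_treatment_var: float = 0.46
    rho: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma2_eC < 0:
            raise ValueError("sigma2_eC must be non-negative")
        # validates rho / total_treatment_var as a side effect
        derive_variance_components(self.rho, self.total_treatment_var)

    @property
    def sigma2_U(self) -> float:
        """Cluster-level (nesting) variance under treatment."""
        return derive_variance_components(self.rho, self.total_treatment_var)[0]

    @property
    def sigma2_eU(self) -> float:
        """Subject-level residual variance under treatment."""
        return derive_variance_components(self.rho, self.total_treatment_var)[1]


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the simulation design.

    ``n_control`` defaults to ``c * m`` (balanced total allocation across
    arms) when not given explicitly.
    """

    c: int
    m: int
    rho: float
    prior_family: str = "uniform"
    n_control: int | None = None

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ValueError("need at least 2 treatment clusters")
        if self.m < 2:
            raise ValueError("need at least 2 subjects per cluster")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must lie in [0, 1), got {self.rho!r}")
        if self.prior_family not in PRIOR_FAMILIES:
            raise ValueError(f"unknown prior family {self.prior_family!r}")
        if self.n_control is None:
            object.__setattr__(self, "n_control", self.c * self.m)
        elif self.n_control < 2:
            raise ValueError("need at least 2 control subjects")

    @property
    def n_treatment(self) -> int:
        return self.c * self.m

    @property
    def n_total(self) -> int:
        return self.n_control + self.n_treatment


def canonical_grid(
    c_levels: Sequence[int] = (8, 12, 16),
    m_levels: Sequence[int] = (5, 10, 15, 20),
    rho_levels: Sequence[float] = (0.05, 0.10, 0.15),
    families: Sequence[str] = PRIOR_FAMILIES,
) -> list[SimulationCondition]:
    """The canonical study grid: 3 x 4 x 3 cells crossed with both prior
    families, 72 conditions in total."""
    return [
        SimulationCondition(c=c, m=m, rho=rho, prior_family=fam)
        for c in c_levels
        for m in m_levels
        for rho in rho_levels
        for fam in families
    ]


@dataclass
class PartiallyNestedDataset:
    """One simulated two-arm dataset.

    Rows are ordered control first, then treatment clusters ``1..c`` each
    contiguous.  ``group`` holds :data:`NO_CLUSTER` for control subjects.
    ``true_group_effects`` retains the realised ``u_j`` draws for
    diagnostics; it is ``None`` for datasets read back from disk.
    """

    y: np.ndarray
    x: np.ndarray
    group: np.ndarray
    true_group_effects: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.x = np.asarray(self.x, dtype=int)
        self.group = np.asarray(self.group, dtype=int)
        if not (len(self.y) == len(self.x) == len(self.group)):
            raise ValueError("y, x, group must have equal length")
        if set(np.unique(self.x)) - {0, 1}:
            raise ValueError("x must be a 0/1 treatment indicator")
        if np.any((self.x == 0) & (self.group != NO_CLUSTER)):
            raise ValueError("control subjects must carry the no-cluster sentinel")
        if np.any((self.x == 1) & (self.group == NO_CLUSTER)):
            raise ValueError("treatment subjects must carry a cluster label")

    @property
    def n_control(self) -> int:
        return int(np.sum(self.x == 0))

    @property
    def n_treatment(self) -> int:
        return int(np.sum(self.x == 1))

    @property
    def cluster_labels(self) -> np.ndarray:
        return np.unique(self.group[self.x == 1])

    @property
    def c(self) -> int:
        return len(self.cluster_labels)

    @property
    def cluster_sizes(self) -> np.ndarray:
        labels = self.group[self.x == 1]
        return np.bincount(labels)[self.cluster_labels]

    def to_frame(self) -> pd.DataFrame:
        cluster = pd.array(
            [g if g != NO_CLUSTER else pd.NA for g in self.group], dtype="Int64"
        )
        return pd.DataFrame(
            {
                "subject_id": np.arange(len(self.y)),
                "arm": self.x,
                "cluster": cluster,
                "y": self.y,
            }
        )


def generate_dataset(
    condition: SimulationCondition,
    truth: TruthParameters | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> PartiallyNestedDataset:
    """Draw one partially nested dataset under the truth model.

    ``truth.rho`` is overridden by ``condition.rho`` so that a single
    :class:`TruthParameters` instance can serve a whole grid.  The same
    ``(condition, truth, seed)`` triple always yields a bit-identical
    dataset.
    """
    if truth is None:
        truth = TruthParameters(rho=condition.rho)
    elif truth.rho != condition.rho:
        truth = dataclasses.replace(truth, rho=condition.rho)

    sigma2_u, sigma2_eu = derive_variance_components(
        condition.rho, truth.total_treatment_var
    )
    rng = np.random.default_rng(seed)
    n_ctrl, c, m = condition.n_control, condition.c, condition.m

    y_control = truth.b0 + np.sqrt(truth.sigma2_eC) * rng.standard_normal(n_ctrl)
    u = np.sqrt(sigma2_u) * rng.standard_normal(c)
    e_treat = np.sqrt(sigma2_eu) * rng.standard_normal(c * m)
    y_treat = truth.b0 + truth.b1 + np.repeat(u, m) + e_treat

    y = np.concatenate([y_control, y_treat])
    x = np.concatenate([np.zeros(n_ctrl, dtype=int), np.ones(c * m, dtype=int)])
    group = np.concatenate(
        [np.full(n_ctrl, NO_CLUSTER), np.repeat(np.arange(1, c + 1), m)]
    )
    return PartiallyNestedDataset(y=y, x=x, group=group, true_group_effects=u)


def empirical_icc(dataset: PartiallyNestedDataset) -> float:
    """One-way ANOVA moment estimator of the treatment-arm intraclass
    correlation, ``(MSB - MSW) / (MSB + (m - 1) * MSW)``.

    Requires at least two equal-sized clusters of at least two subjects.
    May be negative; returns 1.0 in the degenerate case of zero
    within-cluster variance.
    """
    labels = dataset.group[dataset.x == 1]
    y = dataset.y[dataset.x == 1]
    uniq = np.unique(labels)
    c = len(uniq)
    if c < 2:
        raise ValueError("need at least 2 clusters to estimate an ICC")
    sizes = np.array([np.sum(labels == g) for g in uniq])
    if np.any(sizes < 2) or len(set(sizes)) != 1:
        raise ValueError("clusters must be equal-sized with >= 2 members")
    m = int(sizes[0])

    means = np.array([y[labels == g].mean() for g in uniq])
    grand = y.mean()
    msb = m * np.sum((means - grand) ** 2) / (c - 1)
    msw = sum(np.sum((y[labels == g] - mu) ** 2) for g, mu in zip(uniq, means)) / (
        c * (m - 1)
    )
    if msw == 0.0:
        return 1.0
    return float((msb - msw) / (msb + (m - 1) * msw))


def write_dataset_csv(dataset: PartiallyNestedDataset, path) -> None:
    """Write a dataset as headered CSV (subject_id, arm, cluster, y)."""
    dataset.to_frame().to_csv(path, index=False)


def read_dataset_csv(path) -> PartiallyNestedDataset:
    """Read a dataset written by :func:`write_dataset_csv`.

    The realised cluster effects are not stored on disk, so
    ``true_group_effects`` is ``None`` on the returned object.
    """
    frame = pd.read_csv(path)
    required = {"arm", "cluster", "y"}
    if not required <= set(frame.columns):
        raise ValueError(f"dataset CSV must contain columns {sorted(required)}")
    cluster = frame["cluster"].fillna(NO_CLUSTER).astype(int).to_numpy()
    return PartiallyNestedDataset(
        y=frame["y"].to_numpy(dtype=float),
        x=frame["arm"].to_numpy(dtype=int),
        group=cluster,
    )
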