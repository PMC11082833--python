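"""Cross-region grouping of HMM states and PTR-cluster identification.

Univariate HMMs are inferred per region, so state order is arbitrary
between regions.  States are matched across the brain by k-means on their
binary on/off timecourses: each (region, state) row is a point in
T-dimensional space, and rows with similar temporal dynamics (high
functional connectivity) cluster together.  For 78 regions and 3 states
this is a 234-row matrix.

The post-task-response (PTR) cluster is then identified from trial-averaged
state probability evolutions: the cluster whose average evolution is most
elevated in the post-task window relative to a late-rest baseline.  The
visual criterion used on real data is operationalised here as that
window-contrast maximum.

``noise_sweep`` reconstructs the clustering robustness simulation: three
group templates replicated into 78 rows each, corrupted by replacing a
fraction of samples with fair coin flips, swept from 0 to 90% noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .preprocess import epoch_blocks
from .synthetic import BlockDesign

__all__ = [
    "StateTimecourseMatrix",
    "ClusterResult",
    "ProbabilityEvolution",
    "PtrWindow",
    "build_state_matrix",
    "kmeans_binary",
    "probability_evolution",
    "cluster_evolutions",
    "identify_ptr_cluster",
    "hungarian_agreement",
    "make_templates",
    "corrupt_rows",
    "noise_sweep",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PtrWindow:
    """Post-task window in seconds after task cessation."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("PtrWindow end must exceed start")


@dataclass
class StateTimecourseMatrix:
    """Binary state timecourses stacked across regions.

    ``rows`` lists the (region_name, state_index) identity of each row of
    ``matrix`` (n_rows x T, entries in {0, 1}).
    """

    rows: list[tuple[str, int]]
    matrix: np.ndarray

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]


def build_state_matrix(onoff_by_region: dict[str, np.ndarray]) -> StateTimecourseMatrix:
    """Stack per-region (K x T) binary matrices into one (regions*K x T)."""
    rows: list[tuple[str, int]] = []
    mats = []
    for region, onoff in onoff_by_region.items():
        for state in range(onoff.shape[0]):
            rows.append((region, state))
        mats.append(onoff)
    matrix = np.concatenate(mats, axis=0).astype(np.uint8)
    logger.info("%d state timecourses entering clustering", matrix.shape[0])
    return StateTimecourseMatrix(rows=rows, matrix=matrix)


@dataclass
class ClusterResult:
    k: int
    labels: np.ndarray
    centroids: np.ndarray
    distances: np.ndarray
    inertia: float

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def kmeans_binary(
    stm: StateTimecourseMatrix, k: int = 3, seed: int = 0, n_init: int = 10
) -> ClusterResult:
    """Lloyd k-means on binary rows; best of ``n_init`` by inertia.

    Minimises the within-cluster sum of squared Euclidean distances; the
    per-row distance to its own centroid is returned as a cluster-quality
    measure (lower = more representative of the cluster centroid).
    """
    if k > stm.n_rows:
        raise ValueError("k must not exceed the number of state timecourses")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=int(seed), algorithm="lloyd")
    X = stm.matrix.astype(float)
    labels = km.fit_predict(X)
    dists = np.linalg.norm(X - km.cluster_centers_[labels], axis=1)
    return ClusterResult(
        k=k,
        labels=labels,
        centroids=km.cluster_centers_,
        distances=dists,
        inertia=float(km.inertia_),
    )


@dataclass
class ProbabilityEvolution:
    """Trial-averaged state probability over one block per (region, state)."""

    rows: list[tuple[str, int]]
    evolutions: np.ndarray
    fs: float
    design: BlockDesign

    @property
    def block_samples(self) -> int:
        return self.evolutions.shape[1]


def probability_evolution(
    gamma_by_region: dict[str, np.ndarray],
    design: BlockDesign,
    fs: float,
) -> ProbabilityEvolution:
    """Epoch each state's probability timecourse by block and average."""
    rows: list[tuple[str, int]] = []
    evo = []
    for region, gamma in gamma_by_region.items():
        for state in range(gamma.shape[0]):
            rows.append((region, state))
            evo.append(epoch_blocks(gamma[state], design, fs).mean(axis=0))
    return ProbabilityEvolution(
        rows=rows, evolutions=np.stack(evo), fs=fs, design=design
    )


def cluster_evolutions(
    evolution: ProbabilityEvolution, labels: np.ndarray, k: int
) -> np.ndarray:
    """Average the member evolutions of each cluster -> (k, block_samples)."""
    out = np.zeros((k, evolution.block_samples))
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            raise ValueError(f"cluster {c} has no members")
        out[c] = evolution.evolutions[members].mean(axis=0)
    return out


def _window_slice(design: BlockDesign, fs: float, start: float, end: float) -> slice:
    """Samples of a block covering [start, end) seconds after task cessation."""
    cess = design.instruction_dur + design.task_dur
    return slice(int(round((cess + start) * fs)), int(round((cess + end) * fs)))


def identify_ptr_cluster(
    cluster_evo: np.ndarray,
    design: BlockDesign,
    fs: float,
    ptr: PtrWindow | None = None,
    baseline: tuple[float, float] | None = None,
) -> int:
    """Pick the cluster whose evolution is most elevated post-task.

    The contrast is (mean probability in the PTR window) minus (mean in the
    baseline window, default the final 10 s of rest).  A tie within 1e-9
    between the top two clusters raises, demanding manual selection.
    """
    if ptr is None:
        ptr = PtrWindow(*design.ptr_window)
    if baseline is None:
        b0 = max(design.rest_dur - 10.0, ptr.end)
        baseline = (b0, design.rest_dur)
    ptr_sl = _window_slice(design, fs, ptr.start, ptr.end)
    base_sl = _window_slice(design, fs, *baseline)
    contrasts = cluster_evo[:, ptr_sl].mean(axis=1) - cluster_evo[:, base_sl].mean(axis=1)
    order = np.argsort(contrasts)[::-1]
    if contrasts[order[0]] - contrasts[order[1]] < 1e-9:
        raise ValueError(
            "PTR cluster ambiguous (tied contrasts); select manually"
        )
    return int(order[0])


# ---------------------------------------------------------------------------
# Clustering robustness simulation


def hungarian_agreement(labels_true: np.ndarray, labels_pred: np.ndarray, k: int) -> float:
    """Label agreement after optimal (Hungarian) cluster-to-group matching."""
    confusion = np.zeros((k, k))
    for t, p in zip(labels_true, labels_pred):
        confusion[t, p] += 1
    rows, cols = linear_sum_assignment(-confusion)
    return float(confusion[rows, cols].sum() / len(labels_true))


def make_templates(n_timepoints: int, k: int = 3) -> np.ndarray:
    """Three mutually exclusive binary activity patterns.

    Template g is "on" during its own third of each cycle of ``3*k``
    samples, emulating states that are active in different phases of a
    block design.
    """
    t = np.arange(n_timepoints)
    cycle = 3 * k
    templates = np.zeros((k, n_timepoints), dtype=np.uint8)
    for g in range(k):
        phase = (t % cycle) // 3
        templates[g] = (phase == g).astype(np.uint8)
    return templates


def corrupt_rows(
    templates: np.ndarray,
    rows_per_group: int,
    noise: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Replicate templates into groups and replace a fraction ``noise`` of
    each row's samples with fair coin flips."""
    k, T = templates.shape
    X = np.repeat(templates, rows_per_group, axis=0).astype(np.uint8)
    labels = np.repeat(np.arange(k), rows_per_group)
    flip = rng.random(X.shape) < noise
    coins = rng.integers(0, 2, size=X.shape, dtype=np.uint8)
    X = np.where(flip, coins, X)
    return X, labels


def noise_sweep(
    levels: np.ndarray | list[float] | None = None,
    n_seeds: int = 20,
    n_timepoints: int = 21,
    rows_per_group: int = 78,
    k: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Median Hungarian-matched label agreement at each noise level.

    Defaults reconstruct the qualitative robustness result: grouping is
    essentially perfect at low noise and collapses towards chance (1/k)
    once most samples are replaced by coin flips.  Returns a dataframe with
    columns ``noise`` and ``median_agreement`` (plus per-seed columns).
    """
    if levels is None:
        levels = np.round(np.arange(0.0, 0.91, 0.1), 2)
    templates = make_templates(n_timepoints, k)
    records = []
    for level in levels:
        agreements = []
        for s in range(n_seeds):
            rng = np.random.default_rng([int(seed), int(round(level * 100)), s])
            X, labels_true = corrupt_rows(templates, rows_per_group, float(level), rng)
            stm = StateTimecourseMatrix(
                rows=[("sim", i) for i in range(X.shape[0])], matrix=X
            )
            res = kmeans_binary(stm, k=k, seed=int(rng.integers(2**31)))
            agreements.append(hungarian_agreement(labels_true, res.labels, k))
        records.append(
            {"noise": float(level), "median_agreement": float(np.median(agreements)),
             "agreements": agreements}
        )
    return pd.DataFrame(records)


def breakdown_level(sweep: pd.DataFrame, chance_band: float = 0.55) -> float:
    """Lowest noise level at which the median agreement falls below
    ``chance_band``; NaN if it never does."""
    below = sweep[sweep["median_agreement"] < chance_band]
    return float(below["noise"].iloc[0]) if len(below) else float("nan")
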