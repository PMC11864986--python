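"""3D spatial organization of transcriptomic types in the cell-body layer.

The substrate is a labelled point cloud of cell centroids (µm). For every
ordered pair of t-types (a, b), the mean nearest-neighbour distance (NND)
from type-a cells to type-b cells is computed in 3D; hierarchical
clustering of each type's NND profile then groups types into anatomical
layers (superficial / intermediate / deep in the tectum). A
label-permutation null quantifies how much layer structure survives when
type labels are decoupled from position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform


@dataclass
class LabeledPointCloud:
    """3D cell centroids with a categorical type label per point."""

    coords: np.ndarray  # n x 3, µm
    labels: np.ndarray  # n, categorical
    specimen: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be n x 3")
        if len(self.labels) != len(self.coords):
            raise ValueError("one label per point required")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.specimen is None:
            self.specimen = np.zeros(len(self.coords), dtype=int)
        else:
            self.specimen = np.asarray(self.specimen)

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def types(self) -> np.ndarray:
        return np.unique(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_um": self.coords[:, 0],
                "y_um": self.coords[:, 1],
                "z_um": self.coords[:, 2],
                "type": self.labels,
                "specimen": self.specimen,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LabeledPointCloud":
        df = pd.read_csv(path)
        return cls(
            coords=df[["x_um", "y_um", "z_um"]].to_numpy(),
            labels=df["type"].to_numpy(),
            specimen=df["specimen"].to_numpy() if "specimen" in df else None,
        )


@dataclass
class NNDMatrix:
    """Mean 3D nearest-neighbour distances between t-types.

    ``mean_nnd[a, b]`` is the mean, over cells of type ``a``, of the
    distance to the nearest cell of type ``b`` (excluding the cell itself
    on the diagonal). Generally asymmetric.
    """

    mean_nnd: np.ndarray  # t x t, µm
    types: np.ndarray
    counts: np.ndarray  # t, points per type

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.mean_nnd, index=self.types, columns=self.types)


def compute_nnd_matrix(cloud: LabeledPointCloud) -> NNDMatrix:
    """Exact mean NND between every ordered pair of types (KD-tree search)."""
    types = cloud.types
    groups = {t: cloud.coords[cloud.labels == t] for t in types}
    for t, pts in groups.items():
        if len(pts) == 0:
            raise ValueError(f"type {t!r} has no points")
    trees = {t: cKDTree(pts) for t, pts in groups.items()}

    n = len(types)
    mat = np.full((n, n), np.nan)
    counts = np.array([len(groups[t]) for t in types])
    for i, a in enumerate(types):
        pts_a = groups[a]
        for j, b in enumerate(types):
            if i == j:
                if len(pts_a) < 2:
                    continue  # diagonal flagged absent (NaN)
                d, _ = trees[b].query(pts_a, k=2)
                mat[i, j] = d[:, 1].mean()
            else:
                d, _ = trees[b].query(pts_a, k=1)
                mat[i, j] = d.mean()
    return NNDMatrix(mean_nnd=mat, types=types, counts=counts)


def cluster_layers(nnd: NNDMatrix, n_layers: int = 3):
    """Group t-types into anatomical layers from their NND profiles.

    Each type's row of the mean-NND matrix is one observation; rows are
    agglomerated with complete linkage on Euclidean distance and the
    dendrogram is cut into exactly ``n_layers`` flat clusters.

    Returns ``(labels, Z)``: a 1..n_layers label per type (aligned with
    ``nnd.types``) and the scipy linkage matrix.
    """
    rows = np.nan_to_num(nnd.mean_nnd, nan=0.0)
    n_types = rows.shape[0]
    if n_layers > n_types:
        raise ValueError(f"n_layers={n_layers} exceeds {n_types} t-types")
    if n_types == 1:
        return np.array([1]), np.empty((0, 4))
    Z = linkage(rows, method="complete", metric="euclidean")
    labels = fcluster(Z, t=n_layers, criterion="maxclust")
    return labels, Z


def layering_statistic(nnd: NNDMatrix, n_layers: int = 3) -> float:
    """Between- vs within-layer separation of NND profiles.

    Ratio of the mean pairwise (Euclidean) distance between rows in
    different layers to the mean pairwise distance between rows in the
    same layer, at the ``n_layers`` dendrogram cut. Large values mean
    crisp layering; returns ``inf`` when every layer is a singleton.
    """
    labels, _ = cluster_layers(nnd, n_layers)
    rows = np.nan_to_num(nnd.mean_nnd, nan=0.0)
    dist = squareform(pdist(rows))
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), k=1)
    within = dist[iu][same[iu]]
    between = dist[iu][~same[iu]]
    if between.size == 0:
        return 0.0
    if within.size == 0 or within.mean() == 0:
        return np.inf
    return float(between.mean() / within.mean())


@dataclass
class PermutationTestResult:
    observed: float
    null: np.ndarray
    p_value: float


def layering_null(
    cloud: LabeledPointCloud,
    n_layers: int = 3,
    n_perm: int = 100,
    seed: int | None = None,
) -> PermutationTestResult:
    """Label-permutation null for the layering statistic.

    Type labels are permuted over fixed coordinates ``n_perm`` times; the
    permutation p-value is ``(1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = layering_statistic(compute_nnd_matrix(cloud), n_layers)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(cloud.labels)
        shuffled = LabeledPointCloud(cloud.coords, perm, cloud.specimen)
        null[i] = layering_statistic(compute_nnd_matrix(shuffled), n_layers)
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return PermutationTestResult(observed=observed, null=null, p_value=p)


def _sma(x: np.ndarray, window: int) -> np.ndarray:
    """Centered simple moving average with truncated edges."""
    half = window // 2
    out = np.empty_like(x, dtype=float)
    for i in range(len(x)):
        lo = max(0, i - half)
        hi = min(len(x), i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def intensity_profile(
    stacks: list[np.ndarray],
    roi_box: tuple[slice, slice, slice],
    axis: int = 0,
    project_axis: int | None = None,
    window: int = 3,
) -> pd.DataFrame:
    """Z-scored marker intensity profile along one anatomical axis.

    Each specimen's image stack is cropped to ``roi_box``, max-intensity
    projected along ``project_axis`` (the thin slab dimension; default: the
    last axis that is neither ``axis`` nor the profile axis), averaged over
    the remaining in-plane dimension, z-scored within specimen, and
    smoothed with a centered simple moving average (edges truncated).
    Returns mean and s.e.m. across specimens per position.
    """
    if not stacks:
        raise ValueError("at least one specimen stack required")
    profiles = []
    for stack in stacks:
        sub = np.asarray(stack, dtype=float)[roi_box]
        if sub.size == 0:
            raise ValueError("roi_box selects an empty region")
        proj_ax = project_axis
        if proj_ax is None:
            proj_ax = [a for a in range(3) if a != axis][-1]
        proj = sub.max(axis=proj_ax)
        # profile axis position within the projected array
        prof_ax = axis if axis < proj_ax else axis - 1
        other_ax = 1 - prof_ax
        prof = proj.mean(axis=other_ax)
        sd = prof.std()
        if sd == 0:
            raise ValueError("constant intensity in roi_box: z-score undefined")
        z = (prof - prof.mean()) / sd
        profiles.append(_sma(z, window))
    arr = np.vstack(profiles)
    mean = arr.mean(axis=0)
    sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 else np.zeros_like(mean)
    return pd.DataFrame({"position": np.arange(arr.shape[1]), "mean": mean, "sem": sem})
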