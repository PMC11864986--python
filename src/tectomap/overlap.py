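"""Anatomical separation of t/f-clusters via a KDE overlap statistic.

Recorded neurons sharing one t-type and one f-type form a t/f-cluster.
For two clusters, a Gaussian kernel density estimate (scalar bandwidth
factor 0.75 in the covariance-scaling convention of
``scipy.stats.gaussian_kde``) is fitted to each 3D point cloud, both are
sampled on a shared grid, normalized to sum 1, and the overlap is the sum
of the pointwise minimum — 0 for disjoint clouds, ~1 for identical ones.

Anatomical separation is tested against a label-shuffle null: t-type
labels of all ROIs are permuted globally, t/f-clusters are re-formed, and
within-group pairwise overlaps are compared with the real ones by
two-sided Mann–Whitney U tests, Bonferroni-corrected over the tested
groups plus one overall test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TFCluster:
    """ROIs sharing one t-type and one f-type, with their 3D coordinates."""

    t_label: object
    f_label: object
    coords: np.ndarray  # m x 3, µm

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)

    @property
    def size(self) -> int:
        return len(self.coords)


def mirror_hemisphere(
    coords: np.ndarray, midline: float, axis: int = 1
) -> np.ndarray:
    """Reflect points on the far side of ``midline`` onto the near side.

    Used to pool both tectal hemispheres onto the left one before
    clustering; synthetic data are generated one-sided and unaffected.
    """
    out = np.array(coords, dtype=float)
    far = out[:, axis] > midline
    out[far, axis] = 2 * midline - out[far, axis]
    return out


def form_tf_clusters(
    coords: np.ndarray,
    t_labels: np.ndarray,
    f_labels: np.ndarray,
    min_size: int = 10,
) -> list[TFCluster]:
    """One cluster per (t, f) label pair with more than ``min_size`` members."""
    coords = np.asarray(coords, dtype=float)
    t_labels = np.asarray(t_labels)
    f_labels = np.asarray(f_labels)
    clusters = []
    for t in np.unique(t_labels):
        for f in np.unique(f_labels):
            sel = (t_labels == t) & (f_labels == f)
            if sel.sum() > min_size:
                clusters.append(TFCluster(t_label=t, f_label=f, coords=coords[sel]))
    return clusters


def _grid_for(
    clouds: list[np.ndarray],
    bandwidth: float,
    grid_size: int,
    pad_bandwidths: float,
) -> list[np.ndarray]:
    """Shared evaluation grid covering all clouds, padded by the bandwidth."""
    allpts = np.vstack(clouds)
    # effective per-dimension bandwidth of the covariance-scaled estimator
    eff = bandwidth * max(float(np.std(c, axis=0).max()) for c in clouds)
    lo = allpts.min(axis=0) - pad_bandwidths * eff
    hi = allpts.max(axis=0) + pad_bandwidths * eff
    return [np.linspace(lo[d], hi[d], grid_size) for d in range(allpts.shape[1])]


def kde_overlap(
    a: np.ndarray | TFCluster,
    b: np.ndarray | TFCluster,
    bandwidth: float = 0.75,
    grid_size: int = 50,
    pad_bandwidths: float = 3.0,
) -> float:
    """Sampled-minimum overlap of two Gaussian KDEs on a shared 3D grid.

    Each density is evaluated on the same ``grid_size``³ grid covering both
    clouds' padded bounding box, normalized to sum 1, and the overlap is
    ``Σ min(p, q)`` — symmetric by construction and bounded in [0, 1].
    """
    pa = a.coords if isinstance(a, TFCluster) else np.asarray(a, dtype=float)
    pb = b.coords if isinstance(b, TFCluster) else np.asarray(b, dtype=float)
    for name, pts in (("a", pa), ("b", pb)):
        if np.allclose(pts.std(axis=0), 0):
            raise ValueError(f"cluster {name} is degenerate (singular covariance)")
    try:
        kde_a = stats.gaussian_kde(pa.T, bw_method=bandwidth)
        kde_b = stats.gaussian_kde(pb.T, bw_method=bandwidth)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"degenerate cluster: {err}") from err

    axes = _grid_for([pa, pb], bandwidth, grid_size, pad_bandwidths)
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.vstack([m.ravel() for m in mesh])
    da = kde_a(pts)
    db = kde_b(pts)
    da /= da.sum()
    db /= db.sum()
    return float(min(1.0, np.minimum(da, db).sum()))


def overlap_matrix(
    clusters: list[TFCluster],
    bandwidth: float = 0.75,
    grid_size: int = 50,
) -> pd.DataFrame:
    """Pairwise overlap between all t/f-clusters (diagonal ~1)."""
    n = len(clusters)
    mat = np.ones((n, n))
    for i, j in combinations(range(n), 2):
        mat[i, j] = mat[j, i] = kde_overlap(
            clusters[i], clusters[j], bandwidth=bandwidth, grid_size=grid_size
        )
    names = [f"{c.t_label}|{c.f_label}" for c in clusters]
    return pd.DataFrame(mat, index=names, columns=names)


def _within_group_overlaps(
    clusters: list[TFCluster],
    grouping: str,
    bandwidth: float,
    grid_size: int,
) -> dict[object, list[float]]:
    """Pairwise overlaps between subclusters sharing one t-type (or f-type)."""
    key = (lambda c: c.t_label) if grouping == "within-t-type" else (lambda c: c.f_label)
    groups: dict[object, list[TFCluster]] = {}
    for c in clusters:
        groups.setdefault(key(c), []).append(c)
    out: dict[object, list[float]] = {}
    for g, members in sorted(groups.items(), key=lambda kv: str(kv[0])):
        if len(members) < 2:
            continue
        out[g] = [
            kde_overlap(a, b, bandwidth=bandwidth, grid_size=grid_size)
            for a, b in combinations(members, 2)
        ]
    return out


@dataclass
class OverlapSeparationResult:
    grouping: str
    real_overlaps: dict[object, list[float]]
    null_overlaps: dict[object, list[float]]
    table: pd.DataFrame  # group, n_real, n_null, median_real, median_null, U, p, p_bonf
    overall_p: float
    overall_p_bonferroni: float


def overlap_separation_test(
    coords: np.ndarray,
    t_labels: np.ndarray,
    f_labels: np.ndarray,
    grouping: str = "within-t-type",
    min_size: int = 10,
    bandwidth: float = 0.75,
    grid_size: int = 50,
    n_shuffles: int = 100,
    seed: int | None = None,
) -> OverlapSeparationResult:
    """Test anatomical separation of t/f-subclusters against a shuffle null.

    Real statistic: within each group (each t-type for ``within-t-type``,
    each f-type for ``within-f-type``), pairwise KDE overlaps between its
    subclusters. Null: t-type labels of all ROIs are permuted globally,
    clusters are re-formed, and the same within-group overlaps computed,
    ``n_shuffles`` times. Per-group and overall two-sided Mann–Whitney U
    tests compare real vs null; Bonferroni correction over (groups + 1).
    """
    if grouping not in ("within-t-type", "within-f-type"):
        raise ValueError("grouping must be 'within-t-type' or 'within-f-type'")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1 (no null otherwise)")
    rng = np.random.default_rng(seed)
    t_labels = np.asarray(t_labels)
    f_labels = np.asarray(f_labels)

    clusters = form_tf_clusters(coords, t_labels, f_labels, min_size=min_size)
    real = _within_group_overlaps(clusters, grouping, bandwidth, grid_size)
    if not real:
        warnings.warn("no group has >= 2 surviving subclusters; nothing to test")

    null: dict[object, list[float]] = {g: [] for g in real}
    for _ in range(n_shuffles):
        perm_t = rng.permutation(t_labels)
        shuf_clusters = form_tf_clusters(coords, perm_t, f_labels, min_size=min_size)
        shuf = _within_group_overlaps(shuf_clusters, grouping, bandwidth, grid_size)
        for g, vals in shuf.items():
            null.setdefault(g, []).extend(vals)

    n_tests = len(real) + 1
    rows = []
    for g, vals in real.items():
        nv = null.get(g, [])
        if len(nv) == 0 or len(vals) == 0:
            warnings.warn(f"group {g!r}: no null or no real overlaps; skipped")
            continue
        u, p = stats.mannwhitneyu(vals, nv, alternative="two-sided")
        rows.append(
            (g, len(vals), len(nv), float(np.median(vals)), float(np.median(nv)),
             float(u), float(p), float(min(1.0, p * n_tests)))
        )
    table = pd.DataFrame(
        rows,
        columns=["group", "n_real", "n_null", "median_real", "median_null",
                 "U", "p", "p_bonferroni"],
    )
    all_real = [v for vals in real.values() for v in vals]
    all_null = [v for g in real for v in null.get(g, [])]
    if all_real and all_null:
        _, overall_p = stats.mannwhitneyu(all_real, all_null, alternative="two-sided")
    else:
        overall_p = np.nan
    return OverlapSeparationResult(
        grouping=grouping,
        real_overlaps=real,
        null_overlaps=null,
        table=table,
        overall_p=float(overall_p),
        overall_p_bonferroni=float(min(1.0, overall_p * n_tests))
        if np.isfinite(overall_p)
        else np.nan,
    )
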