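"""Functional cell types from scaled response-score vectors.

F-types are derived in two steps, operating on 8-dimensional scaled
response vectors of strongly responding ROIs:

1. **Exemplars** — affinity propagation (similarity = negative squared
   Euclidean distance, preference = median similarity, damping 0.5)
   selects exemplar ROIs; exemplars with fewer than ``min_members``
   associated ROIs are pruned.
2. **F-types** — surviving exemplars are agglomerated with complete
   linkage on correlation distance (1 − Pearson r between exemplar
   vectors) and the dendrogram is cut into exactly ``k`` flat clusters;
   member ROIs inherit their exemplar's label.

Labelled ROIs recorded separately are mapped into the same typology by
nearest retained exemplar. Superclusters are a coarser (k=5 by default)
cut of the same exemplar dendrogram, so downstream statistics never
depend on a stochastic 2-D embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import AffinityPropagation


@dataclass
class ExemplarSet:
    vectors: np.ndarray        # n x 8 input vectors
    exemplar_indices: np.ndarray  # indices into `vectors` of the exemplars
    member_of: np.ndarray      # per input ROI, position in exemplar_indices

    @property
    def exemplar_vectors(self) -> np.ndarray:
        return self.vectors[self.exemplar_indices]

    @property
    def member_counts(self) -> np.ndarray:
        return np.bincount(self.member_of, minlength=len(self.exemplar_indices))

    @property
    def n_exemplars(self) -> int:
        return len(self.exemplar_indices)


@dataclass
class FTypeAssignment:
    """F-type labels (1..k) for retained exemplars and their member ROIs."""

    exemplar_indices: np.ndarray   # retained exemplars (indices into vectors)
    exemplar_ftype: np.ndarray     # f-type (1..k) per retained exemplar
    roi_ftype: np.ndarray          # per input ROI; 0 = unlabelled (pruned)
    roi_supercluster: np.ndarray   # coarser cut; 0 = unlabelled
    k: int
    linkage_matrix: np.ndarray


def find_exemplars(
    scaled_scores: np.ndarray,
    damping: float = 0.7,
    max_iter: int = 1000,
    convergence_iter: int = 50,
    random_state: int = 0,
) -> ExemplarSet:
    """Affinity-propagation exemplars of scaled response vectors.

    Similarity is the negative squared Euclidean distance with the median
    similarity as preference. The defaults deviate from the reference
    implementation (damping 0.5, convergence window 15): at damping 0.5
    message passing oscillates indefinitely on data with tight archetype
    blobs, while very high damping can freeze the labels before the
    messages settle, collapsing everything onto one exemplar. Damping 0.7
    with a 50-iteration stability window converges to the same fixed point
    the undamped updates orbit around.
    """
    X = np.asarray(scaled_scores, dtype=float)
    if X.ndim != 2:
        raise ValueError("scaled_scores must be 2-D")
    if not np.all(np.isfinite(X)):
        raise ValueError("scaled_scores must be finite")
    if len(X) == 1:
        return ExemplarSet(
            vectors=X, exemplar_indices=np.array([0]), member_of=np.array([0])
        )
    ap = AffinityPropagation(
        damping=damping,
        max_iter=max_iter,
        convergence_iter=convergence_iter,
        random_state=random_state,
    )
    labels = ap.fit_predict(X)
    if ap.cluster_centers_indices_ is None or len(ap.cluster_centers_indices_) == 0 or (
        ap.n_iter_ >= max_iter
    ):
        raise RuntimeError(
            f"affinity propagation did not converge after {ap.n_iter_} iterations"
        )
    return ExemplarSet(
        vectors=X,
        exemplar_indices=np.asarray(ap.cluster_centers_indices_),
        member_of=labels,
    )


def cluster_exemplars(
    exemplars: ExemplarSet,
    k: int,
    min_members: int = 10,
    supercluster_k: int = 5,
) -> FTypeAssignment:
    """Prune small exemplars, then cut a complete-linkage dendrogram at k.

    Exemplars with fewer than ``min_members`` member ROIs are excluded;
    their ROIs stay unlabelled (f-type 0). The retained exemplar vectors
    are clustered on correlation distance with complete linkage and cut
    into exactly ``k`` flat f-types (and ``supercluster_k`` superclusters
    from the same dendrogram).
    """
    counts = exemplars.member_counts
    keep = np.flatnonzero(counts >= min_members)
    if len(keep) < k:
        raise ValueError(
            f"k={k} exceeds the {len(keep)} exemplars surviving "
            f"min_members={min_members}"
        )
    vecs = exemplars.exemplar_vectors[keep]
    if len(keep) == 1:
        Z = np.empty((0, 4))
        ftype = np.array([1])
        superc = np.array([1])
    else:
        Z = linkage(vecs, method="complete", metric="correlation")
        ftype = fcluster(Z, t=k, criterion="maxclust")
        superc = fcluster(Z, t=min(supercluster_k, len(keep)), criterion="maxclust")

    # map every input ROI through its exemplar
    ex_to_ftype = np.zeros(exemplars.n_exemplars, dtype=int)
    ex_to_super = np.zeros(exemplars.n_exemplars, dtype=int)
    ex_to_ftype[keep] = ftype
    ex_to_super[keep] = superc
    return FTypeAssignment(
        exemplar_indices=exemplars.exemplar_indices[keep],
        exemplar_ftype=ftype,
        roi_ftype=ex_to_ftype[exemplars.member_of],
        roi_supercluster=ex_to_super[exemplars.member_of],
        k=k,
        linkage_matrix=Z,
    )


def assign_ftypes(
    new_vectors: np.ndarray,
    exemplars: ExemplarSet,
    assignment: FTypeAssignment,
) -> np.ndarray:
    """F-type of each new ROI = f-type of its nearest retained exemplar.

    Uses the same similarity as exemplar finding (negative squared
    Euclidean distance); exact ties go to the lowest exemplar index.
    """
    if len(assignment.exemplar_indices) == 0:
        raise ValueError("no retained exemplars to assign against")
    X = np.atleast_2d(np.asarray(new_vectors, dtype=float))
    E = exemplars.vectors[assignment.exemplar_indices]
    d2 = ((X[:, None, :] - E[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)  # argmin takes the first (lowest index) on ties
    return assignment.exemplar_ftype[nearest]


def ftype_table(
    roi_ids: np.ndarray, exemplars: ExemplarSet, assignment: FTypeAssignment
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "roi_id": roi_ids,
            "exemplar_id": exemplars.exemplar_indices[exemplars.member_of],
            "f_type": assignment.roi_ftype,
            "supercluster": assignment.roi_supercluster,
        }
    )


def embed_scores(
    scaled_scores: np.ndarray,
    n_neighbors: int = 25,
    min_dist: float = 0.7,
    random_state: int | None = 0,
):
    """2-D UMAP embedding of response vectors (visualization only).

    Returns ``(coords, reducer)``; new points can be mapped with
    ``reducer.transform``. Never used for statistics.
    """
    import umap  # deferred: slow import, plotting-only dependency

    X = np.asarray(scaled_scores, dtype=float)
    reducer = umap.UMAP(
        n_neighbors=min(n_neighbors, len(X) - 1),
        min_dist=min_dist,
        metric="euclidean",
        random_state=random_state,
    )
    coords = reducer.fit_transform(X)
    return coords, reducer
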