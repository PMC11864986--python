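"""Matching annotated cell centroids to functional ROI pixel masks.

Centroids (e.g. HCR-labelled nuclei) and functional ROIs are assumed to be
co-registered into one reference frame (integer pixel grid with a plane
index). Each centroid seeds a 3x3 in-plane pixel neighbourhood; the
centroid is assigned to the ROI with the largest fractional overlap
(shared pixels / neighbourhood size), or left unassigned if no ROI touches
the neighbourhood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class RoiMaskSet:
    """Per-ROI pixel coordinate sets in a common reference frame.

    ``masks`` maps ROI id -> integer array of shape (m, 3) with columns
    (plane, row, col). ``shape`` is the frame extent in the same order.
    """

    masks: dict[int, np.ndarray]
    shape: tuple[int, int, int]
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        for roi_id, px in self.masks.items():
            px = np.asarray(px, dtype=int)
            if px.ndim != 2 or px.shape[1] != 3 or len(px) == 0:
                raise ValueError(f"ROI {roi_id}: mask must be a non-empty (m, 3) array")
            if (px < 0).any() or (px >= np.asarray(self.shape)).any():
                raise ValueError(f"ROI {roi_id}: mask pixels outside frame bounds")
            self.masks[roi_id] = px

    def centroid(self, roi_id: int) -> np.ndarray:
        return self.masks[roi_id].mean(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for roi_id, px in sorted(self.masks.items()):
            frames.append(
                pd.DataFrame({"roi_id": roi_id, "plane": px[:, 0], "row": px[:, 1], "col": px[:, 2]})
            )
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, shape=None, pixel_size_um: float = 1.0):
        masks = {
            int(roi_id): g[["plane", "row", "col"]].to_numpy(dtype=int)
            for roi_id, g in df.groupby("roi_id")
        }
        if shape is None:
            all_px = df[["plane", "row", "col"]].to_numpy(dtype=int)
            shape = tuple(all_px.max(axis=0) + 1)
        return cls(masks=masks, shape=shape, pixel_size_um=pixel_size_um)


def _neighborhood_offsets(depth: int) -> np.ndarray:
    """Offsets of the 3x3 (in-plane) or 3x3x3 centroid neighbourhood."""
    r = np.arange(-1, 2)
    if depth == 1:
        planes = np.array([0])
    elif depth == 3:
        planes = r
    else:
        raise ValueError("neighbourhood depth must be 1 or 3")
    return np.array([(p, i, j) for p in planes for i in r for j in r])


def match_centroids_to_rois(
    centroids: pd.DataFrame,
    masks: RoiMaskSet,
    depth: int = 1,
) -> pd.DataFrame:
    """Assign centroids to ROIs by largest fractional pixel overlap.

    ``centroids`` needs columns ``centroid_id, plane, row, col`` (integer
    pixels). Each centroid's 3x3 (or 3x3x3 with ``depth=3``) neighbourhood
    is intersected with every ROI's pixels; the centroid is assigned to the
    argmax of ``|intersection| / neighbourhood size`` if positive. Ties are
    broken by smaller centroid-to-ROI-centroid distance, then by lower ROI
    id. Centroids outside the frame are left unassigned with a warning.

    Returns a table with ``centroid_id, roi_id (nullable), overlap_fraction,
    shared_roi`` where ``shared_roi`` flags ROIs receiving several centroids.
    """
    offsets = _neighborhood_offsets(depth)
    nsize = len(offsets)
    shape = np.asarray(masks.shape)

    pixel_to_rois: dict[tuple[int, int, int], list[int]] = {}
    for roi_id, px in masks.masks.items():
        for p in map(tuple, px):
            pixel_to_rois.setdefault(p, []).append(roi_id)
    roi_centroids = {roi_id: masks.centroid(roi_id) for roi_id in masks.masks}

    records = []
    for rec in centroids.itertuples(index=False):
        pos = np.array([rec.plane, rec.row, rec.col], dtype=int)
        if (pos < 0).any() or (pos >= shape).any():
            warnings.warn(f"centroid {rec.centroid_id} outside frame; unassigned")
            records.append((rec.centroid_id, None, 0.0))
            continue
        counts: dict[int, int] = {}
        for off in offsets:
            key = tuple(pos + off)
            for roi_id in pixel_to_rois.get(key, ()):
                counts[roi_id] = counts.get(roi_id, 0) + 1
        if not counts:
            records.append((rec.centroid_id, None, 0.0))
            continue
        best = max(counts.values())
        tied = [r for r, c in counts.items() if c == best]
        if len(tied) > 1:
            dists = {r: float(np.linalg.norm(roi_centroids[r] - pos)) for r in tied}
            dmin = min(dists.values())
            tied = sorted(r for r in tied if dists[r] == dmin)
        records.append((rec.centroid_id, tied[0], best / nsize))

    out = pd.DataFrame(records, columns=["centroid_id", "roi_id", "overlap_fraction"])
    assigned = out["roi_id"].dropna()
    dup = set(assigned[assigned.duplicated(keep=False)])
    out["shared_roi"] = out["roi_id"].map(lambda r: r in dup if r is not None else False)
    return out
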