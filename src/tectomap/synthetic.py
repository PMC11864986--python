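"""Synthetic layered/mosaic point clouds and stimulus-locked calcium traces.

The generator emulates the structure of the tectal datasets this package
analyses, with planted ground truth throughout:

* **Point clouds** — each t-type occupies one depth slab (layer) along the
  superficial–deep axis (z, µm) and forms a mosaic: same-type cells keep a
  hard-core minimum spacing, realized by dart-throwing with rejection.
  An optional per-type linear density gradient runs along the
  anterior–posterior axis (x).
* **Traces** — each ROI carries one functional archetype; its fluorescence
  is baseline + Σ_s amplitude[archetype, s] · regressor_s(t) + white noise
  + Gaussian random-walk drift.
* **Coupling** — the archetype of an ROI is drawn from
  P(archetype | t-type, anterior–posterior position bin), so transcriptomic,
  positional and functional identity can be coupled with configurable
  strength.

Coordinates are right-handed µm, one (left) hemisphere, z increasing from
superficial to deep. One global seed fans out to per-component child seeds
so stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correspondence import RoiMaskSet
from .layering import LabeledPointCloud
from .scoring import TraceMatrix
from .stimulus import (
    DEFAULT_TAU_S,
    STIM_CLASSES,
    StimulusProtocol,
    build_protocol,
    build_regressors,
)


def default_archetypes(n_archetypes: int, amplitude: float = 1.0) -> np.ndarray:
    """Archetype x stimulus response amplitudes.

    Each archetype responds strongly to one primary stimulus class and
    weakly (40%) to a secondary one, cycling through the eight classes.
    """
    n_stim = len(STIM_CLASSES)
    amps = np.zeros((n_archetypes, n_stim))
    for k in range(n_archetypes):
        amps[k, k % n_stim] = amplitude
        amps[k, (k + 3) % n_stim] = 0.4 * amplitude
    return amps


def coupling_type_only(
    n_types: int, n_pos_bins: int, n_archetypes: int, strength: float = 1.0
) -> np.ndarray:
    """P(archetype | type) = strength * onehot(type % K) + (1-strength)/K."""
    p = np.full((n_types, n_pos_bins, n_archetypes), (1.0 - strength) / n_archetypes)
    for t in range(n_types):
        p[t, :, t % n_archetypes] += strength
    return p


def coupling_position_only(
    n_types: int, n_pos_bins: int, n_archetypes: int, strength: float = 1.0
) -> np.ndarray:
    """P(archetype | position bin), identical for every type."""
    p = np.full((n_types, n_pos_bins, n_archetypes), (1.0 - strength) / n_archetypes)
    for b in range(n_pos_bins):
        p[:, b, b % n_archetypes] += strength
    return p


def coupling_mixed(
    n_types: int,
    n_pos_bins: int,
    n_archetypes: int,
    w_type: float = 0.4,
    w_pos: float = 0.4,
) -> np.ndarray:
    """Convex mixture of type preference, position preference and uniform."""
    if w_type + w_pos > 1 + 1e-12:
        raise ValueError("w_type + w_pos must be <= 1")
    w0 = 1.0 - w_type - w_pos
    p = np.full((n_types, n_pos_bins, n_archetypes), w0 / n_archetypes)
    for t in range(n_types):
        p[t, :, t % n_archetypes] += w_type
    for b in range(n_pos_bins):
        p[:, b, b % n_archetypes] += w_pos
    return p


def coupling_type_position(
    n_types: int,
    n_pos_bins: int,
    n_archetypes: int,
    strength: float = 0.7,
) -> np.ndarray:
    """Type-dependent positional preference (requires n_pos_bins = 2).

    Each t-type prefers archetype ``t % K`` anteriorly and ``(t+1) % K``
    posteriorly with probability ``strength`` (rest uniform), planting
    anatomically segregated functional subclusters *within* each type
    whose preferred archetypes differ across types — the configuration the
    anatomical-overlap shuffle test is designed to detect.
    """
    if n_pos_bins != 2:
        raise ValueError("coupling_type_position requires exactly 2 position bins")
    p = np.full((n_types, n_pos_bins, n_archetypes), (1.0 - strength) / n_archetypes)
    for t in range(n_types):
        p[t, 0, t % n_archetypes] += strength
        p[t, 1, (t + 1) % n_archetypes] += strength
    return p


@dataclass
class SyntheticConfig:
    """Planted structure of a synthetic tectal dataset.

    Depth slabs (``layer_depths``, µm along superficial→deep z) must be
    disjoint; ``layer_assignment`` places each t-type in one slab.
    ``ap_gradient`` tilts each type's density linearly along the
    anterior–posterior axis (slope s in [-2, 2]: density ∝ 1 + s·(x/X − ½)).
    ``coupling`` is P(archetype | type, position bin) with rows summing to 1.
    """

    n_types: int = 6
    layer_assignment: tuple[int, ...] = (0, 0, 1, 1, 2, 2)
    layer_depths: tuple[tuple[float, float], ...] = ((0.0, 20.0), (25.0, 45.0), (50.0, 70.0))
    extent_um: tuple[float, float] = (300.0, 200.0)  # x (anterior–posterior), y
    mosaic_exclusion_radius: float = 6.0
    ap_gradient: tuple[float, ...] | None = None
    n_cells_per_type: int = 100
    n_archetypes: int = 5
    f_archetypes: np.ndarray | None = None
    coupling: np.ndarray | None = None
    n_pos_bins: int = 2
    baseline: float = 1.0
    noise_sd: float = 0.2
    drift_sd: float = 0.0
    frame_rate: float = 5.0
    tau: float = DEFAULT_TAU_S
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ap_gradient is None:
            self.ap_gradient = tuple(0.0 for _ in range(self.n_types))
        if self.f_archetypes is None:
            self.f_archetypes = default_archetypes(self.n_archetypes)
        self.f_archetypes = np.asarray(self.f_archetypes, dtype=float)
        self.n_archetypes = self.f_archetypes.shape[0]
        if self.coupling is None:
            self.coupling = coupling_mixed(self.n_types, self.n_pos_bins, self.n_archetypes)
        self.coupling = np.asarray(self.coupling, dtype=float)
        self.validate()

    def validate(self) -> None:
        if len(self.layer_assignment) != self.n_types:
            raise ValueError("one layer index per type required")
        if max(self.layer_assignment) >= len(self.layer_depths):
            raise ValueError("layer_assignment refers to an undefined layer")
        depths = sorted(self.layer_depths)
        for (lo, hi) in depths:
            if hi <= lo:
                raise ValueError(f"empty layer depth interval ({lo}, {hi})")
        for (_, hi), (lo, _) in zip(depths, depths[1:]):
            if lo < hi:
                raise ValueError("layer depth intervals must be disjoint")
        if self.mosaic_exclusion_radius < 0:
            raise ValueError("mosaic_exclusion_radius must be >= 0")
        if not np.all(np.isfinite(self.f_archetypes)):
            raise ValueError("archetype amplitudes must be finite")
        if self.f_archetypes.shape[1] != len(STIM_CLASSES):
            raise ValueError(f"archetypes need {len(STIM_CLASSES)} stimulus columns")
        if len(self.ap_gradient) != self.n_types:
            raise ValueError("one anterior–posterior slope per type required")
        if any(abs(s) > 2 for s in self.ap_gradient):
            raise ValueError("ap_gradient slopes must lie in [-2, 2]")
        if self.coupling.shape != (self.n_types, self.n_pos_bins, self.n_archetypes):
            raise ValueError("coupling must be (n_types, n_pos_bins, n_archetypes)")
        if (self.coupling < -1e-12).any() or not np.allclose(
            self.coupling.sum(axis=2), 1.0
        ):
            raise ValueError("coupling rows must be probabilities summing to 1")

    def child_seeds(self) -> dict[str, np.random.SeedSequence]:
        names = ("cloud", "archetypes", "traces", "masks")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return dict(zip(names, children))


def _sample_ap(rng: np.random.Generator, n: int, slope: float, extent: float) -> np.ndarray:
    """Inverse-CDF sampling of x with linear density 1 + slope*(x/X - 1/2)."""
    u = rng.random(n)
    if abs(slope) < 1e-12:
        return u * extent
    a = slope / 2.0
    b = 1.0 - a
    t = (-b + np.sqrt(b * b + 4 * a * u)) / (2 * a)
    return t * extent


def generate_point_cloud(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[LabeledPointCloud, np.ndarray]:
    """Dart-throwing generation of a layered, mosaic point cloud.

    Returns the cloud (labels ``t0..t{n-1}``) and the ground-truth layer
    index per cell. Raises if a type's hard-core packing is infeasible at
    the requested density.
    """
    if rng is None:
        rng = np.random.default_rng(config.child_seeds()["cloud"])
    coords_all, labels_all, layers_all = [], [], []
    r2 = config.mosaic_exclusion_radius**2
    ex, ey = config.extent_um
    for t in range(config.n_types):
        lo, hi = config.layer_depths[config.layer_assignment[t]]
        accepted = np.empty((0, 3))
        attempts = 0
        max_attempts = 500 * config.n_cells_per_type
        while len(accepted) < config.n_cells_per_type:
            if attempts >= max_attempts:
                raise RuntimeError(
                    f"infeasible mosaic packing for type t{t}: placed "
                    f"{len(accepted)}/{config.n_cells_per_type} cells at "
                    f"exclusion radius {config.mosaic_exclusion_radius} µm"
                )
            attempts += 1
            x = _sample_ap(rng, 1, config.ap_gradient[t], ex)[0]
            y = rng.random() * ey
            z = lo + rng.random() * (hi - lo)
            p = np.array([x, y, z])
            if r2 > 0 and len(accepted):
                if np.min(np.sum((accepted - p) ** 2, axis=1)) < r2:
                    continue
            accepted = np.vstack([accepted, p])
        coords_all.append(accepted)
        labels_all.extend([f"t{t}"] * config.n_cells_per_type)
        layers_all.extend([config.layer_assignment[t]] * config.n_cells_per_type)
    cloud = LabeledPointCloud(
        coords=np.vstack(coords_all), labels=np.array(labels_all)
    )
    return cloud, np.array(layers_all)


def position_bins(x: np.ndarray, extent: float, n_bins: int) -> np.ndarray:
    """Anterior–posterior bin index per cell (equal-width bins over x)."""
    b = np.floor(np.asarray(x) / extent * n_bins).astype(int)
    return np.clip(b, 0, n_bins - 1)


def generate_traces(
    protocol: StimulusProtocol,
    config: SyntheticConfig,
    roi_ftypes: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[TraceMatrix, np.ndarray]:
    """Stimulus-locked traces for ROIs with the given archetype labels.

    Returns the trace matrix and the noiseless ground-truth signal
    (baseline + archetype amplitudes x regressors) for residual checks.
    """
    roi_ftypes = np.asarray(roi_ftypes, dtype=int)
    if roi_ftypes.min(initial=0) < 0 or roi_ftypes.max(initial=0) >= config.n_archetypes:
        raise ValueError("archetype index out of range")
    if rng is None:
        rng = np.random.default_rng(config.child_seeds()["traces"])
    reg = build_regressors(protocol, config.frame_rate, config.tau)
    signal = config.baseline + config.f_archetypes[roi_ftypes] @ reg.values.T
    noise = rng.normal(0.0, config.noise_sd, signal.shape) if config.noise_sd > 0 else 0.0
    if config.drift_sd > 0:
        drift = np.cumsum(rng.normal(0.0, config.drift_sd, signal.shape), axis=1)
    else:
        drift = 0.0
    traces = TraceMatrix(values=signal + noise + drift, frame_rate=config.frame_rate)
    return traces, signal


@dataclass
class MultimodalDataset:
    """Joint synthetic dataset with full ground-truth provenance."""

    cloud: LabeledPointCloud
    traces: TraceMatrix
    signal: np.ndarray
    protocol: StimulusProtocol
    provenance: pd.DataFrame  # roi_id, t_type, layer, pos_bin, archetype, x/y/z


def generate_multimodal(
    config: SyntheticConfig,
    protocol: StimulusProtocol | None = None,
    with_traces: bool = True,
) -> MultimodalDataset:
    """Generate a matched point-cloud + trace dataset.

    Each cell's functional archetype is drawn from
    P(archetype | t-type, anterior–posterior bin) given by ``config.coupling``.
    ``with_traces=False`` skips trace synthesis (labels and positions only),
    useful for large label-statistics checks.
    """
    seeds = config.child_seeds()
    if protocol is None:
        protocol = build_protocol(frame_rate=config.frame_rate)
    cloud, layers = generate_point_cloud(
        config, np.random.default_rng(seeds["cloud"])
    )
    bins = position_bins(cloud.coords[:, 0], config.extent_um[0], config.n_pos_bins)
    type_idx = np.array([int(lbl[1:]) for lbl in cloud.labels])
    rng_arch = np.random.default_rng(seeds["archetypes"])
    archetypes = np.array(
        [
            rng_arch.choice(config.n_archetypes, p=config.coupling[t, b])
            for t, b in zip(type_idx, bins)
        ]
    )
    if with_traces:
        traces, signal = generate_traces(
            protocol, config, archetypes, np.random.default_rng(seeds["traces"])
        )
    else:
        traces = TraceMatrix(
            values=np.zeros((len(cloud), 1)), frame_rate=config.frame_rate
        )
        signal = traces.values
    provenance = pd.DataFrame(
        {
            "roi_id": np.arange(len(cloud)),
            "t_type": cloud.labels,
            "layer": layers,
            "pos_bin": bins,
            "archetype": archetypes,
            "x_um": cloud.coords[:, 0],
            "y_um": cloud.coords[:, 1],
            "z_um": cloud.coords[:, 2],
        }
    )
    return MultimodalDataset(
        cloud=cloud, traces=traces, signal=signal, protocol=protocol, provenance=provenance
    )


def generate_roi_masks(
    cloud: LabeledPointCloud,
    jitter_sd: float = 0.0,
    mask_radius: int = 2,
    pixel_size_um: float = 1.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[RoiMaskSet, pd.DataFrame]:
    """In-plane disk masks centred on jittered centroids.

    Returns the mask set plus a ground-truth table mapping each centroid
    (integer pixel coordinates) to its own ROI id. Masks may overlap.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    px = cloud.coords / pixel_size_um
    margin = mask_radius + 3
    px = px - px.min(axis=0) + margin
    planes = np.round(px[:, 2]).astype(int)
    rows = np.round(px[:, 1]).astype(int)
    cols = np.round(px[:, 0]).astype(int)
    shape = (planes.max() + margin, rows.max() + margin, cols.max() + margin)

    rr = np.arange(-mask_radius, mask_radius + 1)
    disk = np.array(
        [(i, j) for i in rr for j in rr if i * i + j * j <= mask_radius**2]
    )
    masks: dict[int, np.ndarray] = {}
    records = []
    for roi_id in range(len(cloud)):
        jr, jc = rng.normal(0.0, jitter_sd, 2) if jitter_sd > 0 else (0.0, 0.0)
        cr = int(round(rows[roi_id] + jr))
        cc = int(round(cols[roi_id] + jc))
        cr = np.clip(cr, mask_radius, shape[1] - mask_radius - 1)
        cc = np.clip(cc, mask_radius, shape[2] - mask_radius - 1)
        pix = np.column_stack(
            [
                np.full(len(disk), planes[roi_id]),
                cr + disk[:, 0],
                cc + disk[:, 1],
            ]
        )
        masks[roi_id] = pix
        records.append((roi_id, planes[roi_id], rows[roi_id], cols[roi_id]))
    truth = pd.DataFrame(records, columns=["centroid_id", "plane", "row", "col"])
    truth["true_roi_id"] = truth["centroid_id"]
    return RoiMaskSet(masks=masks, shape=shape, pixel_size_um=pixel_size_um), truth
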