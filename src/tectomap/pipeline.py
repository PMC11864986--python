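"""End-to-end orchestration: simulate → score → ftype → layers → overlap →
classify → match, with a reproducibility manifest.

Each stage is a pure function over the in-memory state plus its config
section; ``run_pipeline`` chains them, writes every artifact (CSV/JSON,
traces as a dense ``.npy`` with a JSON sidecar) into one output directory,
and records a manifest (config snapshot, seed, SHA-256 digest per file) —
re-running with the same config and seed reproduces identical bytes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import validate_config
from .correspondence import match_centroids_to_rois
from .ftypes import cluster_exemplars, find_exemplars, ftype_table
from .identity import svm_type_comparison, ttype_response_summary
from .layering import cluster_layers, compute_nnd_matrix, layering_null
from .overlap import overlap_separation_test
from .scoring import fit_response_scores, scale_scores, select_responders
from .stimulus import build_protocol, build_regressors
from .synthetic import (
    SyntheticConfig,
    coupling_mixed,
    coupling_type_position,
    generate_multimodal,
    generate_roi_masks,
)


def synthetic_config_from(cfg: dict, seed: int) -> SyntheticConfig:
    s = cfg["synthetic"]
    if s["coupling_mode"] == "type_position":
        coupling = coupling_type_position(
            s["n_types"], s["n_pos_bins"], s["n_archetypes"],
            strength=s["coupling_strength"],
        )
    elif s["coupling_mode"] == "mixed":
        coupling = coupling_mixed(
            s["n_types"], s["n_pos_bins"], s["n_archetypes"],
            w_type=s["coupling_w_type"], w_pos=s["coupling_w_pos"],
        )
    else:
        raise ValueError(f"unknown coupling_mode {s['coupling_mode']!r}")
    return SyntheticConfig(
        n_types=s["n_types"],
        layer_assignment=tuple(s["layer_assignment"]),
        layer_depths=tuple(tuple(d) for d in s["layer_depths"]),
        extent_um=tuple(s["extent_um"]),
        mosaic_exclusion_radius=s["mosaic_exclusion_radius"],
        ap_gradient=tuple(s["ap_gradient"]) if s["ap_gradient"] else None,
        n_cells_per_type=s["n_cells_per_type"],
        n_archetypes=s["n_archetypes"],
        coupling=coupling,
        n_pos_bins=s["n_pos_bins"],
        baseline=s["baseline"],
        noise_sd=s["noise_sd"],
        drift_sd=s["drift_sd"],
        frame_rate=s["frame_rate"],
        tau=s["tau"],
        seed=seed,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: dict | None = None,
    out_dir: str | Path = "pipeline_out",
    seed: int | None = None,
) -> dict:
    """Run every stage on synthetic data and write artifacts + manifest.

    Returns a summary dict (also written as ``summary.json``).
    """
    cfg = validate_config(config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- simulate -------------------------------------------------------
    syn = synthetic_config_from(cfg, cfg["seed"])
    data = generate_multimodal(syn)
    data.cloud.to_csv(out / "point_cloud.csv")
    data.provenance.to_csv(out / "provenance.csv", index=False)
    np.save(out / "traces.npy", data.traces.values)
    (out / "traces.json").write_text(
        json.dumps(
            {
                "frame_rate_hz": syn.frame_rate,
                "n_rois": int(data.traces.n_rois),
                "n_frames": int(data.traces.n_frames),
                "roi_ids": [int(r) for r in data.traces.roi_ids],
            }
        )
    )
    (out / "protocol.json").write_text(data.protocol.to_json())

    # ---- score ----------------------------------------------------------
    sc = cfg["scoring"]
    regressors = build_regressors(data.protocol, syn.frame_rate, syn.tau)
    regressors.to_dataframe().to_csv(out / "regressors.csv", index=False)
    scores = fit_response_scores(
        data.traces, regressors, data.protocol, window_pad=sc["window_pad"]
    )
    responders = select_responders(
        scores, percentile=sc["percentile"], pooled=sc["pooled_percentile"]
    )
    scores.scaled_scores = scale_scores(scores.scores, scores.scores)
    scores.to_dataframe(responders).to_csv(out / "scores.csv", index=False)

    # ---- ftype ----------------------------------------------------------
    ft = cfg["ftype"]
    resp_scaled = scores.scaled_scores[responders]
    exemplars = find_exemplars(resp_scaled, damping=ft["damping"])
    k = min(ft["k"], max(1, exemplars.n_exemplars))
    assignment = cluster_exemplars(
        exemplars, k=k, min_members=ft["min_members"],
        supercluster_k=ft["supercluster_k"],
    )
    ftypes_resp = ftype_table(
        np.asarray(scores.roi_ids)[responders], exemplars, assignment
    )
    ftypes_resp.to_csv(out / "ftypes.csv", index=False)
    f_by_roi = np.zeros(scores.scores.shape[0], dtype=int)
    f_by_roi[np.flatnonzero(responders)] = assignment.roi_ftype

    # ---- layers ---------------------------------------------------------
    ly = cfg["layers"]
    nnd = compute_nnd_matrix(data.cloud)
    nnd.to_dataframe().to_csv(out / "nnd_matrix.csv")
    layer_labels, _ = cluster_layers(nnd, n_layers=ly["n_layers"])
    pd.DataFrame({"t_type": nnd.types, "layer": layer_labels}).to_csv(
        out / "layers.csv", index=False
    )
    null = layering_null(
        data.cloud, n_layers=ly["n_layers"], n_perm=ly["n_perm"], seed=cfg["seed"]
    )

    # ---- overlap --------------------------------------------------------
    ov = cfg["overlap"]
    labelled = f_by_roi > 0
    sep = overlap_separation_test(
        data.cloud.coords[labelled],
        data.provenance["t_type"].to_numpy()[labelled],
        f_by_roi[labelled],
        grouping=ov["grouping"],
        min_size=ov["min_size"],
        bandwidth=ov["bandwidth"],
        grid_size=ov["grid_size"],
        n_shuffles=ov["n_shuffles"],
        seed=cfg["seed"],
    )
    sep.table.to_csv(out / "overlap_test.csv", index=False)

    # ---- classify -------------------------------------------------------
    cl = cfg["classify"]
    reports, comparisons = svm_type_comparison(
        scores.scaled_scores,
        data.cloud.coords,
        data.provenance["t_type"].to_numpy(),
        n_repeats=cl["n_repeats"],
        test_frac=cl["test_frac"],
        upsample_to=cl["upsample_to"],
        seed=cfg["seed"],
        standardize_positions=cl["standardize_positions"],
    )
    comparisons.to_csv(out / "classifier_comparisons.csv", index=False)
    for name, rep in reports.items():
        rep.confusion.to_csv(out / f"confusion_{name}.csv")
    ttype_response_summary(
        scores.scaled_scores, data.provenance["t_type"].to_numpy()
    ).to_csv(out / "ttype_response_summary.csv")

    # ---- match ----------------------------------------------------------
    mt = cfg["match"]
    masks, truth = generate_roi_masks(
        data.cloud,
        jitter_sd=mt["jitter_sd"],
        mask_radius=mt["mask_radius"],
        seed=cfg["seed"],
    )
    matched = match_centroids_to_rois(truth, masks)
    matched = matched.merge(truth[["centroid_id", "true_roi_id"]], on="centroid_id")
    matched.to_csv(out / "matching.csv", index=False)
    match_acc = float((matched["roi_id"] == matched["true_roi_id"]).mean())

    summary = {
        "n_rois": int(data.traces.n_rois),
        "n_responders": int(responders.sum()),
        "n_exemplars": int(exemplars.n_exemplars),
        "n_ftypes": int(k),
        "layering_p": null.p_value,
        "overlap_overall_p": sep.overall_p,
        "svm_accuracy": {
            name: float(np.median(rep.accuracies)) for name, rep in reports.items()
        },
        "svm_shuffled_accuracy": {
            name: float(np.median(rep.shuffled_accuracies))
            for name, rep in reports.items()
        },
        "match_accuracy": match_acc,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    manifest = {
        "package_version": __version__,
        "seed": cfg["seed"],
        "config": cfg,
        "digests": {
            p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return summary
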