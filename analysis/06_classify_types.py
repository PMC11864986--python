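"""Is transcriptomic identity better predicted by function or by position?

Trains RBF-kernel SVMs to predict t-type from scaled response vectors,
3D cell-body positions, or both, with repeated stratified splits,
per-type upsampling and shuffled-label negative controls.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tectomap.config import validate_config
from tectomap.identity import svm_type_comparison, ttype_response_summary

ROOT = Path(__file__).resolve().parents[1]
DEMO = ROOT / "results" / "demo"


def main() -> None:
    cfg = validate_config(yaml.safe_load((ROOT / "configs" / "demo.yaml").read_text()))
    cl = cfg["classify"]
    prov = pd.read_csv(DEMO / "provenance.csv")
    scores = pd.read_csv(DEMO / "scores.csv")
    merged = prov.merge(scores, on="roi_id")
    scaled = merged[[c for c in scores.columns if c.startswith("scaled_")]].to_numpy()

    ttype_response_summary(scaled, merged["t_type"].to_numpy()).to_csv(
        DEMO / "ttype_response_summary.csv"
    )
    reports, comparisons = svm_type_comparison(
        scaled, merged[["x_um", "y_um", "z_um"]].to_numpy(),
        merged["t_type"].to_numpy(),
        n_repeats=cl["n_repeats"], test_frac=cl["test_frac"],
        upsample_to=cl["upsample_to"], seed=cfg["seed"],
        standardize_positions=cl["standardize_positions"],
    )
    comparisons.to_csv(DEMO / "classifier_comparisons.csv", index=False)
    report = {}
    for name, rep in reports.items():
        rep.confusion.to_csv(DEMO / f"confusion_{name}.csv")
        report[name] = {
            "median_accuracy": float(np.median(rep.accuracies)),
            "median_shuffled_accuracy": float(np.median(rep.shuffled_accuracies)),
            "real_vs_shuffled_p": rep.real_vs_shuffled_p,
        }
    (DEMO / "classifier_report.json").write_text(json.dumps(report, indent=2))

    for name, r in report.items():
        print(f"{name:9s} accuracy {r['median_accuracy']:.3f} "
              f"(shuffled {r['median_shuffled_accuracy']:.3f}, "
              f"p = {r['real_vs_shuffled_p']:.2g})")
    print(comparisons.to_string(index=False))
    print(f"wrote classifier report, comparisons and confusion matrices to {DEMO}")


if __name__ == "__main__":
    main()
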