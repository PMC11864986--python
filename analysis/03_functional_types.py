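"""Derive functional types from responder score vectors.

Affinity propagation picks exemplar ROIs in 8-dimensional scaled score
space; exemplars with few members are pruned and the survivors are cut
into f-types by complete-linkage clustering on correlation distance.
"""

from pathlib import Path

import pandas as pd
import yaml

from tectomap.config import validate_config
from tectomap.ftypes import cluster_exemplars, find_exemplars, ftype_table

ROOT = Path(__file__).resolve().parents[1]
DEMO = ROOT / "results" / "demo"


def main() -> None:
    cfg = validate_config(yaml.safe_load((ROOT / "configs" / "demo.yaml").read_text()))
    ft = cfg["ftype"]
    df = pd.read_csv(DEMO / "scores.csv")
    resp = df[df["responder"]]
    scaled = resp[[c for c in df.columns if c.startswith("scaled_")]].to_numpy()

    ex = find_exemplars(scaled, damping=ft["damping"])
    assignment = cluster_exemplars(ex, k=min(ft["k"], ex.n_exemplars),
                                   min_members=ft["min_members"],
                                   supercluster_k=ft["supercluster_k"])
    table = ftype_table(resp["roi_id"].to_numpy(), ex, assignment)
    table.to_csv(DEMO / "ftypes.csv", index=False)

    sizes = table[table.f_type > 0]["f_type"].value_counts().sort_index()
    print(f"{ex.n_exemplars} exemplars from {len(resp)} responders; "
          f"{(table.f_type > 0).sum()} ROIs labelled with {assignment.k} f-types")
    print(f"f-type sizes: {sizes.to_dict()}")
    print(f"wrote ftypes.csv to {DEMO}")


if __name__ == "__main__":
    main()
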