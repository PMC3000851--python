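#!/usr/bin/env python
"""Multivariate analysis of the selected wavenumber panel: correlation-
distance UPGMA dendrogram cut into two clusters (cluster composition and
class capture), and PCA with the >= 5%-variance retention rule.
"""

import json
from pathlib import Path

import pandas as pd

import ftir_sputum as fs

SCRATCH = Path("scratch/analysis")
RESULTS = Path("results")


def main() -> None:
    processed = SCRATCH / "processed_per_subject.csv"
    panel_file = RESULTS / "panel.json"
    if not processed.exists() or not panel_file.exists():
        raise SystemExit("run analysis/03_screen_wavenumbers.py first")
    per_subject = fs.read_cohort_matrix(processed, "wide_csv",
                                        kind="second_derivative")
    panel = json.loads(panel_file.read_text())["panel_wavenumbers"]

    pm = fs.build_panel_matrix(per_subject, panel)
    tree = fs.upgma_tree(fs.correlation_distance_matrix(pm), pm.sample_ids)
    (RESULTS / "tree.newick").write_text(fs.to_newick(tree) + "\n")
    assignment = fs.cut_tree(tree, 2)
    clusters = pm.meta[["sample_id", "class", "smoking_status",
                        "prior_cancer", "cough"]].copy()
    clusters["cluster"] = assignment
    clusters.to_csv(RESULTS / "clusters.csv", index=False)
    purity = fs.cluster_purity(assignment, pm.class_labels)

    pca = fs.pca_panel(pm)
    pd.DataFrame({"component": range(1, 6),
                  "variance_fraction": pca.variance_fraction,
                  "retained": pca.variance_fraction >= 0.05}) \
        .to_csv(RESULTS / "scree.csv", index=False, float_format="%.6g")
    pd.DataFrame(pca.loadings, index=[f"{w:.1f}" for w in pm.wavenumbers],
                 columns=[f"PC{i+1}" for i in range(5)]) \
        .to_csv(RESULTS / "pca_loadings.csv", float_format="%.4f",
                index_label="wavenumber")

    print("two-cluster composition (UPGMA on correlation distance):")
    print(purity["contingency"].to_string())
    print("class capture: " + ", ".join(
        f"{cls} {pct:.1f}%" for cls, pct in purity["capture"].items()))
    print("PCA variance fractions: "
          + ", ".join(f"{f:.1%}" for f in pca.variance_fraction)
          + f"; components retained at the 5% rule: {pca.retained}")


if __name__ == "__main__":
    main()
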