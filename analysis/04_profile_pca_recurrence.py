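#!/usr/bin/env python
"""Tumor fingerprints: PCA, clustering, and the recurrence rule.

From the per-tumor profiles of step 02: build the standardized feature
table (category, spontaneous and per-stimulus percentages plus diameter),
run PCA and hierarchical clustering on correlation distance, apply the
recurrence rule (spontaneous activity present AND >20% multi-responsive
AND <50% non-responsive), and compare predictions with the observed
recurrence labels. Tables and QC figures land under results/cohort/.
"""

import argparse
from pathlib import Path

import pandas as pd

from pitcalc import plotting
from pitcalc.profiling import (
    TumorProfile,
    build_feature_table,
    cluster_tumors,
    predict_recurrence,
    run_pca,
)
from pitcalc.protocol import SECRETAGOGUES


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--profiles", type=Path, default=Path("results/cohort/tumor_profiles.tsv"))
    parser.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = parser.parse_args()

    df = pd.read_csv(args.profiles, sep="\t", dtype={"tumor_id": str})
    profiles = [
        TumorProfile(
            tumor_id=row["tumor_id"],
            pct_spontaneous=row["pct_spontaneous"],
            pct_non=row["pct_non"],
            pct_mono=row["pct_mono"],
            pct_multi=100.0 - row["pct_non"] - row["pct_mono"],
            per_stimulus_pct={s: row[f"pct_{s}"] for s in SECRETAGOGUES},
            max_diameter_cm=row["max_diameter_cm"],
            recurrent_observed=bool(row["recurrent_observed"]),
        )
        for _, row in df.iterrows()
    ]

    features, dropped = build_feature_table(profiles)
    if dropped:
        print(f"dropped constant features: {dropped}")
    pca = run_pca(features)
    print("PCA explained variance (%): "
          + ", ".join(f"PC{i+1}={v:.1f}" for i, v in enumerate(pca.explained_pct[:4])))
    print(f"first two components together: {pca.explained_pct[:2].sum():.1f}%")

    order, clusters = cluster_tumors(features)
    print(f"dendrogram order: {order}")

    rows = []
    hits = 0
    for p in profiles:
        predicted, clauses = predict_recurrence(p)
        p.recurrent_predicted = predicted
        hits += predicted == p.recurrent_observed
        rows.append({
            "tumor_id": p.tumor_id,
            "cluster": clusters[p.tumor_id],
            "recurrent_observed": p.recurrent_observed,
            "recurrent_predicted": predicted,
            **{f"clause_{k}": v for k, v in clauses.items()},
        })
    result = pd.DataFrame(rows).set_index("tumor_id")
    print(f"recurrence rule agrees with observed status for {hits}/{len(profiles)} tumors")

    args.out.mkdir(parents=True, exist_ok=True)
    result.to_csv(args.out / "recurrence_predictions.tsv", sep="\t")
    pca.scores.to_csv(args.out / "pca_scores.tsv", sep="\t", float_format="%.6g")
    pca.loadings.to_csv(args.out / "pca_loadings.tsv", sep="\t", float_format="%.6g")

    recurrent = {p.tumor_id: p.recurrent_observed for p in profiles}
    plotting.pca_scatter(pca.scores, pca.explained_pct, args.out / "pca_scatter.png", recurrent)
    heat_cols = ["pct_spontaneous", "pct_non", "pct_mono", "pct_multi"] + [f"pct_{s}" for s in SECRETAGOGUES]
    plotting.proportion_heatmap(df.set_index("tumor_id")[heat_cols].loc[order], args.out / "profile_heatmap.png")
    print(f"-> tables and figures under {args.out}")


if __name__ == "__main__":
    main()
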