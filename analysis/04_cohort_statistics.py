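#!/usr/bin/env python
"""Group statistics on the synthetic cohort: all pairwise contrasts of the
study design (healthy vs diabetic; the healthy/NC/LN/HN severity ladder;
NnA vs NA), Spearman correlations of covariates against the vascular
biomarkers, covariate-adjusted logistic regression, and the SVN threshold
classifier.

Reads results/cohort.csv (built by 03_simulate_cohort.py if missing); writes
the results bundle and a small-vessel bar chart to results/cohort_stats/.
"""

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from rsomskin import pipeline
from rsomskin.phantom import CohortSpec, make_cohort

RESULTS = Path("results")
OUT = RESULTS / "cohort_stats"


def svn_figure(table: pd.DataFrame, comparisons: pd.DataFrame) -> None:
    order = ["healthy", "NC", "LN", "HN"]
    means = [table.loc[table.group == g, "svn"].mean() for g in order]
    sds = [table.loc[table.group == g, "svn"].std() for g in order]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(order, means, yerr=sds, capsize=4, color="#74a9cf")
    svn = comparisons[comparisons.biomarker == "svn"].set_index("contrast")
    for i, contrast in enumerate(("healthy_vs_NC", "NC_vs_LN", "LN_vs_HN")):
        star = svn.loc[contrast, "star"] or "ns"
        y = max(means[i], means[i + 1]) + max(sds[i], sds[i + 1]) + 0.5
        ax.plot([i, i + 1], [y, y], color="k", lw=1)
        ax.text(i + 0.5, y + 0.1, star, ha="center")
    ax.set_ylabel("small vessel number")
    fig.tight_layout()
    fig.savefig(OUT / "svn_ladder.png", dpi=150)
    plt.close(fig)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort_path = RESULTS / "cohort.csv"
    table = (pd.read_csv(cohort_path) if cohort_path.exists()
             else make_cohort(CohortSpec(seed=0)))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle = pipeline.run_cohort(table, out_dir=OUT)

    comp = bundle["comparisons"]
    svn = comp[comp.biomarker == "svn"][
        ["contrast", "test", "p_value", "star", "mean_a", "mean_b"]]
    print("small-vessel-number contrasts:")
    print(svn.round(4).to_string(index=False))
    roc = bundle["roc"]
    print(f"\nSVN classifier: AUC {roc['auc']:.3f}, "
          f"accuracy {roc['accuracy']:.1f} %, "
          f"sensitivity {roc['sensitivity']:.1f} %, "
          f"specificity {roc['specificity']:.1f} % "
          f"(threshold {roc['best_threshold']:.2f} vessels)")
    svn_figure(table, comp)
    print(f"bundle -> {OUT}/")


if __name__ == "__main__":
    main()
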