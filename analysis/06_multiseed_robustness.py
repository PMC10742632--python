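"""Robustness of the cohort-level findings over 100 generator seeds.

Repeats generate -> classify -> stepwise -> ROC for 100 calibrated cohorts
and summarizes how often the published multivariate trio is retained, the
AUC distribution, and the MIO odds ratio.  Writes
results/robustness.json.
"""

import collections
import json
from pathlib import Path

import numpy as np
from scipy import stats

from ferriscope.classification import classify_cohort
from ferriscope.cohort_stats import roc_youden, stepwise_t2star_model
from ferriscope.synthetic_data import make_study_cohort

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

CANDIDATES = ["sex_f", "age", "hb", "ferritin", "vitamin_d", "pth", "lic",
              "pancreas_t2star"]
TRIO = {"ferritin", "vitamin_d", "pancreas_t2star"}

aucs, spearmans, sets = [], [], collections.Counter()
for seed in range(100):
    df = classify_cohort(make_study_cohort(seed))
    df["sex_f"] = (df["sex"] == "F").astype(float)
    rep = stepwise_t2star_model(df, "heart_t2star", CANDIDATES)
    sets[tuple(sorted(rep.retained))] += 1
    aucs.append(roc_youden(df["vitamin_d"].to_numpy(),
                           df["myocardial_overload"].to_numpy(),
                           direction="low").auc)
    spearmans.append(stats.spearmanr(df["pancreas_t2star"],
                                     df["heart_t2star"]).statistic)

trio_rate = sets[tuple(sorted(TRIO))] / 100
summary = {
    "n_seeds": 100,
    "trio_retention_rate": trio_rate,
    "retained_set_counts": {" + ".join(k): v for k, v in sets.most_common()},
    "auc_median": float(np.median(aucs)),
    "auc_q10": float(np.quantile(aucs, 0.10)),
    "auc_q90": float(np.quantile(aucs, 0.90)),
    "pancreas_heart_spearman_mean": float(np.mean(spearmans)),
}
(OUT / "robustness.json").write_text(json.dumps(summary, indent=1))
print(json.dumps(summary, indent=1))
print(f"\nThe published predictor trio (ferritin, vitamin D, pancreatic T2*) "
      f"is retained in {100 * trio_rate:.0f}% of seeds; the vitamin-D ROC "
      f"AUC centers at {np.median(aucs):.3f}.")
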