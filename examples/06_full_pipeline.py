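"""End-to-end run: synthetic cohort -> preprocessing -> ICA/ROI -> features
-> GA selection -> SVM classification, with the report table.

Scaled down (16 subjects, 30 s recordings) so it finishes in about a
minute; the acceptance script runs the full-size benchmark.
"""

import json

from rtmspredict import (
    GAConfig,
    PreprocessConfig,
    RunConfig,
    SyntheticCohortConfig,
    run_pipeline,
)

cfg = RunConfig(
    cohort=SyntheticCohortConfig(n_responders=8, n_nonresponders=8,
                                 duration_s=34.0, fs=250.0, seed=11),
    preprocess=PreprocessConfig(keep_duration_s=30.0),
    ga=GAConfig(population=20, generations=10),
    classifiers=("svm",),
    families=("Power", "Combination"),
    mode="nested",
    folds=8,
    seed=11,
)
report = run_pipeline(cfg)

print(f"subjects: {report['manifest']['n_subjects']}, "
      f"runtime: {report['manifest']['runtime_s']} s, "
      f"feature table sha256: {report['manifest']['feature_table_sha256'][:12]}...")
for family, per_clf in report["results"].items():
    for clf, res in per_clf.items():
        cm = res["pooled_confusion"]
        print(f"{family:>12} / {clf}: accuracy {res['metrics_pct']['accuracy']}% "
              f"(TP={cm['TP']} FP={cm['FP']} FN={cm['FN']} TN={cm['TN']})")
print("ANOVA screen, smallest p-values:")
anova = sorted(report["anova"], key=lambda r: r["p"])[:5]
print(json.dumps([{r['feature']: round(r['p'], 5)} for r in anova], indent=1))
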