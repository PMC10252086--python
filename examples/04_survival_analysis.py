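"""Survival statistics for the SU/SD subtypes.

Kaplan–Meier medians per group, the log-rank test, the SU-vs-SD Cox
hazard ratio, and a multiple-cutoff log-rank scan over the stromal score.
"""

import numpy as np

from stromasig import (
    SimConfig,
    classify_su_sd,
    cox_fit_by_label,
    generate_cohort,
    km_estimate,
    logrank_by_label,
    multi_cutoff_logrank,
    stromal_score,
)

cohort = generate_cohort(SimConfig(seed=4))
labels = classify_su_sd(cohort.expression, cohort.truth.stromal_genes)
clin = cohort.clinical

for name in ("SU", "SD"):
    sel = labels.labels == name
    curve = km_estimate(clin.loc[sel, "os_time"], clin.loc[sel, "os_event"])
    med = f"{curve.median:.1f} months" if curve.median_defined \
        else "not reached within follow-up"
    print(f"{name} (n={int(sel.sum())}): median survival {med}")

lr = logrank_by_label(labels.labels, clin)
model = cox_fit_by_label(labels.labels, clin, reference="SD")
print(f"log-rank chi-square {lr.statistic:.2f} (df={lr.df}), p = {lr.p:.2g}")
print(f"SU vs SD hazard ratio {model.hr[0]:.2f}, Wald p = {model.p[0]:.2g}")

score = stromal_score(cohort.expression, cohort.truth.stromal_genes)
scan = multi_cutoff_logrank(score.scores.to_numpy(),
                            clin["os_time"].to_numpy(),
                            clin["os_event"].to_numpy(dtype=float))
usable = [pt for pt in scan if not pt.skipped]
best = min(usable, key=lambda pt: pt.p)
print(f"cutoff scan: smallest p {best.p:.2g} at the "
      f"{best.quantile:.0%} score percentile (HR {best.hazard_ratio:.2f})")
# A much shorter SU median with HR > 1 reproduces, on synthetic ground
# truth, the poor prognosis of the stroma-rich subtype; the scan shows
# the dichotomization is not knife-edge dependent on the median cutoff.
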