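"""Rate ratios for events in non-adherent vs adherent person-time.

Splits each patient's year into possession-covered and uncovered periods,
assigns exacerbation events to the period containing them, and fits the
random-intercept Poisson model (switching to negative binomial under
overdispersion) plus the linear mixed model for period costs.
"""

import pandas as pd

from adhera import (
    apply_eligibility,
    build_person_periods,
    fit_cost_lmm,
    fit_count_model,
    generate_cohort,
    summarize_cohort,
)
from adhera.outcomes import OutcomesConfig, _detect_exacerbations_pre
from adhera.simulate import gbtm_recovery_config

bundle = generate_cohort(gbtm_recovery_config(n_patients=800, seed=11))
cohort = apply_eligibility(bundle)
summaries = summarize_cohort(bundle, cohort.mpr_set)

cfg = OutcomesConfig()
events, costs = [], []
disp_groups = dict(list(bundle.dispensings.groupby("patient_id", sort=False)))
enc_groups = dict(list(bundle.encounters.groupby("patient_id", sort=False)))
diag_groups = dict(list(bundle.diagnoses.groupby("patient_id", sort=False)))
for row in cohort.mpr_set.itertuples(index=False):
    ev = _detect_exacerbations_pre(
        enc_groups.get(row.patient_id, bundle.encounters.iloc[0:0]),
        disp_groups.get(row.patient_id, bundle.dispensings.iloc[0:0]),
        diag_groups.get(row.patient_id, bundle.diagnoses.iloc[0:0]),
        row.index_date, cfg,
    )
    ev.insert(0, "patient_id", row.patient_id)
    events.append(ev)
events = pd.concat(events, ignore_index=True)

periods = build_person_periods(summaries, events=events)
for outcome in sorted(events["event_type"].unique()):
    res = fit_count_model(periods, outcome)
    print(f"{outcome:20s} rate ratio {res.effect:5.2f}  "
          f"p={res.p_value:.2g}  family={res.family}  "
          f"dispersion={res.dispersion:.2f}")
# A rate ratio above 1 means the event occurs more often per person-day in
# uncovered (non-adherent) time; the cohort is generated with a true rate
# ratio of 2 for asthma-related events.
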