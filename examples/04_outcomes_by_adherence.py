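"""Exacerbations, HCRU and pharmacy costs stratified by adherence category.

Builds the per-patient outcome table (exacerbation counts, hospital use,
JPY pharmacy costs including/excluding biologics, steroid exposure) and
summarizes the key columns by the four-way adherence category, with
relative differences against the adherent group.
"""

from adhera import (
    apply_eligibility,
    build_outcome_table,
    generate_cohort,
    stratify,
    summaries_to_frame,
    summarize_cohort,
)
from adhera.simulate import gbtm_recovery_config

bundle = generate_cohort(gbtm_recovery_config(n_patients=800, seed=11))
cohort = apply_eligibility(bundle)
summaries = summarize_cohort(bundle, cohort.mpr_set)

table = build_outcome_table(bundle, cohort.mpr_set)
categories = summaries_to_frame(summaries)[["patient_id", "category"]]
merged = table.merge(categories, on="patient_id")

strata = stratify(merged.drop(columns="category"), merged["category"],
                  order=["adherent", "partially_adherent",
                         "minimally_adherent", "discontinuation"])
show = strata[strata["outcome"].isin(
    ["exac_total", "cost_allcause_incl_biologics", "cost_asthma_excl_biologics"]
)]
print(show.round(2).to_string(index=False))
# Exacerbations and asthma-related drug spending (excluding the biologics
# themselves) rise as adherence falls; total costs including biologics run
# the other way because adherent patients buy more doses — the hallmark
# reversal when biologic acquisition costs are excluded.
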