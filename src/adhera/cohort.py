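"""Cohort selection: index-date identification, eligibility and switch detection.

The index date is the first-ever dispensing of one of the five biologics;
eligibility applies the study criteria in a fixed, documented order so the
attrition table is reproducible.  "Continuous enrollment" is operationalized
as ``enrollment_start ≤ index − pre_index_days`` and ``enrollment_end ≥
index + followup_days`` (the schema carries no enrollment gaps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import BIOLOGICS, ClaimsBundle


@dataclass(frozen=True)
class ExclusionRule:
    """One exclusion diagnosis: which index biologics it applies to and when.

    ``biologics=None`` means the rule applies regardless of index biologic.
    ``timing`` is ``"pre_index"`` (diagnosis any time before the index date)
    or ``"pre_end"`` (any time before the end of the 12-month follow-up).
    """

    condition: str
    biologics: frozenset | None = None
    timing: str = "pre_index"


DEFAULT_EXCLUSIONS = (
    ExclusionRule("lung_malignancy"),
    ExclusionRule("respiratory_tuberculosis"),
    ExclusionRule("cystic_fibrosis"),
    ExclusionRule("hypereosinophilic_syndrome", timing="pre_end"),
    ExclusionRule("egpa", timing="pre_end"),
    ExclusionRule(
        "chronic_spontaneous_urticaria", frozenset({"dupilumab", "omalizumab"})
    ),
    ExclusionRule("atopic_dermatitis", frozenset({"dupilumab"})),
    ExclusionRule("prurigo_nodularis", frozenset({"dupilumab"})),
    ExclusionRule("seasonal_allergic_rhinitis", frozenset({"omalizumab"})),
    ExclusionRule("crswnp", frozenset({"mepolizumab", "dupilumab"})),
)


@dataclass(frozen=True)
class EligibilityConfig:
    min_age: int = 18
    pre_index_enrollment_days: int = 30
    followup_days: int = 365
    ics_laba_window_days: int = 90
    exclusions: tuple[ExclusionRule, ...] = DEFAULT_EXCLUSIONS

    def __post_init__(self) -> None:
        for w in (
            self.pre_index_enrollment_days,
            self.followup_days,
            self.ics_laba_window_days,
        ):
            if w <= 0:
                raise ValueError("windows must be > 0")


@dataclass
class CohortResult:
    """Eligible patients with index information, plus the attrition table."""

    cohort: pd.DataFrame  # patient_id, index_date, index_biologic, switched, switch_date
    attrition: pd.DataFrame  # criterion, n_remaining

    @property
    def mpr_set(self) -> pd.DataFrame:
        return self.cohort

    @property
    def gbtm_set(self) -> pd.DataFrame:
        """Non-switchers: the trajectory-model analysis set."""
        return self.cohort[~self.cohort["switched"]].reset_index(drop=True)


def find_index(dispensings: pd.DataFrame):
    """First-ever biologic dispensing of one patient.

    Returns ``(index_date, biologic)``, with ``biologic=None`` when two or
    more distinct biologics were dispensed on that first day (which excludes
    the patient), or ``None`` when the patient has no biologic dispensing.
    """
    bio = dispensings[dispensings["drug_code"].isin(BIOLOGICS)]
    if bio.empty:
        return None
    index_date = bio["dispense_date"].min()
    first = bio.loc[bio["dispense_date"] == index_date, "drug_code"].unique()
    return (index_date, first[0] if len(first) == 1 else None)


def detect_switch(
    dispensings: pd.DataFrame,
    index_biologic: str,
    index_date,
    followup_days: int = 365,
):
    """Whether a different biologic was dispensed inside the follow-up window.

    The window is the open interval ``(index, index + followup_days)``;
    returns ``(switched, first_switch_date_or_None)``.
    """
    bio = dispensings[
        dispensings["drug_code"].isin(BIOLOGICS)
        & (dispensings["drug_code"] != index_biologic)
    ]
    offsets = (bio["dispense_date"] - index_date).dt.days
    inside = bio[(offsets > 0) & (offsets < followup_days)]
    if inside.empty:
        return False, None
    return True, inside["dispense_date"].min()


def apply_eligibility(
    bundle: ClaimsBundle, config: EligibilityConfig = EligibilityConfig()
) -> CohortResult:
    """Apply the inclusion/exclusion criteria in their documented order.

    Order: biologic initiation → age → asthma diagnosis before index →
    single biologic on the index date → pre-index enrollment → 12-month
    follow-up → no prior biologic use → ICS+LABA near the asthma diagnosis →
    exclusion diagnoses (one attrition row per condition).  Input row order
    never affects the result.
    """
    pat = bundle.patients.sort_values("patient_id", kind="stable")
    disp = bundle.dispensings.sort_values(
        ["patient_id", "dispense_date", "drug_code"], kind="stable"
    )
    diag = bundle.diagnoses

    rows = []
    for pid, grp in disp.groupby("patient_id", sort=True):
        found = find_index(grp)
        if found is None:
            continue
        rows.append(
            {"patient_id": pid, "index_date": found[0], "index_biologic": found[1]}
        )
    idx = pd.DataFrame(rows, columns=["patient_id", "index_date", "index_biologic"])
    idx = idx.merge(pat, on="patient_id", how="inner")

    attrition = [("all_patients", len(pat)), ("biologic_initiation", len(idx))]

    def keep(mask, criterion: str):
        nonlocal idx
        idx = idx[mask.to_numpy()].reset_index(drop=True)
        attrition.append((criterion, len(idx)))

    if len(idx):
        age = idx["index_date"].dt.year - idx["birth_year"]
        keep(age >= config.min_age, "age_ge_18")
    else:
        attrition.append(("age_ge_18", 0))

    asthma = diag[diag["code"] == "asthma"][["patient_id", "diagnosis_date"]]
    merged = idx.merge(asthma, on="patient_id", how="left")
    merged = merged[merged["diagnosis_date"] < merged["index_date"]]
    has_dx = idx["patient_id"].isin(merged["patient_id"])
    keep(has_dx, "asthma_diagnosis_before_index")

    keep(idx["index_biologic"].notna(), "single_biologic_on_index_date")

    keep(
        idx["enrollment_start"]
        <= idx["index_date"] - pd.Timedelta(days=config.pre_index_enrollment_days),
        "pre_index_enrollment",
    )
    keep(
        idx["enrollment_end"]
        >= idx["index_date"] + pd.Timedelta(days=config.followup_days),
        "twelve_month_followup",
    )

    # No biologic dispensing strictly before the index date.  The index is
    # already the first-ever biologic, so this can only drop pathological
    # input, but the criterion keeps its own attrition row.
    bio = disp[disp["drug_code"].isin(BIOLOGICS)][["patient_id", "dispense_date"]]
    prior = idx.merge(bio, on="patient_id")
    prior = prior[prior["dispense_date"] < prior["index_date"]]
    keep(~idx["patient_id"].isin(prior["patient_id"]), "no_prior_biologic")

    # ICS and LABA within the window anchored at the latest asthma diagnosis
    # on or before the index date; a fixed-dose combination satisfies both.
    anchor = (
        idx.merge(asthma, on="patient_id", how="left")
        .loc[lambda d: d["diagnosis_date"] <= d["index_date"]]
        .groupby("patient_id")["diagnosis_date"]
        .max()
    )
    ok_ids = set()
    window = pd.Timedelta(days=config.ics_laba_window_days)
    rx = disp[disp["drug_code"].isin(["ics", "laba", "ics_laba"])]
    for pid, grp in rx.groupby("patient_id", sort=False):
        a = anchor.get(pid)
        if a is None or pd.isna(a):
            continue
        in_window = grp[(grp["dispense_date"] >= a - window) & (grp["dispense_date"] <= a)]
        codes = set(in_window["drug_code"])
        if ("ics_laba" in codes) or ({"ics", "laba"} <= codes):
            ok_ids.add(pid)
    keep(idx["patient_id"].isin(ok_ids), "ics_laba_within_window")

    for rule in config.exclusions:
        cond = diag[diag["code"] == rule.condition][["patient_id", "diagnosis_date"]]
        merged = idx.merge(cond, on="patient_id")
        if rule.timing == "pre_index":
            bound = merged["index_date"]
        else:
            bound = merged["index_date"] + pd.Timedelta(days=config.followup_days)
        merged = merged[merged["diagnosis_date"] < bound]
        excluded = set(merged["patient_id"])
        if rule.biologics is not None:
            applicable = idx["index_biologic"].isin(rule.biologics)
        else:
            applicable = pd.Series(True, index=idx.index)
        keep(
            ~(idx["patient_id"].isin(excluded) & applicable),
            f"no_{rule.condition}",
        )

    switched_flags, switch_dates = [], []
    groups = dict(list(disp.groupby("patient_id", sort=False)))
    for row in idx.itertuples(index=False):
        sw, when = detect_switch(
            groups[row.patient_id],
            row.index_biologic,
            row.index_date,
            config.followup_days,
        )
        switched_flags.append(sw)
        switch_dates.append(when)

    cohort = idx[["patient_id", "index_date", "index_biologic"]].copy()
    cohort["switched"] = pd.Series(switched_flags, dtype=bool)
    cohort["switch_date"] = pd.Series(switch_dates, dtype="datetime64[ns]")
    attrition_df = pd.DataFrame(attrition, columns=["criterion", "n_remaining"])
    return CohortResult(cohort=cohort.reset_index(drop=True), attrition=attrition_df)
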