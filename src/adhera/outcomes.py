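"""Outcome phenotypes: exacerbations, HCRU, pharmacy costs, steroid exposure.

Exacerbations are claims-operational events of three types — asthma-related
hospital admissions, asthma-related ED visits, and qualifying oral/IV
corticosteroid courses (an OCS dispensing of 3–28 supplied days in the
calendar month of, or the month before, an asthma diagnosis; an IV steroid
in, or at most one month before, an asthma-diagnosis month).  Same-type
events closer than a merge window collapse into one.

HCRU covers all-cause and asthma-related admissions, hospital days (both
endpoints counted, truncated at the follow-up boundary) and ED visits.
Pharmacy costs are summed in JPY, including and excluding biologic lines; a
line is asthma-attributed when an asthma diagnosis falls in the same
calendar month (outpatient) or the line falls within an asthma-flagged
admission.  Oral/IV corticosteroid exposure is converted to prednisone
equivalents, with the daily average taken over exposed days only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ClaimsBundle

#: Prednisone-equivalent potency per mg of compound.
PREDNISONE_EQ = {
    "prednisolone": 1.0,
    "methylprednisolone": 1.25,
    "hydrocortisone": 0.25,
    "dexamethasone": 6.67,
}

EXACERBATION_TYPES = ("hospital_admission", "ed_visit", "ocs_iv_course")


@dataclass(frozen=True)
class OutcomesConfig:
    followup_days: int = 365
    ocs_min_days: int = 3
    ocs_max_days: int = 28
    merge_window_days: int = 7
    #: When True, an ED visit on the first day of an admission is not also
    #: counted as a separate ED exacerbation.
    dedupe_ed_into_admission: bool = False


def _month(ts) -> pd.Period:
    return pd.Period(ts, freq="M")


def _merge_events(days: list[int], window: int) -> list[int]:
    out: list[int] = []
    for d in sorted(days):
        if not out or d - out[-1] >= window:
            out.append(d)
    return out


def detect_exacerbations(
    bundle: ClaimsBundle,
    patient_id: str,
    index_date,
    config: OutcomesConfig = OutcomesConfig(),
) -> pd.DataFrame:
    """Exacerbation events for one patient within ``[index, index+followup)``.

    Returns a frame with ``event_type`` and ``day`` (offset from index).
    """
    enc = bundle.encounters
    disp = bundle.dispensings
    diag = bundle.diagnoses
    return _detect_exacerbations_pre(
        enc[enc["patient_id"] == patient_id],
        disp[disp["patient_id"] == patient_id],
        diag[diag["patient_id"] == patient_id],
        index_date,
        config,
    )


def _detect_exacerbations_pre(
    enc: pd.DataFrame,
    disp: pd.DataFrame,
    diag: pd.DataFrame,
    index_date,
    config: OutcomesConfig,
) -> pd.DataFrame:
    horizon = config.followup_days
    events: list[tuple[str, int]] = []

    offsets = (enc["start_date"] - index_date).dt.days
    in_window = (offsets >= 0) & (offsets < horizon)
    adm = enc[
        in_window
        & (enc["encounter_type"] == "inpatient_admission")
        & enc["asthma_related"]
    ]
    adm_days = _merge_events(
        list((adm["start_date"] - index_date).dt.days), config.merge_window_days
    )
    events += [("hospital_admission", d) for d in adm_days]

    ed = enc[in_window & (enc["encounter_type"] == "ed_visit") & enc["asthma_related"]]
    ed_days = list((ed["start_date"] - index_date).dt.days)
    if config.dedupe_ed_into_admission:
        adm_starts = set((adm["start_date"] - index_date).dt.days)
        ed_days = [d for d in ed_days if d not in adm_starts]
    events += [("ed_visit", d) for d in _merge_events(ed_days, config.merge_window_days)]

    asthma_months = {
        _month(d) for d in diag.loc[diag["code"] == "asthma", "diagnosis_date"]
    }
    d_off = (disp["dispense_date"] - index_date).dt.days
    d_in = (d_off >= 0) & (d_off < horizon)
    ocs = disp[
        d_in
        & (disp["drug_code"] == "ocs")
        & (disp["days_supplied"] >= config.ocs_min_days)
        & (disp["days_supplied"] <= config.ocs_max_days)
    ]
    iv = disp[d_in & (disp["drug_code"] == "iv_steroid")]
    course_days = []
    for df in (ocs, iv):
        for ts, off in zip(df["dispense_date"], (df["dispense_date"] - index_date).dt.days):
            m = _month(ts)
            # Qualifies when an asthma diagnosis falls in the same month or
            # the following month (i.e. the course is in the month of, or the
            # month before, a diagnosis).
            if m in asthma_months or (m + 1) in asthma_months:
                course_days.append(int(off))
    events += [
        ("ocs_iv_course", d)
        for d in _merge_events(course_days, config.merge_window_days)
    ]

    return pd.DataFrame(events, columns=["event_type", "day"]).sort_values(
        ["event_type", "day"], kind="stable"
    ).reset_index(drop=True)


def _hcru_one(enc: pd.DataFrame, index_date, horizon: int) -> dict:
    start_off = (enc["start_date"] - index_date).dt.days
    end_off = (enc["end_date"] - index_date).dt.days
    in_window = (start_off >= 0) & (start_off < horizon)
    out = {}
    for prefix, mask in (
        ("allcause", in_window),
        ("asthma", in_window & enc["asthma_related"]),
    ):
        adm = mask & (enc["encounter_type"] == "inpatient_admission")
        ed = mask & (enc["encounter_type"] == "ed_visit")
        # Inclusive day counting, truncated at the follow-up boundary.
        days = (np.minimum(end_off[adm], horizon) - np.maximum(start_off[adm], 0) + 1)
        out[f"{prefix}_admissions"] = int(adm.sum())
        out[f"{prefix}_hospital_days"] = int(days.sum()) if adm.any() else 0
        out[f"{prefix}_ed_visits"] = int(ed.sum())
    return out


def summarize_hcru(
    bundle: ClaimsBundle,
    cohort: pd.DataFrame,
    config: OutcomesConfig = OutcomesConfig(),
) -> pd.DataFrame:
    """All-cause and asthma-related admissions, hospital days and ED visits."""
    groups = dict(list(bundle.encounters.groupby("patient_id", sort=False)))
    empty = bundle.encounters.iloc[0:0]
    rows = []
    for row in cohort.itertuples(index=False):
        enc = groups.get(row.patient_id, empty)
        rows.append(
            {"patient_id": row.patient_id}
            | _hcru_one(enc, row.index_date, config.followup_days)
        )
    return pd.DataFrame(rows)


def _costs_one(
    disp: pd.DataFrame,
    diag: pd.DataFrame,
    enc: pd.DataFrame,
    index_date,
    horizon: int,
) -> dict:
    off = (disp["dispense_date"] - index_date).dt.days
    disp = disp[(off >= 0) & (off < horizon)]
    if disp.empty:
        return {
            "cost_allcause_incl_biologics": 0.0,
            "cost_allcause_excl_biologics": 0.0,
            "cost_asthma_incl_biologics": 0.0,
            "cost_asthma_excl_biologics": 0.0,
            "cost_biologics": 0.0,
        }
    asthma_months = {
        _month(d) for d in diag.loc[diag["code"] == "asthma", "diagnosis_date"]
    }
    months = disp["dispense_date"].dt.to_period("M")
    asthma_mask = months.isin(asthma_months).to_numpy()
    adm = enc[(enc["encounter_type"] == "inpatient_admission") & enc["asthma_related"]]
    for start, end in zip(adm["start_date"], adm["end_date"]):
        asthma_mask |= (
            (disp["dispense_date"] >= start) & (disp["dispense_date"] <= end)
        ).to_numpy()
    cost = disp["cost"].to_numpy(dtype=float)
    bio = disp["is_biologic"].to_numpy(dtype=bool)
    return {
        "cost_allcause_incl_biologics": float(cost.sum()),
        "cost_allcause_excl_biologics": float(cost[~bio].sum()),
        "cost_asthma_incl_biologics": float(cost[asthma_mask].sum()),
        "cost_asthma_excl_biologics": float(cost[asthma_mask & ~bio].sum()),
        "cost_biologics": float(cost[bio].sum()),
    }


def summarize_costs(
    bundle: ClaimsBundle,
    cohort: pd.DataFrame,
    config: OutcomesConfig = OutcomesConfig(),
    include_biologics: bool | None = None,
) -> pd.DataFrame:
    """Per-patient pharmacy costs (JPY), all-cause and asthma-related.

    Both the including- and excluding-biologics totals are always returned;
    ``include_biologics`` optionally narrows the output to one pair.
    """
    disp_groups = dict(list(bundle.dispensings.groupby("patient_id", sort=False)))
    diag_groups = dict(list(bundle.diagnoses.groupby("patient_id", sort=False)))
    enc_groups = dict(list(bundle.encounters.groupby("patient_id", sort=False)))
    rows = []
    for row in cohort.itertuples(index=False):
        rows.append(
            {"patient_id": row.patient_id}
            | _costs_one(
                disp_groups.get(row.patient_id, bundle.dispensings.iloc[0:0]),
                diag_groups.get(row.patient_id, bundle.diagnoses.iloc[0:0]),
                enc_groups.get(row.patient_id, bundle.encounters.iloc[0:0]),
                row.index_date,
                config.followup_days,
            )
        )
    out = pd.DataFrame(rows)
    if include_biologics is True:
        return out[
            ["patient_id", "cost_allcause_incl_biologics", "cost_asthma_incl_biologics"]
        ]
    if include_biologics is False:
        return out[
            ["patient_id", "cost_allcause_excl_biologics", "cost_asthma_excl_biologics"]
        ]
    return out


def steroid_exposure(
    dispensings: pd.DataFrame,
    index_date,
    config: OutcomesConfig = OutcomesConfig(),
) -> tuple[float, float, bool]:
    """Cumulative and daily-average oral/IV steroid use in prednisone mg.

    ``quantity`` is the dispensed compound mass in mg; each row's exposure
    spans its supplied days (at least one).  The daily average divides by
    the number of distinct exposed days, not the whole follow-up.
    """
    off = (dispensings["dispense_date"] - index_date).dt.days
    rows = dispensings[
        (off >= 0)
        & (off < config.followup_days)
        & dispensings["drug_code"].isin(["ocs", "iv_steroid"])
    ]
    total = 0.0
    exposed: set[int] = set()
    for row in rows.itertuples(index=False):
        factor = PREDNISONE_EQ.get(row.steroid_compound)
        if factor is None:
            warnings.warn(
                f"skipping steroid row with unknown compound {row.steroid_compound!r}",
                stacklevel=2,
            )
            continue
        total += float(row.quantity) * factor
        start = int((row.dispense_date - index_date).days)
        span = max(int(row.days_supplied), 1)
        exposed.update(range(start, min(start + span, config.followup_days)))
    if not exposed:
        return 0.0, 0.0, False
    return total, total / len(exposed), True


def build_outcome_table(
    bundle: ClaimsBundle,
    cohort: pd.DataFrame,
    config: OutcomesConfig = OutcomesConfig(),
) -> pd.DataFrame:
    """One row per patient: exacerbation counts, HCRU, costs, steroid use."""
    enc_groups = dict(list(bundle.encounters.groupby("patient_id", sort=False)))
    disp_groups = dict(list(bundle.dispensings.groupby("patient_id", sort=False)))
    diag_groups = dict(list(bundle.diagnoses.groupby("patient_id", sort=False)))
    e_empty = bundle.encounters.iloc[0:0]
    d_empty = bundle.dispensings.iloc[0:0]
    g_empty = bundle.diagnoses.iloc[0:0]

    rows = []
    for row in cohort.itertuples(index=False):
        enc = enc_groups.get(row.patient_id, e_empty)
        disp = disp_groups.get(row.patient_id, d_empty)
        diag = diag_groups.get(row.patient_id, g_empty)
        events = _detect_exacerbations_pre(enc, disp, diag, row.index_date, config)
        counts = events["event_type"].value_counts()
        rec = {"patient_id": row.patient_id}
        for etype in EXACERBATION_TYPES:
            rec[f"exac_{etype}"] = int(counts.get(etype, 0))
        rec["exac_total"] = int(len(events))
        rec |= _hcru_one(enc, row.index_date, config.followup_days)
        rec |= _costs_one(disp, diag, enc, row.index_date, config.followup_days)
        cum, daily, any_use = steroid_exposure(disp, row.index_date, config)
        rec["steroid_cumulative_mg"] = cum
        rec["steroid_daily_avg_mg"] = daily
        rec["steroid_any_use"] = any_use
        rows.append(rec)
    return pd.DataFrame(rows)


def stratify(
    outcome_table: pd.DataFrame,
    grouping: pd.Series,
    reference: str | None = None,
    order: list[str] | None = None,
) -> pd.DataFrame:
    """Group means with relative % differences versus a reference group.

    ``grouping`` maps each patient (aligned by ``patient_id``) to an
    adherence category or cluster label.  The reference defaults to
    ``"adherent"`` when present, else ``"A"``, else the first group in
    sorted order.  Relative difference is ``(mean_g − mean_ref)/mean_ref ×
    100``; it is NaN (undefined) where the reference mean is 0, and 0 for
    the reference itself.
    """
    df = outcome_table.copy()
    grouping = pd.Series(grouping)
    if grouping.index.equals(df.index) or len(grouping) == len(df):
        df["_group"] = np.asarray(grouping)
    else:
        raise ValueError("grouping must align with the outcome table")
    groups = order or sorted(df["_group"].dropna().unique())
    if reference is None:
        reference = (
            "adherent" if "adherent" in groups else ("A" if "A" in groups else groups[0])
        )
    value_cols = [
        c
        for c in df.columns
        if c not in ("patient_id", "_group") and pd.api.types.is_numeric_dtype(df[c])
    ]
    n_total = len(df)
    rows = []
    for g in groups:
        sub = df[df["_group"] == g]
        for col in value_cols:
            mean_g = float(sub[col].mean()) if len(sub) else np.nan
            ref_mean = float(df.loc[df["_group"] == reference, col].mean())
            if len(sub) == 0:
                rel = np.nan
            elif g == reference:
                rel = 0.0
            elif ref_mean == 0:
                rel = np.nan
            else:
                rel = (mean_g - ref_mean) / ref_mean * 100.0
            rows.append(
                {
                    "group": g,
                    "n": len(sub),
                    "share_pct": 100.0 * len(sub) / n_total,
                    "outcome": col,
                    "mean": mean_g,
                    "rel_diff_pct": rel,
                    "reference": reference,
                }
            )
    return pd.DataFrame(rows)
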