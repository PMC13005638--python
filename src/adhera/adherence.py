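"""Dosing-schedule-aware adherence measurement.

Given a patient's biologic dose dates (integer day offsets from the index
dose at day 0), this module computes:

* the dynamically reset expected schedule with a ±7-day buffer
  (:func:`track_schedule`),
* the medication possession ratio over 12 months (:func:`compute_mpr`),
  where each dose "possesses" its expected phase interval,
* the four-way adherence category from per-phase gap limits and dose-count
  minima, with treatment discontinuation taking precedence
  (:func:`classify_adherence`), and
* a per-bin binary adherence series used as the trajectory-model response
  (:func:`adherence_series`).

Omalizumab is prescribed Q2W or Q4W depending on body weight and IgE level,
neither of which appears in claims, so its mode is inferred from the realized
inter-dose gaps (:func:`infer_omalizumab_regimen`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regimens import DosingRegimen, get_regimen

CATEGORIES = (
    "adherent",
    "partially_adherent",
    "minimally_adherent",
    "discontinuation",
)
ADHERENT, PARTIAL, MINIMAL, DISCONTINUATION = range(4)


@dataclass(frozen=True)
class EngineConfig:
    """Tunables of the adherence engine.

    ``buffer_days`` is the dynamic buffer around each expected dose date.
    ``bin_days`` sets the series resolution (13 bins of 28 days over a
    365-day follow-up; the final day is ignored).  A bin counts as adherent
    when strictly more than ``bin_coverage_fraction`` of its days are
    possession-covered; the default majority rule (0.5) makes the series
    robust both to the ≤7-day possession slivers that buffer-compliant
    dosing slips create and to the partial carry-over a previous dose leaves
    in a skipped bin.  A fraction of 1.0 demands full coverage.
    """

    buffer_days: int = 7
    followup_days: int = 365
    bin_days: int = 28
    bin_coverage_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.buffer_days < 0:
            raise ValueError("buffer_days must be >= 0")
        if not 0.0 < self.bin_coverage_fraction <= 1.0:
            raise ValueError("bin_coverage_fraction must be in (0, 1]")

    @property
    def n_bins(self) -> int:
        return self.followup_days // self.bin_days


DEFAULT_CONFIG = EngineConfig()


def _clean_doses(dose_dates) -> np.ndarray:
    dates = np.asarray(dose_dates, dtype=np.int64)
    if dates.ndim != 1:
        raise ValueError("dose_dates must be one-dimensional")
    dates = np.sort(dates)
    unique = np.unique(dates)
    if len(unique) < len(dates):
        warnings.warn(
            "duplicate dose dates collapsed to single doses", stacklevel=3
        )
    return unique


def infer_omalizumab_regimen(dose_dates) -> str:
    """Infer the omalizumab prescription mode from realized inter-dose gaps.

    Returns ``"Q2W"`` when the median positive gap is below 21 days (the
    midpoint of the 14- and 28-day cycles), otherwise ``"Q4W"``; a single
    dose defaults to Q4W.  An empty dose list is an error.
    """
    dates = _clean_doses(dose_dates)
    if len(dates) == 0:
        raise ValueError("cannot infer a regimen from an empty dose list")
    if len(dates) == 1:
        return "Q4W"
    gaps = np.diff(dates)
    return "Q2W" if float(np.median(gaps)) < 21.0 else "Q4W"


def track_schedule(
    dose_dates, regimen: DosingRegimen, config: EngineConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Expected dose dates under dynamic schedule reset, plus buffer flags.

    The first dose anchors the schedule; the expected date of dose *k+1* is
    the *actual* date of dose *k* plus that position's phase interval.  A
    dose is on schedule when it falls within ``buffer_days`` of its expected
    date.
    """
    dates = _clean_doses(dose_dates)
    n = len(dates)
    expected = np.empty(n, dtype=np.int64)
    if n:
        expected[0] = dates[0]
        for k in range(1, n):
            expected[k] = dates[k - 1] + regimen.interval_after(k)
    on_schedule = np.abs(dates - expected) <= config.buffer_days
    return pd.DataFrame(
        {"dose": np.arange(1, n + 1), "date": dates, "expected": expected,
         "on_schedule": on_schedule}
    )


def coverage_intervals(
    dose_dates, regimen: DosingRegimen, config: EngineConfig = DEFAULT_CONFIG
) -> list[tuple[int, int]]:
    """Merged half-open day intervals of medication possession.

    Dose *k* covers ``[date, date + interval_after(k))``; overlapping
    intervals are unioned and everything is clipped to ``[0, followup)``.
    """
    dates = _clean_doses(dose_dates)
    merged: list[tuple[int, int]] = []
    for k, d in enumerate(dates, start=1):
        start = int(max(d, 0))
        end = int(min(d + regimen.interval_after(k), config.followup_days))
        if end <= start:
            continue
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def uncovered_intervals(
    dose_dates, regimen: DosingRegimen, config: EngineConfig = DEFAULT_CONFIG
) -> list[tuple[int, int]]:
    """Complement of :func:`coverage_intervals` within ``[0, followup)``."""
    covered = coverage_intervals(dose_dates, regimen, config)
    out = []
    cursor = 0
    for start, end in covered:
        if start > cursor:
            out.append((cursor, start))
        cursor = end
    if cursor < config.followup_days:
        out.append((cursor, config.followup_days))
    return out


def compute_mpr(
    dose_dates, regimen: DosingRegimen, config: EngineConfig = DEFAULT_CONFIG
) -> float:
    """Medication possession ratio: covered days / days in follow-up."""
    covered = sum(e - s for s, e in coverage_intervals(dose_dates, regimen, config))
    return covered / config.followup_days


def classify_many(
    dates: np.ndarray,
    lengths: np.ndarray,
    regimen: DosingRegimen,
    config: EngineConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    """Vectorized four-way classification of padded dose-date sequences.

    ``dates`` is an ``(N, M)`` integer array of sorted day offsets whose row
    *i* holds ``lengths[i]`` real doses (padding is ignored).  Returns
    category codes: 0 adherent, 1 partially adherent, 2 minimally adherent,
    3 treatment discontinuation.

    Rules, with discontinuation evaluated first:

    * discontinuation — the terminal gap from the last dose to the end of
      follow-up reaches the phase's discontinuation limit;
    * a gap opened by dose *k* is *prolonged* when it reaches that phase's
      gap limit (raw gaps; the scheduling buffer is not added, since the gap
      limits already span one full missed cycle);
    * adherent — no prolonged gap and at least the minimum dose count;
    * minimally adherent — a prolonged gap and at most
      ``adherent_min_doses − 1`` doses;
    * partially adherent — the remaining two combinations.
    """
    dates = np.asarray(dates, dtype=np.int64)
    lengths = np.asarray(lengths, dtype=np.int64)
    if dates.ndim != 2:
        raise ValueError("dates must be a 2-D padded matrix")
    n_rows, m = dates.shape
    if np.any(lengths < 1):
        raise ValueError("every sequence needs at least the index dose")

    if m > 1:
        gaps = dates[:, 1:] - dates[:, :-1]
        limits = np.array([regimen.gap_limit(k) for k in range(1, m)])
        valid = np.arange(m - 1)[None, :] < (lengths - 1)[:, None]
        prolonged = np.any((gaps >= limits[None, :]) & valid, axis=1)
    else:
        prolonged = np.zeros(n_rows, dtype=bool)

    last = dates[np.arange(n_rows), lengths - 1]
    term_limits = np.array(
        [regimen.terminal_limit(n) for n in range(1, int(lengths.max()) + 1)]
    )
    disc = (config.followup_days - last) >= term_limits[lengths - 1]

    codes = np.full(n_rows, PARTIAL, dtype=np.int64)
    codes[prolonged & (lengths <= regimen.minimal_max_doses)] = MINIMAL
    codes[~prolonged & (lengths >= regimen.adherent_min_doses)] = ADHERENT
    codes[disc] = DISCONTINUATION
    return codes


def classify_adherence(
    dose_dates, regimen: DosingRegimen, config: EngineConfig = DEFAULT_CONFIG
) -> str:
    """Four-way adherence category for one patient (see :func:`classify_many`)."""
    dates = _clean_doses(dose_dates)
    if len(dates) == 0:
        raise ValueError("classification requires at least the index dose")
    code = classify_many(dates[None, :], np.array([len(dates)]), regimen, config)[0]
    return CATEGORIES[code]


def adherence_series(
    dose_dates, regimen: DosingRegimen, config: EngineConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Binary per-bin adherence vector over ``n_bins`` bins of ``bin_days``.

    Bin *t* is 1 when strictly more than ``bin_coverage_fraction`` of its
    days are covered (with a fraction of 1.0, when it is fully covered).
    """
    n_days = config.n_bins * config.bin_days
    day_covered = np.zeros(n_days, dtype=bool)
    for start, end in coverage_intervals(dose_dates, regimen, config):
        day_covered[start : min(end, n_days)] = True
    per_bin = day_covered.reshape(config.n_bins, config.bin_days).sum(axis=1)
    if config.bin_coverage_fraction >= 1.0:
        return (per_bin == config.bin_days).astype(np.int8)
    return (per_bin > config.bin_coverage_fraction * config.bin_days).astype(np.int8)


@dataclass
class AdherenceSummary:
    """Everything the pipeline needs to know about one patient's adherence."""

    patient_id: str
    biologic: str
    regimen: str
    dose_dates: np.ndarray
    mpr: float
    on_schedule: np.ndarray
    category: str
    series: np.ndarray
    covered: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_doses(self) -> int:
        return len(self.dose_dates)


def summarize_patient(
    patient_id: str,
    dose_dates,
    biologic: str,
    config: EngineConfig = DEFAULT_CONFIG,
) -> AdherenceSummary:
    """Run the full engine for one patient."""
    dates = _clean_doses(dose_dates)
    mode = infer_omalizumab_regimen(dates) if biologic == "omalizumab" else None
    regimen = get_regimen(biologic, mode)
    schedule = track_schedule(dates, regimen, config)
    return AdherenceSummary(
        patient_id=patient_id,
        biologic=biologic,
        regimen=regimen.name,
        dose_dates=dates,
        mpr=compute_mpr(dates, regimen, config),
        on_schedule=schedule["on_schedule"].to_numpy(),
        category=classify_adherence(dates, regimen, config),
        series=adherence_series(dates, regimen, config),
        covered=coverage_intervals(dates, regimen, config),
    )


def summarize_cohort(
    bundle,
    cohort: pd.DataFrame,
    config: EngineConfig = DEFAULT_CONFIG,
) -> list[AdherenceSummary]:
    """Adherence summaries for every patient in a selected cohort.

    ``cohort`` needs ``patient_id``, ``index_date`` and ``index_biologic``
    columns (as produced by cohort selection).  Dose dates are the index
    biologic's dispensings within the follow-up window, as day offsets from
    the index date.
    """
    disp = bundle.dispensings
    groups = {
        key: grp
        for key, grp in disp.groupby(["patient_id", "drug_code"], sort=False)
    }
    out: list[AdherenceSummary] = []
    empty = disp.iloc[0:0]
    for row in cohort.itertuples(index=False):
        grp = groups.get((row.patient_id, row.index_biologic), empty)
        offsets = (grp["dispense_date"] - row.index_date).dt.days.to_numpy()
        offsets = offsets[(offsets >= 0) & (offsets < config.followup_days)]
        out.append(
            summarize_patient(row.patient_id, offsets, row.index_biologic, config)
        )
    return out


def summaries_to_frame(summaries: list[AdherenceSummary]) -> pd.DataFrame:
    """Flatten summaries to one row per patient (series as a 0/1 string)."""
    return pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in summaries],
            "biologic": [s.biologic for s in summaries],
            "regimen": [s.regimen for s in summaries],
            "n_doses": [s.n_doses for s in summaries],
            "mpr": [s.mpr for s in summaries],
            "category": [s.category for s in summaries],
            "series": ["".join(map(str, s.series)) for s in summaries],
        }
    )


def series_matrix(
    summaries: list[AdherenceSummary], drop_index_bin: bool = True
) -> np.ndarray:
    """Stack per-patient binary series into the N×T trajectory-model response.

    By default the first bin is dropped: the index dose is taken by
    definition, so the index cycle is adherent for every patient and carries
    no clustering information (a structurally constant column only distorts
    polynomial trajectory fits).
    """
    y = np.vstack([s.series for s in summaries]).astype(np.int8)
    return y[:, 1:] if drop_index_bin else y
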