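"""Synthetic severe-asthma claims cohorts with known adherence structure.

The generator emulates the statistical structure the downstream analysis
assumes, so that every pipeline stage is testable without access to any
proprietary claims source:

* five biologics with their approved dosing schedules (omalizumab patients
  are silently Q2W or Q4W, forcing the regimen-inference path),
* seven adherence archetypes — named after commonly observed 12-month
  trajectory morphologies (sustained adherence, early/late U-shaped dips,
  late and delayed stoppers, intermittent use, near-immediate drop-off) —
  mixed with realistic weights,
* exacerbation / encounter / cost event streams drawn from inhomogeneous
  Poisson processes whose rate is multiplied by an adherence rate ratio
  during possession-uncovered person-time, and
* per-line pharmacy costs in JPY with a biologic/non-biologic flag, so that
  cost summaries including biologics favor adherent patients while summaries
  excluding them reverse.

Dose realization: each patient draws one latent on/off adherence state per
28-day window from the archetype's probability curve, then walks the
protocol dosing schedule, keeping every dose slot whose protocol date falls
in an "on" window (realized at that date plus a uniform ±7-day jitter) and
skipping slots due in "off" windows.  Archetype curves are crisp canonical
step shapes (on-probability ≈ 0.995, off ≈ 0.002) whose transitions align
with benralizumab's Q8W cycle boundaries, so a lapse window corresponds to
whole skipped doses for every regimen; patient-level noise comes from rare
slot-level lapses and the dose-date jitter rather than from diffuse
per-window coin flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .adherence import EngineConfig, uncovered_intervals
from .io import BIOLOGICS, ClaimsBundle, empty_bundle
from .regimens import get_regimen

#: Latent adherence windows: 13 windows of 28 days span the 12-month follow-up.
WINDOW_DAYS = 28
N_WINDOWS = 13

ARCHETYPE_NAMES = (
    "highest",
    "early_u",
    "late_u",
    "late_stop",
    "intermittent",
    "delayed_stop",
    "lowest",
)


@dataclass(frozen=True)
class ArchetypeSpec:
    """One adherence archetype: a per-bin schedule-keeping probability curve."""

    name: str
    curve: tuple[float, ...]
    mixture_weight: float

    def __post_init__(self) -> None:
        if any(not 0.0 <= p <= 1.0 for p in self.curve):
            raise ValueError("curve probabilities must lie in [0, 1]")
        if self.mixture_weight < 0:
            raise ValueError("mixture weight must be >= 0")


def _step_curve(off_windows: tuple[int, ...], on: float = 0.995, off: float = 0.002) -> tuple[float, ...]:
    """A crisp trajectory: high on-probability except in the listed (1-based) windows."""
    curve = [on] * N_WINDOWS
    for w in off_windows:
        curve[w - 1] = off
    return tuple(curve)


def default_archetypes() -> tuple[ArchetypeSpec, ...]:
    """The packaged seven-archetype set.

    Each archetype is a canonical 12-month trajectory morphology: sustained
    adherence; a brief early U-shaped lapse; a longer late-stage U-shaped
    lapse; a late stopper; cyclic on/off ("intermittent") use; a delayed
    stopper who quits after about four months; and near-immediate drop-off.
    Off-phases sit on 8-week boundaries so they correspond to whole skipped
    doses on every approved schedule.  Mixture weights follow the relative
    cluster sizes reported for a large severe-asthma biologic cohort
    (~39/7/13/9/6/13/13%), and the implied mean possession ratios decrease
    from roughly 95% down to 10% in the archetype order below.
    """
    specs = [
        ArchetypeSpec("highest", _step_curve(()), 0.3915),
        ArchetypeSpec("early_u", _step_curve((3, 4)), 0.0703),
        ArchetypeSpec("late_u", _step_curve((7, 8, 9, 10)), 0.1328),
        ArchetypeSpec("late_stop", _step_curve((9, 10, 11, 12, 13)), 0.0897),
        ArchetypeSpec("intermittent", _step_curve((3, 4, 7, 8, 11, 12, 13)), 0.0612),
        ArchetypeSpec("delayed_stop", _step_curve((5, 6, 7, 8, 9, 10, 11, 12, 13)), 0.1252),
        ArchetypeSpec("lowest", _step_curve(tuple(range(2, 14))), 0.1292),
    ]
    total = sum(s.mixture_weight for s in specs)
    return tuple(replace(s, mixture_weight=s.mixture_weight / total) for s in specs)


@dataclass(frozen=True)
class OutcomeRatesSpec:
    """Event and cost parameters of the generative outcome model.

    Baseline rates are events per patient-year during possession-covered
    time; ``adherence_rate_ratio`` multiplies the asthma-related rates during
    uncovered time (> 1 means non-adherence is harmful).  Costs are JPY.
    """

    asthma_admission_rate: float = 0.04
    asthma_ed_rate: float = 0.08
    ocs_course_rate: float = 0.30
    other_admission_rate: float = 0.08
    other_ed_rate: float = 0.08
    adherence_rate_ratio: float = 2.0
    biologic_dose_cost: dict = field(
        default_factory=lambda: {
            "benralizumab": 350_000.0,
            "mepolizumab": 170_000.0,
            "dupilumab": 66_000.0,
            "omalizumab": 45_000.0,
            "tezepelumab": 150_000.0,
        }
    )
    maintenance_monthly_cost: float = 8_000.0
    admission_pharmacy_cost: float = 30_000.0
    ed_pharmacy_cost: float = 5_000.0
    ocs_course_cost: float = 2_000.0
    #: Additional acute pharmacotherapy dispensed with an OCS burst
    #: (relievers, antibiotics, escalated controllers).
    exacerbation_care_cost: float = 12_000.0

    def __post_init__(self) -> None:
        if self.adherence_rate_ratio <= 0:
            raise ValueError("adherence_rate_ratio must be > 0")
        for r in (
            self.asthma_admission_rate,
            self.asthma_ed_rate,
            self.ocs_course_rate,
            self.other_admission_rate,
            self.other_ed_rate,
        ):
            if r < 0:
                raise ValueError("rates must be >= 0")


#: Biologic mix of a large Japanese severe-asthma cohort (normalized shares).
DEFAULT_BIOLOGIC_MIX = {
    "benralizumab": 1080 / 2850,
    "mepolizumab": 837 / 2850,
    "dupilumab": 406 / 2850,
    "omalizumab": 375 / 2850,
    "tezepelumab": 152 / 2850,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything the generator needs; a fixed seed makes output deterministic."""

    n_patients: int = 2500
    biologic_mix: dict = field(default_factory=lambda: dict(DEFAULT_BIOLOGIC_MIX))
    archetypes: tuple[ArchetypeSpec, ...] = field(default_factory=default_archetypes)
    outcome_rates: OutcomeRatesSpec = field(default_factory=OutcomeRatesSpec)
    switch_probability: float = 0.1284
    exclusion_probabilities: dict = field(default_factory=dict)
    jitter_days: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.biologic_mix.values()), 1.0):
            raise ValueError("biologic mix proportions must sum to 1")
        if not np.isclose(sum(a.mixture_weight for a in self.archetypes), 1.0):
            raise ValueError("archetype mixture weights must sum to 1")
        if not 0.0 <= self.switch_probability <= 1.0:
            raise ValueError("switch probability must lie in [0, 1]")
        if set(self.biologic_mix) - BIOLOGICS:
            raise ValueError("unknown biologic in mix")


def gbtm_recovery_config(n_patients: int = 2500, seed: int = 0) -> GeneratorConfig:
    """The packaged trajectory-recovery cohort: no switching, no exclusions.

    Turning switching off realizes the non-switcher analysis set directly at
    the configured size, which is the set trajectory modeling operates on.
    """
    return GeneratorConfig(
        n_patients=n_patients,
        switch_probability=0.0,
        exclusion_probabilities={},
        seed=seed,
    )


def load_generator_config(path) -> GeneratorConfig:
    """Read a ``generator.yaml`` into a :class:`GeneratorConfig`."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for key in ("n_patients", "switch_probability", "jitter_days", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    if "biologic_mix" in raw:
        kwargs["biologic_mix"] = dict(raw["biologic_mix"])
    if "exclusion_probabilities" in raw:
        kwargs["exclusion_probabilities"] = dict(raw["exclusion_probabilities"])
    if "outcome_rates" in raw:
        kwargs["outcome_rates"] = OutcomeRatesSpec(**raw["outcome_rates"])
    if "archetypes" in raw:
        kwargs["archetypes"] = tuple(
            ArchetypeSpec(a["name"], tuple(a["curve"]), a["mixture_weight"])
            for a in raw["archetypes"]
        )
    return GeneratorConfig(**kwargs)


def simulate_dose_days(
    rng: np.random.Generator,
    regimen,
    bin_states: np.ndarray,
    jitter_days: int,
    followup_days: int = 365,
    bin_days: int = WINDOW_DAYS,
) -> np.ndarray:
    """Walk the expected schedule, taking doses due in "on" windows.

    The index dose at day 0 is always taken.  Each subsequent dose slot sits
    on the *protocol* calendar (expected intervals accumulated from day 0);
    the slot is kept when its protocol date falls in an "on" window, and a
    kept slot's realized dispensing date is the protocol date plus a uniform
    ±``jitter_days`` slip.  Anchoring slots to the protocol calendar keeps a
    patient's latent behavior tied to therapy months — individual slips do
    not accumulate into a drift of the whole schedule — while the jitter
    still exercises the engine's dynamic-buffer logic downstream.
    """
    doses = [0]
    slot = 1
    protocol = regimen.interval_after(1)
    while protocol < followup_days:
        b = min(protocol // bin_days, len(bin_states) - 1)
        if bin_states[b]:
            d = protocol + (
                int(rng.integers(-jitter_days, jitter_days + 1)) if jitter_days else 0
            )
            if doses[-1] < d < followup_days:
                doses.append(d)
        slot += 1
        protocol += regimen.interval_after(slot)
    return np.asarray(doses, dtype=np.int64)


def _poisson_event_days(
    rng: np.random.Generator,
    intervals: list[tuple[int, int]],
    daily_rate: float,
) -> list[int]:
    days: list[int] = []
    for start, end in intervals:
        n = rng.poisson(daily_rate * (end - start))
        if n:
            days.extend(int(x) for x in rng.integers(start, end, size=n))
    return sorted(days)


_EXCLUSION_TIMING = {
    # condition -> (applies to which index biologics or None for all,
    #              "pre_index" or "pre_end")
    "lung_malignancy": (None, "pre_index"),
    "respiratory_tuberculosis": (None, "pre_index"),
    "cystic_fibrosis": (None, "pre_index"),
    "hypereosinophilic_syndrome": (None, "pre_end"),
    "egpa": (None, "pre_end"),
    "chronic_spontaneous_urticaria": ({"dupilumab", "omalizumab"}, "pre_index"),
    "atopic_dermatitis": ({"dupilumab"}, "pre_index"),
    "prurigo_nodularis": ({"dupilumab"}, "pre_index"),
    "seasonal_allergic_rhinitis": ({"omalizumab"}, "pre_index"),
    "crswnp": ({"mepolizumab", "dupilumab"}, "pre_index"),
}


def generate_cohort(
    config: GeneratorConfig, with_truth: bool = False
) -> ClaimsBundle | tuple[ClaimsBundle, pd.DataFrame]:
    """Generate a claims bundle (optionally with the generating ground truth).

    Every patient has an index biologic dispensing at day 0, at least 30
    days of enrollment before the index date and at least 365 days after.
    With ``with_truth=True`` a second return value records each patient's
    archetype, biologic, omalizumab mode and index date.
    """
    rng = np.random.default_rng(config.seed)
    engine = EngineConfig(buffer_days=config.jitter_days or 7)
    rates = config.outcome_rates

    biologics = list(config.biologic_mix)
    bio_p = np.array([config.biologic_mix[b] for b in biologics])
    arch_p = np.array([a.mixture_weight for a in config.archetypes])

    patients, dispensings, diagnoses, encounters = [], [], [], []
    truth = []

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        index_date = pd.Timestamp("2016-01-01") + pd.Timedelta(
            days=int(rng.integers(0, 2200))
        )
        age = int(np.clip(rng.normal(64, 14), 18, 95))
        patients.append(
            {
                "patient_id": pid,
                "birth_year": index_date.year - age,
                "sex": "female" if rng.random() < 0.61 else "male",
                "enrollment_start": index_date
                - pd.Timedelta(days=30 + int(rng.integers(0, 300))),
                "enrollment_end": index_date
                + pd.Timedelta(days=365 + int(rng.integers(0, 200))),
                "smoking_status": str(
                    rng.choice(
                        ["current_former", "never", "unknown"], p=[0.14, 0.24, 0.62]
                    )
                ),
            }
        )

        biologic = biologics[int(rng.choice(len(biologics), p=bio_p))]
        arch = config.archetypes[int(rng.choice(len(config.archetypes), p=arch_p))]
        oma_mode = str(rng.choice(["Q2W", "Q4W"])) if biologic == "omalizumab" else None
        regimen = get_regimen(biologic, oma_mode)

        bin_states = rng.random(N_WINDOWS) < np.asarray(arch.curve)
        bin_states[0] = True  # the index dose is taken by definition
        dose_days = simulate_dose_days(
            rng, regimen, bin_states, config.jitter_days, engine.followup_days
        )
        truth.append(
            {
                "patient_id": pid,
                "biologic": biologic,
                "omalizumab_mode": oma_mode,
                "archetype": arch.name,
                "index_date": index_date,
                "n_doses": len(dose_days),
            }
        )

        def day(offset: int) -> pd.Timestamp:
            return index_date + pd.Timedelta(days=int(offset))

        # Pre-index qualification: asthma diagnosis, ICS+LABA in the window.
        dx_offset = -int(rng.integers(1, 60))
        diagnoses.append(
            {"patient_id": pid, "code": "asthma", "diagnosis_date": day(dx_offset)}
        )
        dispensings.append(
            {
                "patient_id": pid,
                "drug_code": "ics_laba",
                "dispense_date": day(dx_offset - int(rng.integers(0, 30))),
                "days_supplied": 30,
                "quantity": 1.0,
                "cost": rates.maintenance_monthly_cost,
                "is_biologic": False,
                "steroid_compound": "none",
            }
        )

        # Biologic dose lines.
        for d in dose_days:
            dispensings.append(
                {
                    "patient_id": pid,
                    "drug_code": biologic,
                    "dispense_date": day(d),
                    "days_supplied": 0,
                    "quantity": 1.0,
                    "cost": rates.biologic_dose_cost[biologic],
                    "is_biologic": True,
                    "steroid_compound": "none",
                }
            )

        # Monthly maintenance refills, each with an outpatient asthma diagnosis.
        for m in range(12):
            refill = 15 + 30 * m
            dispensings.append(
                {
                    "patient_id": pid,
                    "drug_code": "ics_laba",
                    "dispense_date": day(refill),
                    "days_supplied": 30,
                    "quantity": 1.0,
                    "cost": rates.maintenance_monthly_cost,
                    "is_biologic": False,
                    "steroid_compound": "none",
                }
            )
            diagnoses.append(
                {"patient_id": pid, "code": "asthma", "diagnosis_date": day(refill)}
            )

        covered_rate = 1.0
        uncov_rate = rates.adherence_rate_ratio
        uncov = uncovered_intervals(dose_days, regimen, engine)
        cov = []
        cursor = 0
        for s, e in uncov:
            if s > cursor:
                cov.append((cursor, s))
            cursor = e
        if cursor < engine.followup_days:
            cov.append((cursor, engine.followup_days))

        def draw(base_rate: float, modulated: bool) -> list[int]:
            daily = base_rate / 365.0
            if not modulated:
                return _poisson_event_days(
                    rng, [(0, engine.followup_days)], daily
                )
            return sorted(
                _poisson_event_days(rng, cov, daily * covered_rate)
                + _poisson_event_days(rng, uncov, daily * uncov_rate)
            )

        for d in draw(rates.asthma_admission_rate, True):
            los = 1 + int(rng.poisson(3.0))
            end = min(d + los - 1, engine.followup_days)
            encounters.append(
                {
                    "patient_id": pid,
                    "encounter_type": "inpatient_admission",
                    "start_date": day(d),
                    "end_date": day(end),
                    "asthma_related": True,
                    "planned": False,
                }
            )
            diagnoses.append(
                {"patient_id": pid, "code": "asthma", "diagnosis_date": day(d)}
            )
            dispensings.append(
                {
                    "patient_id": pid,
                    "drug_code": "other",
                    "dispense_date": day(min(d + 1, end)),
                    "days_supplied": 0,
                    "quantity": 1.0,
                    "cost": rates.admission_pharmacy_cost,
                    "is_biologic": False,
                    "steroid_compound": "none",
                }
            )
            if rng.random() < 0.5:  # IV steroid during the admission
                dispensings.append(
                    {
                        "patient_id": pid,
                        "drug_code": "iv_steroid",
                        "dispense_date": day(d),
                        "days_supplied": 1,
                        "quantity": 125.0,
                        "cost": 3_000.0,
                        "is_biologic": False,
                        "steroid_compound": "methylprednisolone",
                    }
                )

        for d in draw(rates.asthma_ed_rate, True):
            encounters.append(
                {
                    "patient_id": pid,
                    "encounter_type": "ed_visit",
                    "start_date": day(d),
                    "end_date": day(d),
                    "asthma_related": True,
                    "planned": False,
                }
            )
            diagnoses.append(
                {"patient_id": pid, "code": "asthma", "diagnosis_date": day(d)}
            )
            dispensings.append(
                {
                    "patient_id": pid,
                    "drug_code": "other",
                    "dispense_date": day(d),
                    "days_supplied": 0,
                    "quantity": 1.0,
                    "cost": rates.ed_pharmacy_cost,
                    "is_biologic": False,
                    "steroid_compound": "none",
                }
            )

        for d in draw(rates.ocs_course_rate, True):
            supplied = int(rng.integers(3, 15))
            dispensings.append(
                {
                    "patient_id": pid,
                    "drug_code": "ocs",
                    "dispense_date": day(d),
                    "days_supplied": supplied,
                    "quantity": 30.0 * supplied,
                    "cost": rates.ocs_course_cost,
                    "is_biologic": False,
                    "steroid_compound": "prednisolone",
                }
            )
            diagnoses.append(
                {"patient_id": pid, "code": "asthma", "diagnosis_date": day(d)}
            )
            dispensings.append(
                {
                    "patient_id": pid,
                    "drug_code": "other",
                    "dispense_date": day(d),
                    "days_supplied": 0,
                    "quantity": 1.0,
                    "cost": rates.exacerbation_care_cost,
                    "is_biologic": False,
                    "steroid_compound": "none",
                }
            )

        for d in draw(rates.other_admission_rate, False):
            los = 1 + int(rng.poisson(4.0))
            encounters.append(
                {
                    "patient_id": pid,
                    "encounter_type": "inpatient_admission",
                    "start_date": day(d),
                    "end_date": day(min(d + los - 1, engine.followup_days)),
                    "asthma_related": False,
                    "planned": bool(rng.random() < 0.3),
                }
            )
        for d in draw(rates.other_ed_rate, False):
            encounters.append(
                {
                    "patient_id": pid,
                    "encounter_type": "ed_visit",
                    "start_date": day(d),
                    "end_date": day(d),
                    "asthma_related": False,
                    "planned": False,
                }
            )

        # Exclusion-condition injections (off by default).
        for condition, prob in config.exclusion_probabilities.items():
            if rng.random() < prob:
                _, timing = _EXCLUSION_TIMING[condition]
                offset = (
                    -int(rng.integers(30, 400))
                    if timing == "pre_index"
                    else int(rng.integers(0, 365))
                )
                diagnoses.append(
                    {
                        "patient_id": pid,
                        "code": condition,
                        "diagnosis_date": day(offset),
                    }
                )

    bundle = empty_bundle()
    if patients:
        bundle = ClaimsBundle(
            patients=pd.DataFrame(patients),
            dispensings=pd.DataFrame(dispensings),
            diagnoses=pd.DataFrame(diagnoses),
            encounters=pd.DataFrame(encounters),
        )
    if config.switch_probability > 0 and config.n_patients > 0:
        bundle = inject_switchers(
            bundle, config.switch_probability, seed=config.seed + 1
        )
    if with_truth:
        return bundle, pd.DataFrame(
            truth,
            columns=[
                "patient_id",
                "biologic",
                "omalizumab_mode",
                "archetype",
                "index_date",
                "n_doses",
            ],
        )
    return bundle


def inject_switchers(
    bundle: ClaimsBundle, switch_probability: float, seed: int = 0
) -> ClaimsBundle:
    """Replace some patients' biologic with a second one after a random day.

    Selected patients keep their index biologic's dispensings up to the
    switch day, then receive the new biologic on its own expected schedule
    for the rest of follow-up.  The switch is recoverable downstream from
    the dispensing stream alone.
    """
    if not 0.0 <= switch_probability <= 1.0:
        raise ValueError("switch probability must lie in [0, 1]")
    if switch_probability == 0.0:
        return bundle
    rng = np.random.default_rng(seed)
    disp = bundle.dispensings.copy()
    bio = disp[disp["is_biologic"]]
    drop_rows: list[int] = []
    new_rows: list[dict] = []
    for pid, grp in bio.groupby("patient_id", sort=True):
        if rng.random() >= switch_probability:
            continue
        grp = grp.sort_values("dispense_date")
        index_date = grp["dispense_date"].iloc[0]
        index_biologic = grp["drug_code"].iloc[0]
        switch_day = int(rng.integers(45, 320))
        offsets = (grp["dispense_date"] - index_date).dt.days
        drop_rows.extend(grp.index[offsets > switch_day].tolist())
        new_biologic = str(
            rng.choice(sorted(BIOLOGICS - {index_biologic}))
        )
        regimen = get_regimen(
            new_biologic, "Q4W" if new_biologic == "omalizumab" else None
        )
        cost = OutcomeRatesSpec().biologic_dose_cost[new_biologic]
        d = switch_day + int(rng.integers(1, 15))
        k = 1
        while d < 365:
            new_rows.append(
                {
                    "patient_id": pid,
                    "drug_code": new_biologic,
                    "dispense_date": index_date + pd.Timedelta(days=d),
                    "days_supplied": 0,
                    "quantity": 1.0,
                    "cost": cost,
                    "is_biologic": True,
                    "steroid_compound": "none",
                }
            )
            d += regimen.interval_after(k)
            k += 1
    disp = disp.drop(index=drop_rows)
    if new_rows:
        disp = pd.concat([disp, pd.DataFrame(new_rows)], ignore_index=True)
    disp = disp.sort_values(["patient_id", "dispense_date"], kind="stable").reset_index(
        drop=True
    )
    return ClaimsBundle(bundle.patients, disp, bundle.diagnoses, bundle.encounters)
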