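"""Independent brute-force transcription of the four-category dosing rules.

Each biologic's function below hard-codes the published gap windows, dose
counts and end-of-follow-up discontinuation thresholds literally, with no
shared code or threshold tables from the package: it exists solely to
cross-check the engine's classifier.  Scalar functions handle one dose
sequence; ``classify_grid`` is the same transcription vectorized over a
padded matrix for exhaustive enumeration.
"""

from __future__ import annotations

import numpy as np

FOLLOWUP = 365


def _cat(disc: bool, prolonged: bool, enough_doses: bool, few_doses: bool) -> str:
    if disc:
        return "discontinuation"
    if prolonged and few_doses:
        return "minimally_adherent"
    if not prolonged and enough_doses:
        return "adherent"
    return "partially_adherent"


def benralizumab(dates, followup: int = FOLLOWUP) -> str:
    dates = list(dates)
    n = len(dates)
    gaps = [b - a for a, b in zip(dates, dates[1:])]
    prolonged = False
    for i, g in enumerate(gaps):  # gap i is between dose i+1 and dose i+2
        window = 56 if i == 0 else (84 if i == 1 else 112)
        if g >= window:
            prolonged = True
    end_gap = followup - dates[-1]
    disc_limit = 112 if n == 1 else (140 if n == 2 else 168)
    return _cat(end_gap >= disc_limit, prolonged, n > 4, n <= 4)


def _q2w_like(dates, followup: int) -> str:
    dates = list(dates)
    n = len(dates)
    prolonged = any(b - a >= 28 for a, b in zip(dates, dates[1:]))
    return _cat(followup - dates[-1] >= 42, prolonged, n >= 13, n < 13)


def _q4w_like(dates, followup: int) -> str:
    dates = list(dates)
    n = len(dates)
    prolonged = any(b - a >= 56 for a, b in zip(dates, dates[1:]))
    return _cat(followup - dates[-1] >= 84, prolonged, n >= 7, n < 7)


def dupilumab(dates, followup: int = FOLLOWUP) -> str:
    return _q2w_like(dates, followup)


def mepolizumab(dates, followup: int = FOLLOWUP) -> str:
    return _q4w_like(dates, followup)


def tezepelumab(dates, followup: int = FOLLOWUP) -> str:
    return _q4w_like(dates, followup)


def omalizumab_q2w(dates, followup: int = FOLLOWUP) -> str:
    return _q2w_like(dates, followup)


def omalizumab_q4w(dates, followup: int = FOLLOWUP) -> str:
    return _q4w_like(dates, followup)


ORACLES = {
    "benralizumab": benralizumab,
    "dupilumab": dupilumab,
    "mepolizumab": mepolizumab,
    "tezepelumab": tezepelumab,
    "omalizumab_q2w": omalizumab_q2w,
    "omalizumab_q4w": omalizumab_q4w,
}


def classify_grid(dates: np.ndarray, lengths: np.ndarray, drug: str,
                  followup: int = FOLLOWUP) -> np.ndarray:
    """Vectorized oracle over a padded (N, M) matrix of sorted dose days.

    Returns category names aligned with the scalar functions.
    """
    dates = np.asarray(dates)
    lengths = np.asarray(lengths)
    n_rows, m = dates.shape
    gaps = dates[:, 1:] - dates[:, :-1] if m > 1 else np.zeros((n_rows, 0), int)
    gap_valid = np.arange(m - 1)[None, :] < (lengths - 1)[:, None]

    if drug == "benralizumab":
        windows = np.where(
            np.arange(m - 1) == 0, 56, np.where(np.arange(m - 1) == 1, 84, 112)
        )
        few = lengths <= 4
        enough = lengths > 4
        disc_limits = np.where(lengths == 1, 112, np.where(lengths == 2, 140, 168))
    elif drug in ("dupilumab", "omalizumab_q2w"):
        windows = np.full(max(m - 1, 1), 28)[: m - 1]
        few = lengths < 13
        enough = lengths >= 13
        disc_limits = np.full(n_rows, 42)
    elif drug in ("mepolizumab", "tezepelumab", "omalizumab_q4w"):
        windows = np.full(max(m - 1, 1), 56)[: m - 1]
        few = lengths < 7
        enough = lengths >= 7
        disc_limits = np.full(n_rows, 84)
    else:
        raise KeyError(drug)

    prolonged = np.any((gaps >= windows[None, :]) & gap_valid, axis=1)
    last = dates[np.arange(n_rows), lengths - 1]
    disc = (followup - last) >= disc_limits

    out = np.where(
        disc,
        "discontinuation",
        np.where(
            prolonged & few,
            "minimally_adherent",
            np.where(~prolonged & enough, "adherent", "partially_adherent"),
        ),
    )
    return out
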