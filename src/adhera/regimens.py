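"""Approved dosing schedules and gap/dose-count thresholds for the five biologics.

Each :class:`DosingRegimen` carries three pieces of information:

* the expected dose-to-dose interval as a function of dose position
  (benralizumab is Q4W for the first three doses, then Q8W; dupilumab Q2W;
  mepolizumab and tezepelumab Q4W; omalizumab Q2W or Q4W depending on the
  individual prescription),
* the per-phase gap limit separating "within window" from "prolonged" gaps,
* the terminal-gap limit that marks treatment discontinuation at the end of
  the 12-month follow-up, and the dose-count cut separating the adherent from
  the minimally adherent range.

Gap limits equal two missed cycles of the phase interval (e.g. 56 days for a
Q4W phase); terminal-discontinuation limits equal three missed cycles, except
for benralizumab where they are phase-shifted (112/140/168 days after doses
1/2/≥3).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class DosingRegimen:
    """Expected dosing schedule plus classification thresholds for one biologic.

    ``intervals`` lists the expected gap in days opened by each dose position
    (1-based); the last entry repeats indefinitely.  ``gap_limits`` and
    ``terminal_limits`` are aligned the same way: ``gap_limits[k-1]`` bounds
    the gap between dose *k* and dose *k+1*, and ``terminal_limits[n-1]`` is
    the discontinuation threshold for the gap from the *n*-th (last observed)
    dose to the end of follow-up.
    """

    name: str
    intervals: tuple[int, ...]
    gap_limits: tuple[int, ...]
    terminal_limits: tuple[int, ...]
    adherent_min_doses: int

    def __post_init__(self) -> None:
        if any(i <= 0 for i in self.intervals):
            raise ValueError("intervals must be positive")
        for g, t in zip(self.gap_limits, self.terminal_limits):
            if t <= g:
                raise ValueError("discontinuation limit must exceed the gap limit")

    def _phase(self, seq: tuple[int, ...], position: int) -> int:
        if position < 1:
            raise ValueError("dose positions are 1-based")
        return seq[min(position, len(seq)) - 1]

    def interval_after(self, position: int) -> int:
        """Expected days from dose ``position`` to the next dose."""
        return self._phase(self.intervals, position)

    def gap_limit(self, position: int) -> int:
        """Gaps from dose ``position`` of at least this many days are prolonged."""
        return self._phase(self.gap_limits, position)

    def terminal_limit(self, n_doses: int) -> int:
        """Terminal gap (last dose to end of follow-up) marking discontinuation."""
        return self._phase(self.terminal_limits, n_doses)

    @property
    def minimal_max_doses(self) -> int:
        """Largest dose count compatible with the minimally adherent category."""
        return self.adherent_min_doses - 1


BENRALIZUMAB = DosingRegimen(
    name="benralizumab",
    intervals=(28, 28, 56),
    gap_limits=(56, 84, 112),
    terminal_limits=(112, 140, 168),
    adherent_min_doses=5,  # "> 4 doses"
)

DUPILUMAB = DosingRegimen(
    name="dupilumab",
    intervals=(14,),
    gap_limits=(28,),
    terminal_limits=(42,),
    adherent_min_doses=13,
)

MEPOLIZUMAB = DosingRegimen(
    name="mepolizumab",
    intervals=(28,),
    gap_limits=(56,),
    terminal_limits=(84,),
    adherent_min_doses=7,
)

TEZEPELUMAB = DosingRegimen(
    name="tezepelumab",
    intervals=(28,),
    gap_limits=(56,),
    terminal_limits=(84,),
    adherent_min_doses=7,
)

OMALIZUMAB_Q2W = DosingRegimen(
    name="omalizumab_q2w",
    intervals=(14,),
    gap_limits=(28,),
    terminal_limits=(42,),
    adherent_min_doses=13,
)

OMALIZUMAB_Q4W = DosingRegimen(
    name="omalizumab_q4w",
    intervals=(28,),
    gap_limits=(56,),
    terminal_limits=(84,),
    adherent_min_doses=7,
)

#: All concrete regimens (omalizumab appears twice, once per prescription mode).
REGIMENS: dict[str, DosingRegimen] = {
    r.name: r
    for r in (
        BENRALIZUMAB,
        DUPILUMAB,
        MEPOLIZUMAB,
        TEZEPELUMAB,
        OMALIZUMAB_Q2W,
        OMALIZUMAB_Q4W,
    )
}


def get_regimen(biologic: str, omalizumab_mode: str | None = None) -> DosingRegimen:
    """Resolve a biologic name (plus omalizumab Q2W/Q4W mode) to its regimen."""
    if biologic == "omalizumab":
        if omalizumab_mode not in ("Q2W", "Q4W"):
            raise ValueError("omalizumab requires an inferred mode, 'Q2W' or 'Q4W'")
        return OMALIZUMAB_Q2W if omalizumab_mode == "Q2W" else OMALIZUMAB_Q4W
    try:
        return REGIMENS[biologic]
    except KeyError:
        raise KeyError(f"unknown biologic {biologic!r}") from None
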