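"""Rule-based controllers for variable-start ovarian stimulation.

Two protocols are implemented, both evaluated once per simulated day (at a
fixed morning check time) and both sharing the stopping criterion that
stimulation ends once at least three growing follicles have reached 18 mm:

* **Late-follicular start** — daily hMG begins when at least one follicle
  measures 14 mm; 150 IU/day for the first six administrations, 225 IU/day
  thereafter.  Ovulation of the dominant follicle during stimulation is
  permitted (and expected).
* **Luteal start** — daily 225 IU hMG begins at the first morning check
  falling 1–3 days after an ovulation, provided a growing follicle smaller
  than 8 mm exists.  Ovulation suppression during treatment is emergent
  (high luteal P4), not enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .config import ProtocolParams
from .follicles import Follicle
from .pk import DoseEvent


class ProtocolPhase(str, Enum):
    WAITING = "waiting"
    STIMULATING = "stimulating"
    STOPPED = "stopped"


@dataclass
class ProtocolState:
    """Controller state: phase, start time, and the doses emitted so far."""

    phase: ProtocolPhase = ProtocolPhase.WAITING
    t_start: float | None = None
    day_index: int = -1
    emitted_doses: list[DoseEvent] = field(default_factory=list)
    missed_windows: int = 0  # luteal: post-ovulation windows that passed unmet


def stopping_criterion(follicles: list[Follicle],
                       params: ProtocolParams) -> bool:
    """True once at least ``stop_n_follicles`` growing follicles have
    diameter >= ``stop_size`` (default: 3 follicles at 18 mm)."""
    n = sum(1 for f in follicles
            if f.active and f.size >= params.stop_size)
    return n >= params.stop_n_follicles


class StimulationProtocol:
    """Base class: daily evaluation cadence, dose bookkeeping, stop rule.

    ``arm_time`` delays the controller so the simulated cycle is established
    before a trigger is considered.
    """

    name = "base"

    def __init__(self, params: ProtocolParams, arm_time: float = 35.0):
        self.params = params
        self.arm_time = arm_time
        self.state = ProtocolState()

    # -- hooks ------------------------------------------------------------
    def _should_start(self, t: float, follicles: list[Follicle],
                      t_last_ovulation: float | None) -> bool:
        raise NotImplementedError

    def _dose_for_day(self, day_index: int) -> float:
        raise NotImplementedError

    # -- daily evaluation --------------------------------------------------
    def daily_check(self, t: float, follicles: list[Follicle],
                    t_last_ovulation: float | None) -> DoseEvent | None:
        """Evaluate the controller at the daily check time ``t``.

        Idempotent within a day: a repeated call at the same day index does
        not emit a second dose.
        """
        st = self.state
        if st.phase is ProtocolPhase.STOPPED or t < self.arm_time:
            return None
        if st.phase is ProtocolPhase.WAITING:
            if self._should_start(t, follicles, t_last_ovulation):
                st.phase = ProtocolPhase.STIMULATING
                st.t_start = t
                st.day_index = -1
            else:
                return None
        # stimulating: stop check precedes dosing (census on the morning the
        # criterion is met; that morning receives no further dose)
        if stopping_criterion(follicles, self.params):
            st.phase = ProtocolPhase.STOPPED
            return None
        day_index = int(round(t - st.t_start))
        if day_index == st.day_index:   # already dosed today
            return None
        st.day_index = day_index
        dose = DoseEvent(t_admin=t, dose=self._dose_for_day(day_index))
        st.emitted_doses.append(dose)
        return dose

    @property
    def duration(self) -> int:
        """Treatment duration in days = number of daily administrations."""
        return len(self.state.emitted_doses)

    @property
    def complete(self) -> bool:
        return self.state.phase is ProtocolPhase.STOPPED


class LateFollicularProtocol(StimulationProtocol):
    """Stimulation initiated in the late follicular phase: daily hMG begins
    when a follicle first measures 14 mm; 150 IU/day, escalated to
    225 IU/day after six days.

    The start is edge-triggered: after arming, the controller first waits
    for a check with every follicle below the trigger size, so stimulation
    begins at a fresh 14-mm crossing rather than mid-way through an already
    advanced follicular race.
    """

    name = "late-follicular"

    def __init__(self, params: ProtocolParams, arm_time: float = 35.0):
        super().__init__(params, arm_time)
        self._below_seen = False

    def _should_start(self, t, follicles, t_last_ovulation):
        above = any(f.active and f.size >= self.params.lf_trigger_size
                    for f in follicles)
        if not self._below_seen:
            if not above:
                self._below_seen = True
            return False
        return above

    def _dose_for_day(self, day_index: int) -> float:
        if day_index >= self.params.lf_escalation_day:
            return self.params.lf_escalated_dose
        return self.params.lf_initial_dose


class LutealStartProtocol(StimulationProtocol):
    """Stimulation initiated 1-3 days after ovulation, conditional on a
    growing follicle smaller than 8 mm: flat 225 IU/day."""

    name = "luteal"

    def __init__(self, params: ProtocolParams, arm_time: float = 35.0):
        super().__init__(params, arm_time)
        self._checked_ovulations: set[float] = set()

    def _should_start(self, t, follicles, t_last_ovulation):
        if t_last_ovulation is None:
            return False
        lo, hi = self.params.luteal_window
        delta = t - t_last_ovulation
        if delta > hi and t_last_ovulation not in self._checked_ovulations:
            # window passed without the condition being met; wait for the
            # next ovulation
            self._checked_ovulations.add(t_last_ovulation)
            self.state.missed_windows += 1
            return False
        if not (lo <= delta <= hi):
            return False
        return any(f.active and f.size < self.params.luteal_max_follicle_size
                   for f in follicles)

    def _dose_for_day(self, day_index: int) -> float:
        return self.params.luteal_dose


PROTOCOLS = {
    "late-follicular": LateFollicularProtocol,
    "luteal": LutealStartProtocol,
}


def make_protocol(name: str | None, params: ProtocolParams,
                  arm_time: float = 35.0) -> StimulationProtocol | None:
    """Instantiate a protocol controller by name (``None``/"none" -> no
    stimulation)."""
    if name is None or name == "none":
        return None
    try:
        cls = PROTOCOLS[name]
    except KeyError:
        raise ValueError(
            f"unknown protocol {name!r}; choose from {sorted(PROTOCOLS)}")
    return cls(params, arm_time=arm_time)
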