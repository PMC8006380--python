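"""Stochastic follicle cohort: Poisson recruitment, growth ODE, life cycle.

Each follicle carries two random properties drawn once at recruitment: its
recruitment time (a Poisson process whose intensity switches to an elevated
level when serum FSH exceeds a threshold) and its FSH sensitivity threshold
(normal, truncated at zero).  A follicle only grows while the ovarian FSH
signal exceeds its own sensitivity threshold; growth saturates logistically
toward a maximal diameter, is inhibited by P4 and stimulated by the
FSH-receptor complex, and is opposed by a shared competition term that high
FSH switches off (the "FSH window": wide-open FSH windows let many follicles
escape competition, which is what stimulation protocols exploit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .config import GrowthParams, RecruitmentParams
from .hormones import hill


class FollicleStatus(str, Enum):
    GROWING = "growing"
    OVULATED = "ovulated"
    ATRETIC = "atretic"


@dataclass
class Follicle:
    """One follicle: identity, random effects, current size and status."""

    id: int
    t_recruited: float
    fsh_sensitivity: float
    size: float
    status: FollicleStatus = FollicleStatus.GROWING
    t_cross_4mm: float | None = None   # first time diameter exceeded 4 mm
    t_retired: float | None = None     # ovulation/atresia time

    @property
    def active(self) -> bool:
        return self.status is FollicleStatus.GROWING


def recruit(t: float, dt: float, fsh_signal: float, rng: np.random.Generator,
            params: RecruitmentParams, next_id: int) -> list[Follicle]:
    """Draw the follicles recruited in [t, t+dt).

    The count is Poisson with intensity ``elevated_rate`` when the FSH signal
    exceeds the recruitment threshold and ``base_rate`` otherwise (rate held
    fixed over the interval); recruitment times are uniform in the interval
    and each recruit receives a sensitivity ~ Normal(sens_mean, sens_sd)
    truncated at zero, entering at the seed diameter.
    """
    if dt <= 0:
        raise ValueError(f"recruit requires dt > 0, got {dt}")
    rate = (params.elevated_rate if fsh_signal > params.fsh_recruit_threshold
            else params.base_rate)
    n = rng.poisson(rate * dt)
    out = []
    for k in range(n):
        t_rec = t + dt * rng.random()
        sens = rng.normal(params.sens_mean, params.sens_sd)
        while sens <= 0.0:
            sens = rng.normal(params.sens_mean, params.sens_sd)
        out.append(Follicle(id=next_id + k, t_recruited=t_rec,
                            fsh_sensitivity=sens, size=params.seed_size))
    return out


def growth_rates(sizes: np.ndarray, sensitivities: np.ndarray,
                 fsh_ovary: float, fsh_rec_complex: float, p4: float,
                 params: GrowthParams) -> np.ndarray:
    """d(size)/dt for every growing follicle in the cohort (vectorized).

    rate_i = gate_i * Hi(P4) * Hs(complex) * g * s_i * (1 - s_i/s_max)
             - c * Hi_window(FSH_ov) * s_i * L_i
             - a * (1 - gate_i) * s_i

    where gate_i is a steep Hill switch of the ovarian FSH signal at the
    follicle's own sensitivity threshold and
    L_i = sum over strictly larger follicles of (s_j/s_max)^q
    is the dominance load: a follicle is suppressed only by larger
    competitors, so the current leader is never blocked (winner-take-all
    selection).  Competition vanishes when ovarian FSH exceeds the window
    threshold — a wide-open FSH window lets several follicles reach
    dominant size, which stimulation protocols exploit.  The last term is
    regression of FSH-deprived follicles toward atresia.
    """
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        return np.zeros(0)
    g = params
    fsh = max(fsh_ovary, 0.0)
    # per-follicle FSH gate: ~0 below the sensitivity threshold, ~1 above
    r = (fsh / sensitivities) ** g.gate_exponent
    gate = r / (1.0 + r)
    modifiers = (gate
                 * hill(p4, g.p4_growth_inhibition)
                 * hill(fsh_rec_complex, g.rec_complex_stimulation))
    # dominance: the selected (largest) follicle past the dominance size has
    # switched its gonadotropin dependence and keeps growing at low FSH
    leader = int(np.argmax(sizes))
    dominant = sizes[leader] >= g.dominance_size
    if dominant:
        modifiers[leader] = max(modifiers[leader], g.dominance_floor)
    intrinsic = g.growth_rate * sizes * (1.0 - sizes / g.max_size)
    # dominance load: aggregate weight of strictly larger follicles
    order = np.argsort(sizes)
    w_sorted = (sizes[order] / g.max_size) ** g.competition_load_exponent
    cw = np.cumsum(w_sorted)
    pos = np.searchsorted(sizes[order], sizes, side="right")
    load = cw[-1] - cw[pos - 1]
    window = hill(fsh, __window_spec(g))
    competition = g.competition_strength * window * sizes * load
    # FSH-deprived follicles regress; large (near-dominant) follicles are
    # progressively less dependent on FSH for survival.  Luteal-phase P4
    # accelerates the clearance of the leftover sub-dominant cohort.
    p4_boost = 1.0 + g.p4_atresia_boost * hill(p4, g.p4_atresia)
    regression = (g.atresia_rate * p4_boost * (1.0 - gate) * sizes
                  * (1.0 - sizes / g.max_size))
    if dominant:
        regression[leader] = 0.0
    return modifiers * intrinsic - competition - regression


def __window_spec(g: GrowthParams):
    from .config import HillSpec
    return HillSpec(g.fsh_window_threshold, g.fsh_window_exponent, "inhibitory")


def follicle_rhs(follicle: Follicle, cohort: list[Follicle], fsh_ovary: float,
                 fsh_rec_complex: float, p4: float,
                 params: GrowthParams) -> float:
    """Single-follicle growth rate within its cohort (scalar convenience
    wrapper around :func:`growth_rates`)."""
    if follicle.status is not FollicleStatus.GROWING:
        raise ValueError(f"follicle {follicle.id} is not growing")
    active = [f for f in cohort if f.active]
    if follicle not in active:
        active = active + [follicle]
    sizes = np.array([f.size for f in active])
    sens = np.array([f.fsh_sensitivity for f in active])
    idx = active.index(follicle)
    return float(growth_rates(sizes, sens, fsh_ovary, fsh_rec_complex, p4,
                              params)[idx])


def update_lifecycle(follicles: list[Follicle], t: float,
                     params: GrowthParams) -> list[int]:
    """Retire shrunken follicles: any growing follicle whose diameter has
    fallen below the atresia floor becomes atretic.  Returns retired ids."""
    retired = []
    for f in follicles:
        if f.active and f.size < params.atresia_floor:
            f.status = FollicleStatus.ATRETIC
            f.t_retired = t
            retired.append(f.id)
    return retired


def eligible_for_ovulation(follicles: list[Follicle],
                           params: GrowthParams) -> list[int]:
    """Ids of growing follicles at/above the ovulable diameter."""
    return [f.id for f in follicles
            if f.active and f.size >= params.ovulation_size_threshold]


@dataclass
class Cohort:
    """Bookkeeping container for the whole follicle population of a run."""

    follicles: list[Follicle] = field(default_factory=list)
    _next_id: int = 0

    def add(self, new: list[Follicle]) -> None:
        self.follicles.extend(new)
        if new:
            self._next_id = max(f.id for f in new) + 1

    @property
    def next_id(self) -> int:
        return self._next_id

    @property
    def active(self) -> list[Follicle]:
        return [f for f in self.follicles if f.active]

    def counts(self) -> dict[str, int]:
        c = {"growing": 0, "ovulated": 0, "atretic": 0}
        for f in self.follicles:
            c[f.status.value] += 1
        return c
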