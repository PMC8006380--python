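"""The reduced pituitary/ovarian endocrine core.

The continuous state couples hypothalamic GnRH activity (pulse frequency and
releasable mass), pituitary LH/FSH pools, serum LH/FSH, an ovarian FSH
transport compartment, and the bound FSH–receptor complex.  Estradiol (E2)
and progesterone (P4) are algebraic outputs: a constant baseline, plus
Gaussian luteal curves anchored at the last ovulation, plus (for E2) a
size-dependent follicular production term.

All feedbacks are Hill functions:

* E2 acts biphasically on GnRH (inhibitory at low levels, stimulatory at
  pre-ovulatory levels) and stimulates LH synthesis steeply — this is the
  surge generator.
* P4 inhibits GnRH frequency, LH synthesis and FSH synthesis (the latter
  standing in for the inhibin feedback of the parent model).
* Serum FSH is transported into an ovarian compartment from which receptor
  binding proceeds; the bound complex is the growth-stimulatory signal seen
  by follicles.

Exogenous gonadotropin (hMG) enters as an additive rate in the ovarian FSH
transport equation, supplied by the pharmacokinetics module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import HillSpec, HormoneCoreParams, LutealCurveParams, ModelParameters

# Order of the continuous endocrine state vector.
STATE_NAMES = (
    "gnrh_freq", "gnrh_mass",
    "lh_pit", "lh_serum",
    "fsh_pit", "fsh_serum",
    "fsh_ovary", "fsh_rec_complex",
)
N_HORMONE_STATES = len(STATE_NAMES)

IDX = {name: i for i, name in enumerate(STATE_NAMES)}


@dataclass
class HormoneState:
    """A labeled snapshot of the endocrine state, with the algebraic
    steroid outputs attached."""

    gnrh_freq: float
    gnrh_mass: float
    lh_pit: float
    lh_serum: float
    fsh_pit: float
    fsh_serum: float
    fsh_ovary: float
    fsh_rec_complex: float
    e2: float
    p4: float


class IntegrationFailure(RuntimeError):
    """Raised when the ODE right-hand side is evaluated on an invalid state."""


def hill(x, spec: HillSpec):
    """Hill feedback factor in [0, 1].

    Stimulatory: x^n / (T^n + x^n); inhibitory: T^n / (T^n + x^n).
    Accepts scalars or arrays; negative inputs are clipped to 0.
    """
    if not (spec.threshold > 0 and spec.exponent > 0):
        raise ValueError(
            f"Hill spec requires threshold > 0 and exponent > 0, got {spec}")
    x = np.clip(x, 0.0, None)
    r = (x / spec.threshold) ** spec.exponent
    up = r / (1.0 + r)
    if spec.mode == "stimulatory":
        return up
    return 1.0 - up


def luteal_steroids(t: float, t_ovulation: float | None,
                    params: LutealCurveParams) -> tuple[float, float]:
    """Luteal (E2, P4) contributions at time ``t`` given the last ovulation.

    Gaussian curves peaking ``peak_offset`` days after ovulation with a hard
    14-day support; (0, 0) before any ovulation or after luteal regression.
    """
    if t_ovulation is None:
        return 0.0, 0.0
    dt = t - t_ovulation
    if dt < 0.0 or dt > params.luteal_length:
        return 0.0, 0.0
    shape = np.exp(-0.5 * ((dt - params.peak_offset) / params.width) ** 2)
    return params.amplitude_e2 * shape, params.amplitude_p4 * shape


def follicular_e2(sizes, params: ModelParameters) -> float:
    """Size-dependent follicular E2 production (pg/mL), summed over the
    active cohort.  Scales as diameter^exponent, reflecting the growth of
    the granulosa layer; the dominant follicle therefore dominates output."""
    hc = params.hormone_core
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        return 0.0
    return float(hc.e2_per_follicle * np.sum(sizes ** hc.e2_size_exponent))


def steroid_levels(t: float, sizes, t_ovulation: float | None,
                   params: ModelParameters) -> tuple[float, float]:
    """Total serum (E2, P4): baseline + luteal curve (+ follicular E2)."""
    hc = params.hormone_core
    e2_lut, p4_lut = luteal_steroids(t, t_ovulation, params.luteal)
    e2 = hc.e2_baseline + e2_lut + follicular_e2(sizes, params)
    p4 = hc.p4_baseline + p4_lut
    return e2, p4


def gnrh_activity(state) -> float:
    """Effective GnRH drive on the pituitary: pulse frequency x mass."""
    return state[IDX["gnrh_freq"]] * state[IDX["gnrh_mass"]]


def hormone_rhs(t: float, state, e2: float, p4: float, dose_input: float,
                params: HormoneCoreParams):
    """Time derivative of the 8-component endocrine state.

    ``e2``/``p4`` are the algebraic steroid levels at ``t``; ``dose_input``
    is the exogenous FSH-activity rate (IU/L/day) entering the ovarian
    compartment, already converted from the drug schedule by the PK layer.
    """
    state = np.asarray(state, dtype=float)
    if np.any(~np.isfinite(state)):
        raise IntegrationFailure(
            f"non-finite endocrine state at t={t:.3f}: {state}")
    gf, gm, lh_pit, lh_serum, fsh_pit, fsh_serum, fsh_ov, fsh_rc = state
    p = params

    # GnRH pulse frequency relaxes toward a P4-inhibited target in [0, 1],
    # with a pulsatility floor
    freq_target = (p.gnrh_freq_floor
                   + (1.0 - p.gnrh_freq_floor) * hill(p4, p.gnrh_freq_p4))
    d_gf = p.gnrh_freq_gain * (freq_target - gf)

    # GnRH mass: biphasic E2 control of synthesis, first-order release
    biphasic = (p.gnrh_e2_inhibitory_weight * hill(e2, p.gnrh_e2_inhibitory)
                + p.gnrh_e2_stimulatory_weight * hill(e2, p.gnrh_e2_stimulatory))
    d_gm = p.gnrh_mass_synthesis * biphasic - p.gnrh_mass_release * gm
    gnrh = gf * gm

    # LH: E2-stimulated, P4-inhibited synthesis; GnRH-dependent release
    lh_syn = (p.lh_syn_basal + p.lh_syn_e2_max * hill(e2, p.lh_e2)) \
        * hill(p4, p.lh_p4)
    lh_rel = p.lh_release * gnrh * lh_pit
    d_lh_pit = lh_syn - lh_rel
    d_lh_serum = lh_rel / p.blood_volume - p.lh_clearance * lh_serum

    # FSH: P4- and E2-inhibited synthesis; GnRH-dependent release
    fsh_syn = p.fsh_syn_basal * hill(p4, p.fsh_p4) * hill(e2, p.fsh_e2)
    fsh_rel = p.fsh_release * gnrh * fsh_pit
    d_fsh_pit = fsh_syn - fsh_rel
    d_fsh_serum = fsh_rel / p.blood_volume - p.fsh_clearance * fsh_serum

    # ovarian FSH compartment: transport in (+ exogenous dose), binding and
    # degradation out; receptor complex from linear binding kinetics
    d_fsh_ov = (p.fsh_transport * fsh_serum + dose_input
                - (p.fsh_ovary_clearance + p.fsh_binding) * fsh_ov)
    d_fsh_rc = p.fsh_binding * fsh_ov - p.fsh_unbinding * fsh_rc

    return np.array([d_gf, d_gm, d_lh_pit, d_lh_serum,
                     d_fsh_pit, d_fsh_serum, d_fsh_ov, d_fsh_rc])


def default_initial_state() -> np.ndarray:
    """A mid-follicular-phase starting point; transients decay within the
    first simulated cycle."""
    return np.array([0.9, 0.7, 120.0, 8.0, 80.0, 7.0, 7.0, 7.0])
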