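"""Pharmacokinetics of exogenous gonadotropin (hMG) dosing.

A one-compartment model with first-order absorption and elimination — three
drug-specific parameters (ka, ke, and a lumped bioavailability/volume scale).
The serum drug level is the closed-form superposition of Bateman functions
over all past doses, which keeps the hormone ODE free of additional states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PKParams

# relative |ka-ke| below which the confluent (ka == ke) limit is used
_CONFLUENT_EPS = 1e-9


@dataclass(frozen=True)
class DoseEvent:
    """A single timed drug administration."""

    t_admin: float   # days
    dose: float      # IU
    drug: str = "hMG"

    def __post_init__(self):
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose}")


def drug_level(t, doses: list[DoseEvent], pk: PKParams):
    """Exogenous drug concentration (IU/L) at time(s) ``t``.

    Superposition over past doses of
    ``scale * D * ka/(ka-ke) * (exp(-ke*dt) - exp(-ka*dt))``;
    future doses contribute nothing.  The confluent limit
    ``scale * D * ka * dt * exp(-ka*dt)`` is used when ka == ke.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    ka, ke, s = pk.absorption_rate, pk.elimination_rate, pk.scale
    for d in doses:
        dt = t - d.t_admin
        past = dt >= 0.0
        if not np.any(past):
            continue
        dtp = np.where(past, dt, 0.0)
        if abs(ka - ke) <= _CONFLUENT_EPS * max(ka, ke):
            contrib = s * d.dose * ka * dtp * np.exp(-ka * dtp)
        else:
            contrib = (s * d.dose * ka / (ka - ke)
                       * (np.exp(-ke * dtp) - np.exp(-ka * dtp)))
        out += np.where(past, contrib, 0.0)
    return out if out.ndim else float(out)
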