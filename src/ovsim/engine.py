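"""Hybrid simulation loop for the coupled endocrine + follicle system.

The continuous state (8 endocrine components plus one size per active
follicle) is integrated segment-by-segment with a stiff-capable solver
(LSODA).  Segments are cut at most ``max_segment`` days apart and at every
discrete event time.  At each segment boundary the engine:

* draws Poisson follicle recruitments for the next segment,
* locates LH-surge upcrossings inside the finished segment (dense output),
  scheduling ovulation of all size-eligible follicles 12 h later,
* applies ovulations (follicle removal, luteal-clock reset) and atresia,
* evaluates the stimulation-protocol controller at its daily check time and
  records emitted doses.

Everything stochastic goes through one seeded generator, so a (parameters,
protocol, config, seed) tuple reproduces the identical event log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .config import ModelParameters, default_parameters
from .follicles import (Cohort, Follicle, FollicleStatus, growth_rates,
                        recruit, update_lifecycle, eligible_for_ovulation)
from .hormones import (IDX, N_HORMONE_STATES, STATE_NAMES, IntegrationFailure,
                       default_initial_state, hormone_rhs, steroid_levels)
from .pk import DoseEvent, drug_level
from .protocols import ProtocolPhase, StimulationProtocol

_TIME_EPS = 1e-9


@dataclass
class SimulationConfig:
    """Run controls: horizon, seed, reporting grid, event thresholds and
    solver tolerances."""

    t_end: float = 1300.0
    seed: int = 0
    output_dt: float = 0.25
    lh_surge_threshold: float = 35.0   # IU/L; surge = supra-threshold serum LH
    ovulation_delay: float = 0.5       # days (12 h) from surge to ovulation
    surge_refractory: float = 3.5      # days; suppress re-triggering
    solver_rtol: float = 1e-6
    solver_atol: float = 1e-8
    max_segment: float = 0.25          # days between event checks
    stop_after_protocol: float | None = 2.0  # keep simulating this many days
    # after the protocol stops, then end the run early (None: run to t_end)

    def validate(self) -> None:
        if not (self.solver_rtol > 0 and self.solver_atol > 0):
            raise ValueError("solver tolerances must be > 0")
        if not (self.t_end > 0 and self.output_dt > 0 and self.max_segment > 0):
            raise ValueError("t_end, output_dt and max_segment must be > 0")
        if self.ovulation_delay <= 0:
            raise ValueError("ovulation_delay must be > 0")


@dataclass
class Event:
    time: float
    type: str         # recruit | lh_surge | ovulation | dose | atresia |
    #                   protocol_start | protocol_stop
    follicle_id: int | None = None
    detail: str = ""


@dataclass
class SimulationResult:
    """Trajectories on the reporting grid, the full cohort, and the ordered
    event log of one run."""

    times: np.ndarray
    hormones: np.ndarray            # len(times) x (8 states + e2 + p4)
    follicle_traj: dict[int, tuple[list, list]]  # id -> (times, sizes)
    cohort: Cohort
    events: list[Event]
    doses: list[DoseEvent]
    protocol: StimulationProtocol | None
    params: ModelParameters
    config: SimulationConfig
    treatment_census: dict | None = None   # sizes of growing follicles when
    #                                        the stopping criterion fired
    incomplete: bool = False               # protocol never ran to its stop

    HORMONE_COLUMNS = STATE_NAMES + ("e2", "p4")

    def hormone(self, name: str) -> np.ndarray:
        return self.hormones[:, self.HORMONE_COLUMNS.index(name)]

    def ovulation_times(self) -> np.ndarray:
        seen = sorted({e.time for e in self.events if e.type == "ovulation"})
        return np.array(seen)

    # -- tidy exports -----------------------------------------------------
    def hormones_dataframe(self) -> pd.DataFrame:
        rows = []
        for j, name in enumerate(self.HORMONE_COLUMNS):
            rows.append(pd.DataFrame({
                "time_days": self.times, "variable": name,
                "value": self.hormones[:, j]}))
        return pd.concat(rows, ignore_index=True)

    def follicles_dataframe(self) -> pd.DataFrame:
        recs = []
        status = {f.id: f.status.value for f in self.cohort.follicles}
        for fid, (ts, ss) in self.follicle_traj.items():
            for t, s in zip(ts, ss):
                recs.append((t, fid, s, status[fid]))
        return pd.DataFrame(
            recs, columns=["time_days", "follicle_id", "size_mm", "status"])

    def events_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.time, e.type, e.follicle_id, e.detail) for e in self.events],
            columns=["time", "event_type", "follicle_id", "detail"])


def locate_upcrossing(times, values, threshold: float) -> float | None:
    """Earliest time where ``values`` crosses ``threshold`` from below
    (linear interpolation between samples); None if no upcrossing."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    below = values < threshold
    for i in range(1, len(times)):
        if below[i - 1] and not below[i]:
            v0, v1 = values[i - 1], values[i]
            frac = (threshold - v0) / (v1 - v0) if v1 != v0 else 0.0
            return float(times[i - 1] + frac * (times[i] - times[i - 1]))
    return None


def simulate(params: ModelParameters | None = None,
             protocol: StimulationProtocol | None = None,
             config: SimulationConfig | None = None) -> SimulationResult:
    """Run the coupled hormone + follicle simulation.

    Returns trajectories on the reporting grid, the complete follicle
    bookkeeping and the ordered event log.  Reproducible given
    ``config.seed``.
    """
    params = params or default_parameters()
    config = config or SimulationConfig()
    config.validate()
    params.validate()

    hc = params.hormone_core
    rng = np.random.default_rng(config.seed)
    cohort = Cohort()
    events: list[Event] = []
    doses: list[DoseEvent] = []

    y = default_initial_state()
    t = 0.0
    t_ov_clock: float | None = None      # anchors the luteal steroid curves
    t_last_ovulation: float | None = None
    last_surge = -math.inf
    pending_ovulations: list[float] = []
    next_check = params.protocol.dose_hour  # daily protocol evaluation time
    protocol_stop_time: float | None = None
    treatment_census = None

    out_times: list[float] = []
    out_hormones: list[np.ndarray] = []
    follicle_traj: dict[int, tuple[list, list]] = {}
    next_output = 0.0

    def record_sample(ts: float, h: np.ndarray, active: list[Follicle],
                      sizes: np.ndarray) -> None:
        e2, p4 = steroid_levels(ts, sizes, t_ov_clock, params)
        out_times.append(ts)
        out_hormones.append(np.concatenate([np.maximum(h, 0.0), [e2, p4]]))
        for f, s in zip(active, sizes):
            traj = follicle_traj.setdefault(f.id, ([], []))
            traj[0].append(ts)
            traj[1].append(float(s))

    record_sample(0.0, y, [], np.zeros(0))
    next_output = config.output_dt

    while t < config.t_end - _TIME_EPS:
        # ---- segment end: next discrete event or max_segment -------------
        t1 = min(t + config.max_segment, config.t_end)
        for tv in pending_ovulations:
            if t + _TIME_EPS < tv < t1:
                t1 = tv
        if protocol is not None and t + _TIME_EPS < next_check < t1:
            t1 = next_check
        seg = t1 - t

        # ---- recruitment for this segment --------------------------------
        exo_now = drug_level(t, doses, params.pk) if doses else 0.0
        fsh_total = max(y[IDX["fsh_serum"]], 0.0) + exo_now
        recruits = recruit(t, seg, fsh_total, rng, params.recruitment,
                           cohort.next_id)
        cohort.add(recruits)
        for f in recruits:
            events.append(Event(f.t_recruited, "recruit", f.id,
                                f"sens={f.fsh_sensitivity:.3f}"))

        active = cohort.active
        sens = np.array([f.fsh_sensitivity for f in active])
        sizes0 = np.array([f.size for f in active])
        y0 = np.concatenate([y, sizes0])
        clock = t_ov_clock

        def rhs(tt, yy):
            h = yy[:N_HORMONE_STATES]
            s = np.clip(yy[N_HORMONE_STATES:], 0.0, None)
            e2, p4 = steroid_levels(tt, s, clock, params)
            exo = drug_level(tt, doses, params.pk) if doses else 0.0
            dose_rate = hc.fsh_transport * exo
            dh = hormone_rhs(tt, h, e2, p4, dose_rate, hc)
            ds = growth_rates(s, sens, max(h[IDX["fsh_ovary"]], 0.0),
                              max(h[IDX["fsh_rec_complex"]], 0.0), p4,
                              params.growth)
            return np.concatenate([dh, ds])

        sol = solve_ivp(rhs, (t, t1), y0, method="LSODA",
                        rtol=config.solver_rtol, atol=config.solver_atol,
                        dense_output=True)
        if not sol.success:
            raise IntegrationFailure(
                f"solver failed on [{t:.4f}, {t1:.4f}]: {sol.message}; "
                f"last good state {y0}")

        # ---- LH-surge detection within the segment ------------------------
        tt = np.linspace(t, t1, max(int(seg / 0.01), 4) + 1)
        lh = sol.sol(tt)[IDX["lh_serum"]]
        ts = locate_upcrossing(tt, lh, config.lh_surge_threshold)
        if ts is None and lh[-1] >= config.lh_surge_threshold:
            # surge condition is level-based: sustained supra-threshold LH
            # re-triggers once the refractory window has passed
            ts = t1
        if ts is not None and ts - last_surge >= config.surge_refractory:
            last_surge = ts
            events.append(Event(ts, "lh_surge",
                                detail=f"lh={config.lh_surge_threshold:.1f}"))
            pending_ovulations.append(ts + config.ovulation_delay)
            pending_ovulations.sort()

        # ---- advance state -------------------------------------------------
        yend = sol.y[:, -1]
        y = np.maximum(yend[:N_HORMONE_STATES], 0.0)
        new_sizes = np.clip(yend[N_HORMONE_STATES:], 0.0, None)
        for f, s in zip(active, new_sizes):
            f.size = float(s)
            if f.t_cross_4mm is None and f.size > 4.0:
                f.t_cross_4mm = t1

        # ---- reporting grid -------------------------------------------------
        while next_output <= t1 + _TIME_EPS:
            hs = sol.sol(next_output)
            record_sample(next_output, hs[:N_HORMONE_STATES],
                          active, np.clip(hs[N_HORMONE_STATES:], 0.0, None))
            next_output += config.output_dt

        t = t1

        # ---- ovulation events ----------------------------------------------
        if pending_ovulations and abs(pending_ovulations[0] - t) < 1e-6:
            pending_ovulations.pop(0)
            eligible = eligible_for_ovulation(cohort.follicles, params.growth)
            if eligible:
                # one surge releases one oocyte: the dominant (largest)
                # follicle ovulates; co-eligible followers stay growing
                by_size = {f.id: f.size for f in cohort.follicles}
                eligible = [max(eligible, key=by_size.get)]
                # a fresh corpus luteum only forms if the previous one is
                # past its peak; mid-luteal ovulations (stimulation edge
                # cases) do not restart the luteal clock
                luteal_active = (t_ov_clock is not None and
                                 t - t_ov_clock <= params.luteal.peak_offset)
                for fid in eligible:
                    f = next(f for f in cohort.follicles if f.id == fid)
                    f.status = FollicleStatus.OVULATED
                    f.t_retired = t
                    events.append(Event(t, "ovulation", fid,
                                        f"size={f.size:.2f}"))
                if not luteal_active:
                    t_ov_clock = t
                t_last_ovulation = t

        # ---- atresia ---------------------------------------------------------
        for fid in update_lifecycle(cohort.follicles, t, params.growth):
            events.append(Event(t, "atresia", fid))

        # ---- protocol controller --------------------------------------------
        if protocol is not None and abs(t - next_check) < 1e-6:
            phase_before = protocol.state.phase
            dose = protocol.daily_check(t, cohort.follicles, t_last_ovulation)
            phase_after = protocol.state.phase
            if (phase_before is ProtocolPhase.WAITING
                    and phase_after is not ProtocolPhase.WAITING):
                events.append(Event(t, "protocol_start", detail=protocol.name))
            if dose is not None:
                doses.append(dose)
                events.append(Event(t, "dose",
                                    detail=f"{dose.dose:.0f} IU {dose.drug}"))
            if (phase_before is not ProtocolPhase.STOPPED
                    and phase_after is ProtocolPhase.STOPPED):
                events.append(Event(t, "protocol_stop", detail=protocol.name))
                protocol_stop_time = t
                growing = [f.size for f in cohort.active]
                treatment_census = {"t": t, "sizes": np.array(growing)}
            next_check += 1.0

        if (protocol is not None and protocol_stop_time is not None
                and config.stop_after_protocol is not None
                and t >= protocol_stop_time + config.stop_after_protocol):
            break

    events.sort(key=lambda e: e.time)
    incomplete = protocol is not None and not protocol.complete
    return SimulationResult(
        times=np.array(out_times),
        hormones=np.vstack(out_hormones),
        follicle_traj=follicle_traj,
        cohort=cohort,
        events=events,
        doses=doses,
        protocol=protocol,
        params=params,
        config=config,
        treatment_census=treatment_census,
        incomplete=incomplete,
    )
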