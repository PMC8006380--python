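"""Outcome statistics: cycle segmentation, follicle counts, treatment
summaries, normality/correlation checks.

A menstrual cycle is defined ovulation-to-ovulation.  A follicle is counted
in a cycle if its diameter first exceeds 4 mm within that cycle (the
ultrasound-visible threshold).  Treatment outcomes are censused on the last
treatment day: counts of follicles with final diameter in [10, 14] mm and
> 14 mm, plus treatment duration in dosing days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .engine import SimulationResult

# Clinical reference values (mean ± SD) the simulated protocols are
# compared against: luteal-phase start and late-follicular start cohorts.
CLINICAL_REFERENCE = {
    "luteal": {"n_10_14": (13.9, 7.8), "n_gt14": (11.1, 5.5),
               "duration": (10.2, 1.6), "source": "Kuang et al."},
    "late-follicular": {"n_10_14": (np.nan, np.nan), "n_gt14": (11.7, 6.2),
                        "duration": (10.93, 1.66), "source": "Zhu & Fu"},
}


@dataclass
class CycleRecord:
    """One ovulation-to-ovulation cycle with its follicle count."""

    t_start: float
    t_end: float
    n_follicles_gt4: int

    @property
    def length(self) -> float:
        return self.t_end - self.t_start


@dataclass
class TreatmentOutcome:
    """End-of-treatment summary of one stimulated run."""

    protocol: str
    duration: int          # number of daily hMG administrations
    n_10_14: int           # follicles with final diameter in [10, 14] mm
    n_gt14: int            # follicles with final diameter > 14 mm
    n_lt10: int = 0


def segment_cycles(result: SimulationResult) -> list[CycleRecord]:
    """Split a run into consecutive ovulation-to-ovulation cycles and count
    the distinct follicles that first exceeded 4 mm within each."""
    ov = result.ovulation_times()
    if len(ov) < 2:
        return []
    cross = np.array([f.t_cross_4mm for f in result.cohort.follicles
                      if f.t_cross_4mm is not None])
    records = []
    for a, b in zip(ov[:-1], ov[1:]):
        n = int(np.sum((cross >= a) & (cross < b)))
        records.append(CycleRecord(t_start=float(a), t_end=float(b),
                                   n_follicles_gt4=n))
    return records


def cycle_summary(records: list[CycleRecord]) -> dict:
    """Mean/SD of cycle length and follicle count, Shapiro–Wilk normality
    p-values, and the length-vs-count Pearson correlation.

    With fewer than 3 records the tests are skipped and the summary is
    flagged (``tests_performed = False``).
    """
    lengths = np.array([r.length for r in records], dtype=float)
    counts = np.array([r.n_follicles_gt4 for r in records], dtype=float)
    out = {
        "n_cycles": len(records),
        "length_mean": float(np.mean(lengths)) if len(records) else np.nan,
        "length_sd": float(np.std(lengths, ddof=1)) if len(records) > 1 else np.nan,
        "count_mean": float(np.mean(counts)) if len(records) else np.nan,
        "count_sd": float(np.std(counts, ddof=1)) if len(records) > 1 else np.nan,
        "tests_performed": False,
    }
    if len(records) >= 3:
        out["tests_performed"] = True
        out["length_shapiro_p"] = float(sps.shapiro(lengths).pvalue)
        out["count_shapiro_p"] = float(sps.shapiro(counts).pvalue)
        r, p = sps.pearsonr(lengths, counts)
        out["length_count_pearson_r"] = float(r)
        out["length_count_pearson_p"] = float(p)
    return out


def treatment_outcome(result: SimulationResult) -> TreatmentOutcome:
    """Census one stimulated run on its last treatment day.

    Bins as printed in the clinical comparisons: [10, 14] mm inclusive and
    strictly > 14 mm; only growing follicles count.
    """
    if result.protocol is None or result.treatment_census is None:
        raise ValueError("run has no completed treatment to summarize")
    sizes = np.asarray(result.treatment_census["sizes"], dtype=float)
    n_10_14 = int(np.sum((sizes >= 10.0) & (sizes <= 14.0)))
    n_gt14 = int(np.sum(sizes > 14.0))
    n_lt10 = int(np.sum(sizes < 10.0))
    return TreatmentOutcome(protocol=result.protocol.name,
                            duration=result.protocol.duration,
                            n_10_14=n_10_14, n_gt14=n_gt14, n_lt10=n_lt10)


def treatment_summary(outcomes: list[TreatmentOutcome]) -> pd.DataFrame:
    """Mean ± SD of duration and size-bin counts over replicates, laid out
    against the embedded clinical reference values.

    All outcomes must come from the same protocol.
    """
    if len(outcomes) < 2:
        raise ValueError("need >= 2 outcomes for a replicate summary")
    protocols = {o.protocol for o in outcomes}
    if len(protocols) != 1:
        raise ValueError(f"mixed-protocol input: {sorted(protocols)}")
    protocol = protocols.pop()
    ref = CLINICAL_REFERENCE.get(protocol, {})
    rows = []
    for key, label in [("n_10_14", "follicles 10-14 mm"),
                       ("n_gt14", "follicles > 14 mm"),
                       ("duration", "treatment duration (days)")]:
        vals = np.array([getattr(o, key) for o in outcomes], dtype=float)
        ref_mean, ref_sd = ref.get(key, (np.nan, np.nan))
        rows.append({
            "protocol": protocol, "quantity": label,
            "sim_mean": float(np.mean(vals)),
            "sim_sd": float(np.std(vals, ddof=1)),
            "clinical_mean": ref_mean, "clinical_sd": ref_sd,
            "clinical_source": ref.get("source", ""),
            "n_replicates": len(outcomes),
        })
    return pd.DataFrame(rows)


CHECKPOINT_LABELS = ("pre_start_1d", "post_start_1d", "day_6", "last_day")


def hormone_checkpoints(result: SimulationResult) -> dict[str, dict[str, float]]:
    """LH/FSH/E2/P4 at the four characteristic treatment times: 1 day before
    start, 1 day after start, 6 days after start, last treatment day.

    Serum FSH includes the exogenous drug contribution.  For treatments
    shorter than 6 days the day-6 checkpoint is clamped to the last day and
    flagged (``clamped`` key).
    """
    from .pk import drug_level

    if (result.protocol is None or result.protocol.state.t_start is None
            or result.treatment_census is None):
        raise ValueError("run has no completed treatment")
    t0 = result.protocol.state.t_start
    t_last = result.treatment_census["t"]
    checkpoint_times = [t0 - 1.0, t0 + 1.0, t0 + 6.0, t_last]
    out = {}
    for label, tc in zip(CHECKPOINT_LABELS, checkpoint_times):
        clamped = False
        if tc > t_last:
            tc, clamped = t_last, True
        exo = float(drug_level(tc, result.doses, result.params.pk))
        vals = {
            "lh": float(np.interp(tc, result.times, result.hormone("lh_serum"))),
            "fsh": float(np.interp(tc, result.times,
                                   result.hormone("fsh_serum"))) + exo,
            "e2": float(np.interp(tc, result.times, result.hormone("e2"))),
            "p4": float(np.interp(tc, result.times, result.hormone("p4"))),
            "time": float(tc),
        }
        if clamped:
            vals["clamped"] = True
        out[label] = vals
    return out


def checkpoint_summary(replicates: list[dict]) -> dict[str, dict[str, tuple]]:
    """Across-replicate mean ± SD for each checkpoint/hormone pair."""
    out: dict[str, dict[str, tuple]] = {}
    for label in CHECKPOINT_LABELS:
        out[label] = {}
        for h in ("lh", "fsh", "e2", "p4"):
            vals = np.array([rep[label][h] for rep in replicates])
            out[label][h] = (float(np.mean(vals)),
                             float(np.std(vals, ddof=1)) if len(vals) > 1
                             else 0.0)
    return out
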