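# Methods

## Scope and intent

`ovsim` simulates the hormonal control of the human menstrual cycle coupled
to a stochastic population of growing antral follicles, and uses the
coupled system to run *in-silico* ovarian-stimulation treatments. The
package is built around three claims that the simulations are meant to
support: (i) random recruitment plus competitive selection produces
wave-like follicular growth and realistic cycle-to-cycle variability;
(ii) a single parameter set reproduces both unstimulated cycle statistics
and stimulated treatment outcomes; (iii) variable-start stimulation
(luteal or late-follicular) works because high FSH opens the competition
window at any cycle phase.

## Endocrine core

Eight ODE states: GnRH pulse frequency and releasable mass, pituitary and
serum LH, pituitary and serum FSH, ovarian FSH, and FSH–receptor complex.
Units: days; IU and IU/L for gonadotropins; pg/mL for E2; ng/mL for P4.

* **GnRH.** Frequency relaxes (gain 5/d) toward a P4-inhibited target with
  a pulsatility floor of 0.15 — luteal P4 slows but does not stop the
  pulse generator. Releasable mass is synthesized under biphasic E2
  control (one inhibitory low-threshold term, one stimulatory
  high-threshold term) and released first-order. The product
  frequency × mass is the drive for pituitary release.
* **LH.** Synthesis is basal plus a steep E2-stimulated term (Hill
  threshold 210 pg/mL, exponent 10) — this is the surge generator — and is
  strongly inhibited by P4 (threshold 0.35 ng/mL). Release is
  GnRH-proportional; serum LH clears at 14/d.
* **FSH.** Synthesis is inhibited by P4 (the inhibin role is folded into
  P4, which peaks mid-luteally just as inhibin A would) and by E2
  (threshold 135 pg/mL, exponent 5 — the mechanism that closes the FSH
  window once a dominant follicle produces estradiol). Serum FSH is
  transported into an ovarian compartment (4/d) from which linear receptor
  binding produces the bound complex seen by follicles.
* **Steroids.** E2 and P4 are algebraic: constant baselines
  (20 pg/mL, 0.3 ng/mL), Gaussian luteal curves anchored at the last
  ovulation (amplitudes 110 pg/mL and 13 ng/mL, peak 7 days
  post-ovulation, σ = 1.8 d, hard 14-day support), and for E2 an additive
  follicular term 0.0075·Σ s_i^3.5 over growing follicles. The exponent
  3.5 makes the dominant follicle the main E2 source while letting a
  burst cohort contribute enough to modulate FSH.

The fixed 14-day luteal support reflects the observation that luteal-phase
length varies far less than follicular-phase length; all cycle-length
variability in the model is follicular.

## Follicle population

Follicles carry two random effects drawn once at recruitment: the
recruitment time (Poisson process, 0.7/d base intensity, 4.5/d while serum
FSH exceeds 6.5 IU/L) and an FSH-sensitivity threshold
(Normal(8.0, 2.0) IU/L, truncated at zero). Recruits enter at 2 mm.

Growth is logistic (rate 0.6/d, asymptote 26 mm) multiplied by three Hill
factors: the steep per-follicle FSH gate (exponent 6 on ovarian FSH over
the follicle's own threshold), P4 inhibition (threshold 8.5 ng/mL), and
receptor-complex stimulation (threshold 8, exponent 2 — this is what makes
exogenously stimulated growth much faster than endogenous growth, since
stimulation roughly triples the complex level). Three structural choices
matter and are deliberate departures from the simplest textbook form:

* **Dominance-ordered competition.** The competition load on a follicle is
  the summed size weight `(s_j/s_max)^2` of *strictly larger* competitors,
  scaled by 0.10/d and by an inhibitory Hill of ovarian FSH (threshold 10,
  exponent 6 — the FSH window). A linear all-to-all load lets an
  accumulating crowd of 2-mm recruits freeze every front-runner and the
  system locks into an anovulatory fixed point; downhill-only suppression
  makes selection winner-take-all, which is what mono-ovulation requires.
* **FSH-deprivation regression.** Gated-off follicles shrink at
  0.25/d · (1 − gate) · s · (1 − s/s_max), accelerated four-fold under
  luteal P4 (the post-selection atresia of sub-dominant follicles).
  Follicles below 1.8 mm are retired as atretic and never return.
* **Gonadotropin switch of the dominant follicle.** The largest growing
  follicle past 15 mm has its growth modifier floored at 0.30 and is
  exempt from regression: the selected follicle survives the low-FSH
  pre-ovulatory environment, as the real dominant does by switching to LH
  dependence. Without this the model's own E2→FSH feedback strands
  dominants a few millimetres short of ovulation.

## Events and integration

The coupled system (8 endocrine states + one size per active follicle) is
integrated with LSODA in segments of at most 0.25 d, cut additionally at
every scheduled event. At segment boundaries the engine draws
recruitments, checks the serum-LH surge condition, applies ovulations and
atresia, and evaluates the protocol controller at its daily 08:00 check.

The surge condition is level-based, following the rule that ovulation
occurs 12 h after LH exceeds a threshold (35 IU/L): an upcrossing triggers
immediately, and sustained supra-threshold LH re-triggers once a 3.5-day
refractory period has passed. Twelve hours after each surge the largest
growing follicle at or above 18 mm ovulates; its removal resets the luteal
clock unless a luteal phase is still on its rising limb (before the P4
peak), so mid-luteal ovulations under stimulation do not restart the
curves. One surge releases one oocyte: co-eligible followers continue
growing (and are then suppressed by rising luteal P4).

Halving the solver tolerances moves ovulation times by well under 0.05 d
over a 200-day run; all stochasticity flows from a single
`numpy.random.Generator` seeded per run, so a (parameters, protocol,
config, seed) tuple reproduces the identical event log. Replicate seeds
derive from one root seed via `numpy.random.SeedSequence.spawn`.

## Pharmacokinetics and protocols

hMG is modelled as pure FSH activity with three drug parameters:
first-order absorption (3.0/d), elimination (0.35/d) and a lumped
dose-to-concentration scale (0.044 IU/L per IU — at 225 IU/day the
steady-state average exogenous level is ≈ 28 IU/L). The serum level is the
closed-form Bateman superposition over past doses and feeds the ovarian
FSH transport equation.

The two controllers follow the published clinical rules: luteal start
(first morning check 1–3 days after an ovulation with a growing follicle
below 8 mm; 225 IU daily), late-follicular start (a *fresh* 14-mm
crossing; 150 IU daily, 225 IU from the seventh administration). Both
stop when three growing follicles reach 18 mm; the stop check precedes
dosing, so the criterion morning receives no dose. The late-follicular
trigger is edge-detected (the controller must first see a check with all
follicles below 14 mm) so that stimulation never starts mid-way through an
already advanced race. Dose adjustments beyond the printed schedule are
not modelled. No hCG trigger is modelled: runs end at the stopping
criterion, and the post-stop LH rebound that follows once luteal P4 decays
is outside the reported treatment window.

## Calibration

The literal parameter values of the source models were not available to
this implementation, so the published summary statistics serve as the
calibration objective, with the structural property suite as the hard
gate. Calibration targeted, simultaneously: unstimulated cycle length
30.56 ± 7.00 d and 16.19 ± 3.08 follicles > 4 mm per cycle (~42-cycle
runs); luteal-start outcomes 11.1 ± 3.5 follicles 10–14 mm, 8.9 ± 3.7
follicles > 14 mm, 9.4 ± 0.7 dosing days; late-follicular outcomes
6.3 ± 2.2, 8.0 ± 2.2, 6.0 ± 0.7 days; and serum P4 ≈ 0.99 ng/mL at
late-follicular treatment day 6. Every hormone-core, growth, recruitment
and PK value is tagged `calibrated` in the config provenance; protocol
rule constants are `clinical`; the 14-day luteal length is `convention`.
The default set holds roughly eighty scalar constants across the six
parameter groups.

Two emergent mechanisms carry the statistics. Cycle-length variability
comes from *wave skipping*: a recruitment cohort whose most sensitive
member cannot sustain growth at the FSH trough regresses, E2 falls, FSH
recovers, and the next cohort tries again — cycles therefore lengthen in
quasi-discrete steps and the SD arises without any per-cycle parameter
noise. The per-cycle follicle count comes from the elevated-recruitment
window: every recruit that enters while FSH is high grows past the 4-mm
detection size before selection culls the cohort.

Known calibration limit: the stimulated size ladder is slightly more
top-heavy than the clinical reference. At the stopping criterion the
luteal-start 10–14 mm bin averages ≈ 7.3 against the published 11.1 ± 3.5,
i.e. at the edge of the one-SD band, and the > 14 mm bin sits near the top
of its band; shifting mass between the bins consistently pushed either the
other bin or the treatment duration out of its band, so the joint optimum
was kept. All other targets sit inside their one-SD bands across the
seeds tested.

## What the simulations do and do not show

The generator reproduces summary statistics of an idealized patient: one
parameter set, no inter-individual variability, no measurement error, no
dose individualization, no anti-Müllerian axis, no inhibins, no LH
receptor dynamics, no oocyte quality. Between-replicate variability stems
solely from follicular randomness, which is why simulated SDs are smaller
than clinical ones. Agreement with the published statistics therefore
shows that the coupled mechanism is sufficient to generate the observed
central tendencies — not that the model predicts individual patients.
Double stimulation (two treatments within one cycle) is not simulated.
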