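# ovsim

A hybrid stochastic simulator of the human menstrual cycle and of
variable-start ovarian-stimulation protocols, written for reproductive
endocrinologists and modellers who want to test stimulation strategies
*in silico*.

## The model

The simulator couples two sub-models:

**Endocrine core (ODEs).** A reduced pituitary/ovarian network with eight
continuous states — GnRH pulse frequency and releasable mass, pituitary and
serum LH, pituitary and serum FSH, an ovarian FSH transport compartment,
and the bound FSH–receptor complex. All feedbacks are Hill functions:
estradiol (E2) acts biphasically on GnRH and steeply stimulates LH synthesis
(the surge generator); progesterone (P4) inhibits GnRH frequency and both
gonadotropin syntheses. E2 and P4 are algebraic outputs: baselines, plus
Gaussian luteal curves with a fixed 14-day support anchored at the last
ovulation, plus (for E2) a follicular production term that scales with
follicle diameter as `s^3.5`.

**Follicle population (stochastic).** Follicles are recruited by a Poisson
process whose intensity switches to an elevated level while serum FSH is
high. Each follicle draws a lifelong FSH-sensitivity threshold from a
truncated normal distribution and grows by a logistic law

```
ds/dt = gate(FSH_ov/θ) · H⁻(P4) · H⁺(complex) · γ·s·(1 − s/s_max)
        − c · H⁻(FSH_ov) · s · L   −   atresia terms
```

where the gate opens when ovarian FSH exceeds the follicle's own threshold
θ, `L` is the aggregate weight of strictly larger competitors (dominance
runs downhill), and the competition factor `H⁻(FSH_ov)` switches off above
the *FSH window* threshold — which is how exogenous gonadotropin lets many
follicles grow at once. The largest follicle past 15 mm escapes FSH
dependence (the gonadotropin switch of the selected follicle).

**Events.** When serum LH exceeds the surge threshold, the dominant
follicle ovulates 12 h later (if it has reached 18 mm), the luteal clock
resets, and the cohort bookkeeping is updated. Dosing, protocol triggers
and stop rules are evaluated once per simulated day.

**Protocols.** Two variable-start ovarian-stimulation protocols are
implemented: *luteal start* (225 IU hMG daily, starting 1–3 days after an
ovulation when a follicle < 8 mm exists) and *late-follicular start*
(150 IU daily from a fresh 14-mm crossing, escalated to 225 IU after six
days). Both stop once at least three growing follicles reach 18 mm. hMG
enters through a one-compartment first-order absorption/elimination model.

## Worked example

Simulate 400 unstimulated days and a small luteal-start experiment:

```bash
$ ovsim simulate --protocol none --t-end 400 --seed 1 --out runs/unstim
simulated 400.0 days, 14 ovulations, 998 follicles recruited -> runs/unstim

$ ovsim run-experiment --protocol luteal --n-replicates 5 --seed 1 \
      --t-end 150 --out runs/luteal
protocol                  quantity  sim_mean   sim_sd  clinical_mean  clinical_sd clinical_source
  luteal        follicles 10-14 mm       7.6 2.966479           13.9          7.8    Kuang et al.
  luteal         follicles > 14 mm       9.2 6.016644           11.1          5.5    Kuang et al.
  luteal treatment duration (days)       9.0 1.000000           10.2          1.6    Kuang et al.
```

The first run writes tidy CSVs (`hormones.csv` with time/variable/value
rows, `follicles.csv` with per-follicle size trajectories, `events.csv`
with recruitments, LH surges, ovulations and doses) plus run metadata.
The 14 ovulations over 400 days correspond to roughly 30-day cycles; the
experiment table reports the end-of-treatment follicle counts per size bin
and the number of dosing days, side by side with the clinical reference
values embedded for comparison.

From Python:

```python
import ovsim

result = ovsim.simulate(config=ovsim.SimulationConfig(t_end=1300, seed=1))
cycles = ovsim.segment_cycles(result)
summary = ovsim.cycle_summary(cycles)   # mean/SD, Shapiro-Wilk, Pearson r
```

Parameters live in one YAML file (`configs/default.yaml`), grouped by
sub-model; `ovsim validate-config` schema-checks edited copies and
`ovsim write-default-config` regenerates the defaults.

## Layout

```
src/ovsim/
  hormones.py    endocrine ODE right-hand side, Hill machinery, luteal curves
  follicles.py   Poisson recruitment, growth law, life-cycle rules
  engine.py      hybrid integration loop and event handling
  pk.py          hMG pharmacokinetics (Bateman superposition)
  protocols.py   luteal-start and late-follicular-start controllers
  stats.py       cycle segmentation, replicate summaries, hormone checkpoints
  config.py      parameter schema, validation, YAML I/O
  cli.py         command-line entry points and the experiment driver
docs/methods.md  model description, assumptions, calibration, limitations
```
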