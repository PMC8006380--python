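hormone_core:
  gnrh_freq_gain: 5.0
  gnrh_freq_floor: 0.15
  gnrh_freq_p4:
    threshold: 1.5
    exponent: 2.0
    mode: inhibitory
  gnrh_mass_synthesis: 2.0
  gnrh_mass_release: 2.0
  gnrh_e2_inhibitory:
    threshold: 120.0
    exponent: 2.0
    mode: inhibitory
  gnrh_e2_stimulatory:
    threshold: 200.0
    exponent: 8.0
    mode: stimulatory
  gnrh_e2_inhibitory_weight: 1.0
  gnrh_e2_stimulatory_weight: 2.0
  lh_syn_basal: 250.0
  lh_syn_e2_max: 4000.0
  lh_e2:
    threshold: 210.0
    exponent: 10.0
    mode: stimulatory
  lh_p4:
    threshold: 0.35
    exponent: 2.0
    mode: inhibitory
  lh_release: 3.0
  lh_clearance: 14.0
  fsh_syn_basal: 145.0
  fsh_p4:
    threshold: 4.0
    exponent: 2.0
    mode: inhibitory
  fsh_e2:
    threshold: 135.0
    exponent: 5.0
    mode: inhibitory
  fsh_release: 1.0
  fsh_clearance: 5.0
  blood_volume: 2.5
  fsh_transport: 4.0
  fsh_ovary_clearance: 2.0
  fsh_binding: 2.0
  fsh_unbinding: 2.0
  e2_baseline: 20.0
  e2_per_follicle: 0.0075
  e2_size_exponent: 3.5
  p4_baseline: 0.3
luteal:
  amplitude_p4: 13.0
  amplitude_e2: 110.0
  peak_offset: 7.0
  width: 1.8
  luteal_length: 14.0
recruitment:
  base_rate: 0.7
  elevated_rate: 4.5
  fsh_recruit_threshold: 6.5
  sens_mean: 8.0
  sens_sd: 2.0
  seed_size: 2.0
growth:
  growth_rate: 0.6
  max_size: 26.0
  competition_strength: 0.1
  competition_load_exponent: 2.0
  fsh_window_threshold: 10.0
  fsh_window_exponent: 6.0
  gate_exponent: 6.0
  atresia_rate: 0.25
  p4_atresia_boost: 3.0
  p4_atresia:
    threshold: 4.0
    exponent: 4.0
    mode: stimulatory
  p4_growth_inhibition:
    threshold: 8.5
    exponent: 2.0
    mode: inhibitory
  rec_complex_stimulation:
    threshold: 8.0
    exponent: 2.0
    mode: stimulatory
  ovulation_size_threshold: 18.0
  atresia_floor: 1.8
  dominance_size: 15.0
  dominance_floor: 0.3
pk:
  absorption_rate: 3.0
  elimination_rate: 0.35
  scale: 0.044
  lh_activity: false
protocol:
  stop_n_follicles: 3
  stop_size: 18.0
  lf_trigger_size: 14.0
  lf_initial_dose: 150.0
  lf_escalated_dose: 225.0
  lf_escalation_day: 6
  luteal_window:
  - 1.0
  - 3.0
  luteal_max_follicle_size: 8.0
  luteal_dose: 225.0
  dose_hour: 0.3333333333333333
meta:
  schema_version: 1
  provenance:
    hormone_core: calibrated
    luteal: calibrated
    recruitment: calibrated
    growth: calibrated
    pk: calibrated
    protocol: clinical
    luteal.luteal_length: convention
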