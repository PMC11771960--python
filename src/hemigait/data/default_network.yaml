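constants:
  E_syn_exc: -10.0
  E_syn_inh: -75.0
  V_threshold: -50.0
  V_max: 0.0
  k_psi: 1.1
  k_e1: 1.0
  k_e2: 1.0
  t_ramp: 1.0
  chi_reset_tau: 0.01
  extensor_on_scale: 0.05
  gamma_drive: 0.5
burster_defaults:
  C: 20.0
  g_leak: 4.5
  E_leak: -62.5
  g_nap: 5.2
  E_na: 50.0
  theta_m: -40.0
  sigma_m: 6.0
  theta_h: -45.0
  sigma_h: 6.0
  tau_h0: 600.0
simple_defaults:
  C: 20.0
  g_leak: 4.5
  E_leak: -62.5
connections:
- source: F
  target: InF
  target_rel: ipsi
  sign: excitatory
  weight: 30.0
- source: InF
  target: E
  target_rel: ipsi
  sign: inhibitory
  weight: 6.168
- source: E
  target: InE
  target_rel: ipsi
  sign: excitatory
  weight: 30.0
- source: InE
  target: F
  target_rel: ipsi
  sign: inhibitory
  weight: 3.614
- source: F
  target: V0D
  target_rel: ipsi
  sign: excitatory
  weight: 30.0
- source: V0D
  target: F
  target_rel: contra
  sign: inhibitory
  weight: 0.1
- source: F
  target: V2a
  target_rel: ipsi
  sign: excitatory
  weight: 30.0
- source: V2a
  target: V0V
  target_rel: ipsi
  sign: excitatory
  weight: 10.0
- source: V0V
  target: Ini
  target_rel: contra
  sign: excitatory
  weight: 10.0
- source: Ini
  target: F
  target_rel: ipsi
  sign: inhibitory
  weight: 0.5
- source: F
  target: V3
  target_rel: ipsi
  sign: excitatory
  weight: 10.0
- source: V3
  target: F
  target_rel: contra
  sign: excitatory
  weight: 0.5
- source: E
  target: V3E
  target_rel: ipsi
  sign: excitatory
  weight: 10.0
- source: V3E
  target: E
  target_rel: contra
  sign: excitatory
  weight: 6.0
drives:
- drive: alpha
  target: F
  target_rel: ipsi
  sign: excitatory
  weight: 0.84
- drive: alpha
  target: F
  target_rel: contra
  sign: excitatory
  weight: 0.05
- drive: alpha
  target: V2a
  target_rel: ipsi
  sign: excitatory
  weight: 1.0
- drive: gamma
  target: E
  target_rel: ipsi
  sign: excitatory
  weight: 6.393
- drive: alpha
  target: InE
  target_rel: ipsi
  sign: excitatory
  weight: 4.0
feedback:
- feedback: SF_E1
  target: F
  target_rel: ipsi
  sign: excitatory
  weight: 6.6
  gated: true
- feedback: SF_E1
  target: Ini
  target_rel: contra
  sign: excitatory
  weight: 5.101
  gated: true
- feedback: SF_E2
  target: E
  target_rel: ipsi
  sign: excitatory
  weight: 10.0
  gated: true
- feedback: SF_E2
  target: V3E
  target_rel: ipsi
  sign: excitatory
  weight: 2.0
  gated: true
lesion: intact
population_overrides:
  F:
    g_nap: 6.599
    theta_h: -40.066
    sigma_h: 6.732
    tau_h0: 440.0
    sigma_m: 6.6
  E:
    tau_h0: 250.0
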