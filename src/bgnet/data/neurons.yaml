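# Neuron model parameter sets, one block per population.
# Units: mV, ms, pF, nS, pA.  QIF recovery rate `a` is per ms.
# `source` names the published table each block transcribes.

FSN:
  model: qif            # quadratic IF with cubic recovery below v_b
  source: FSN parameter table
  a: 0.2                # recovery current rate, 1/ms
  b: 0.025              # voltage dependency of recovery current (cubic)
  c: -60.0              # spike reset
  C: 80.0               # membrane capacitance
  d: 0.0                # spike-triggered recovery increment
  k: 1.0                # steady-state I-V coefficient
  v_b: -55.0            # recovery-current kink voltage
  v_peak: 25.0          # spike cutoff
  v_r: -64.4            # resting potential
  v_th: -50.0           # threshold potential
  is_fsn_variant: true
  beta_vr: -0.078       # dopamine effect on v_r (5 mV hyperpolarized at alpha=0)

MSN_D1:
  model: qif
  source: MSN parameter table (D1 column)
  a: 0.01
  b: -20.0
  c: -60.0
  C: 15.2
  d: 66.9               # spike-triggered adaptation, D1
  k: 1.0
  v_peak: 40.0
  v_r: -78.2
  v_th: -29.7
  beta_vr: 0.0296       # D1 effect on resting potential
  beta_d: -0.450        # D1 effect on d
  alpha_k: 0.032        # magnitude of D2 effect on k; disabled by default

MSN_D2:
  model: qif
  source: MSN parameter table (D2 column)
  a: 0.01
  b: -20.0
  c: -60.0
  C: 15.2
  d: 91.0               # spike-triggered adaptation, D2
  k: 1.0
  v_peak: 40.0
  v_r: -80.0
  v_th: -29.7
  alpha_k: 0.032        # stored but off: no postsynaptic D2 effect included

GPe_TI:
  model: adex
  source: GPe parameter table (TI values)
  a_sub: 2.5            # subthreshold adaptation
  b_spike: 70.0         # spike-triggered adaptation, TI
  C: 40.0
  Delta_T: 1.7
  E_L: -55.1
  g_L: 1.0
  I_e: 12.0             # bias giving 18 Hz in vitro rate
  tau_w: 20.0
  t_f: 15.0
  V_r: -60.0
  V_T: -54.7
  beta_EL: -0.181       # dopamine effect on E_L (10 mV lower at alpha=0)

GPe_TA:
  model: adex
  source: GPe parameter table (TA values; b, Delta_T, C at 150% of TI)
  a_sub: 2.5
  b_spike: 105.0
  C: 60.0
  Delta_T: 2.55
  E_L: -55.1
  g_L: 1.0
  I_e: 1.0              # bias giving 8 Hz in vitro rate
  tau_w: 20.0
  t_f: 15.0
  V_r: -60.0
  V_T: -54.7
  beta_EL: -0.181

SNr:
  model: adex
  source: SNr parameter table
  a_sub: 3.0
  b_spike: 200.0
  C: 80.0
  Delta_T: 1.8
  E_L: -55.8
  g_L: 3.0
  I_e: 15.0
  tau_w: 20.0
  t_f: 20.0
  V_r: -65.0
  V_T: -55.2
  beta_EL: -0.0896      # dopamine effect on E_L (5 mV lower at alpha=0)

STN:
  model: adex
  source: STN parameter table
  a_sub: 0.3            # applies below -70 mV, otherwise 0
  b_spike: 0.05
  C: 60.0
  Delta_T: 16.2
  E_L: -80.2
  g_L: 10.0
  I_e: 5.0
  tau_w: 333.0
  t_f: 15.0
  V_r: -70.0
  V_T: -64.0
  adaptation_gate_mV: -70.0
  stn_rebound: true     # depolarized reset V_r + max(w-15, 20) when w < 0
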