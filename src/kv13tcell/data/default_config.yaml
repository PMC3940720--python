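# Default kv13tcell run configuration.
#
# Rates are the published Kv1.3 whole-cell fit (all ten constants verbatim);
# scheme and convention are the shipped calibrated topology; cell and Ca
# blocks are the calibrated T-cell defaults (see docs/methods.md).
seed: 0
dt_ms: 0.05
output_dir: out

scheme:
  n_closed: 4
  closed_fwd_mults: [1, 1, 1]
  closed_bwd_mults: [3, 2, 3]

rates:
  a: 0.448
  b: 0.043
  c: 0.003
  d: 0.00008
  A: 280.035
  B: 1.648
  m: 27.530
  n: 17.528
  p: 174.961
  q: 1016.330

convention:
  alpha: 1
  beta: -1
  eta: 1
  phi: 1

population:
  n_channels: 1500
  g_pS: 15.0
  e_rev_mV: -73.0

protocol:
  kind: activation

cell:
  cm_pF: 1.5
  v_rest_mV: -55.0
  g_task_nS: 0.13
  e_task_mV: -100.0
  g_crac_nS: 0.09
  e_crac_mV: 80.0
  g_ik_nS: 0.11
  e_ik_mV: -75.0
  kv_g_total_nS: 4.5
  i_inj_pA: 15.0
  duration_ms: 10000.0

ca:
  e_trans: 0.003      # calibrated; published table value is 0.006
  e_diff: 0.003
  kappa_global: 0.0682
  ik_k50_uM: 0.8
  ik_hill: 4.0

fit:
  free: [a, b, m, n]
  n_particles: 20
  n_iterations: 200
  noise_sd_pA: 0.0
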