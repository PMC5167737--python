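# Default parameters for the STN-GPe network model.
#
# Units: time in ms, potentials in mV, conductances and currents in the
# model's nominal units (pA/um^2 with C = 1 pF/um^2), [Ca] in the model's
# concentration units.  Every constant used by the code lives in this file;
# nothing is hard-coded elsewhere.
#
# Gating-curve conventions:
#   x_inf(v)  = 1 / (1 + exp(-(v - theta_x) / sigma_x))
#   tau_x(v)  = tau_x0 + tau_x1 / (1 + exp(-(v - theta_tau_x) / sigma_tau_x))
#   b_inf(r)  = 1 / (1 + exp((r - theta_b) / sigma_b))
#               - 1 / (1 + exp(-theta_b / sigma_b))
#   H_inf(v)  = 1 / (1 + exp(-(v - Theta_gH) / sigma_gH))

stn:
  cell_class: STN
  C: 1.0
  g_Na: 37.5
  g_K: 45.0
  g_L: 2.25
  g_Ca: 0.5
  g_T: 0.5
  g_AHP: 9.0
  v_Na: 55.0
  v_K: -80.0
  v_L: -60.0
  v_Ca: 140.0
  v_AHP: -80.0
  k1: 15.0
  epsilon: 5.0e-05
  k_Ca: 22.5
  phi_n: 0.75
  phi_h: 0.75
  phi_r: 0.5
  theta_m: -30.0
  sigma_m: 15.0
  theta_h: -39.0
  sigma_h: -3.1
  theta_n: -32.0
  sigma_n: 8.0
  theta_r: -67.0
  sigma_r: -2.0
  theta_a: -63.0
  sigma_a: 7.8
  theta_s: -39.0
  sigma_s: 8.0
  theta_b: 0.4
  sigma_b: -0.1
  tau_n0: 1.0
  tau_n1: 100.0
  theta_tau_n: -80.0
  sigma_tau_n: -26.0
  tau_h0: 1.0
  tau_h1: 500.0
  theta_tau_h: -57.0
  sigma_tau_h: -3.0
  tau_r0: 40.0
  tau_r1: 17.5
  theta_tau_r: 68.0
  sigma_tau_r: -2.2
  I_app: 18.0
  i_app_jitter: 2.0

gpe:
  cell_class: GPe
  C: 1.0
  g_Na: 120.0
  g_K: 30.0
  g_L: 1.0
  g_Ca: 0.15
  g_T: 0.5
  g_AHP: 30.0
  v_Na: 55.0
  v_K: -80.0
  v_L: -65.0
  v_Ca: 120.0
  v_AHP: -80.0
  k1: 30.0
  epsilon: 1.0e-04
  k_Ca: 20.0
  phi_n: 0.05
  phi_h: 0.05
  phi_r: 1.0
  theta_m: -37.0
  sigma_m: 10.0
  theta_h: -58.0
  sigma_h: -12.0
  theta_n: -50.0
  sigma_n: 14.0
  theta_r: -70.0
  sigma_r: -2.0
  theta_a: -57.0
  sigma_a: 2.0
  theta_s: -35.0
  sigma_s: 2.0
  theta_b: 0.4
  sigma_b: -0.1
  tau_n0: 0.05
  tau_n1: 0.27
  theta_tau_n: -40.0
  sigma_tau_n: -12.0
  tau_h0: 0.05
  tau_h1: 0.27
  theta_tau_h: -40.0
  sigma_tau_h: -12.0
  tau_r0: 30.0
  tau_r1: 0.0
  theta_tau_r: 0.0
  sigma_tau_r: -1.0
  I_app: 5.0
  i_app_jitter: 0.0

synapse:
  stn_to_gpe:
    alpha: 5.0
    beta: 1.0
    theta_g: 30.0
    Theta_gH: -39.0
    sigma_gH: 8.0
    g_syn: 0.3
    v_syn: 0.0
    polarity: excitatory
  gpe_to_stn:
    alpha: 2.0
    beta: 0.2
    theta_g: 40.0
    Theta_gH: -57.0
    sigma_gH: 2.0
    g_syn: 0.5
    v_syn: -85.0
    polarity: inhibitory

topology:
  n_stn: 10
  n_gpe: 10

simulation:
  dt: 0.05              # ms, fixed RK4 step
  duration: 20000.0     # ms of simulated time (including transient)
  transient: 1000.0     # ms discarded before any analysis
  spike_threshold: -20.0  # mV, upward crossing
  spike_refractory: 2.0   # ms
  v_init_low: -65.0
  v_init_high: -55.0
  ca_init: 0.3
  s_init: 0.0

analysis:
  beta_band: [10.0, 30.0]   # Hz
  filter_order: 4
  slow_variable: r          # one of {r, Ca, s}
  pca_threshold: 0.8
  lfp_neighborhood: 1       # ring radius of the uniform LFP weighting
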