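alpha_max: 1311.0
alpha_suppression_ratio: 13.9
k_sigma_hyd: 0.000502
k_sigma_hyd_star: 0.83
pde_sigma: 1000.0
K_cyc: 0.1
m_cyc: 2.5
K_cG: 20.0
m_cG: 2.0
K_ex: 0.69
J_cG_max: 2500.0
J_ex_sat: 4.87
f_Ca: 0.33
B_Ca: 20.0
B_cG: 1.0
faraday: 96500.0
avogadro: 6.02e+23
D_cG: 120.0
D_Ca: 15.0
D_T: 2.2
D_E: 1.2
D_R: 1.5
nu_RT: 125.0
nu_RE: 125.0
c_TE: 1.0
k_E: 18.5
k_v: 0.5
lambda0: 105.0
mu0: 12.5
n_step: 1
arrestin_any_state: true
shutoff_mode: mean_path
current_convention: channel_only
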