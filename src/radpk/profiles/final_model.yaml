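theta:
  cl_pop: 23.0
  theta_disease: 0.646
  theta_circadian: 0.683
  circadian_acrophase: 7.0
  circadian_period: 24.0
  vc_pop: 383.0
  theta_age: -0.0129
  age_ref: 31.0
  q_pop: 132.0
  vp_pop: 519.0
  ka: 1.59
  mtt: 1.88
  n_transit: 6.58
  bioavailability_f: 1.0
variance:
  omega_cl: 0.389
  omega_vc: 0.0
  omega_q: 0.0
  omega_vp: 0.0
  omega_ka: 0.0
  omega_mtt: 0.316
  omega_n: 0.447
  omega_iov: 0.698
  sigma_prop: 0.2
  estimated:
  - omega_cl
  - omega_iov
  - sigma_prop
  iov_shared: true
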