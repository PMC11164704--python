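# Nominal study configuration: vulture-like glider in the reference
# thermal, 200 s episodes, full wind curriculum at reduced budget.
seed: 1
glider:
  preset: vulture   # m = 7.75 kg, S = 0.87 m^2, calibrated polar
thermal:
  w_star: 5.0       # m/s, characteristic updraft amplitude
  z_star: 2000.0    # m, characteristic thermal altitude
episode:
  duration: 200.0   # s
  control_interval: 1.0
  memory_size: 8    # previous control steps in the observation
  z0: 500.0         # m
  V0: 15.0          # m/s
  gamma0_deg: -5.0
  init_radius: [80.0, 150.0]   # m, initial annulus around the center
training:
  stages:
    - {u_min: 0.0, u_max: 2.0, budget_seconds: 200000}
    - {u_min: 0.0, u_max: 4.0, budget_seconds: 200000}
    - {u_min: 0.0, u_max: 6.0, budget_seconds: 200000}
  hidden: [200, 200]
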