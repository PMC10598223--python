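{
  "diagnostics": {
    "converged": true,
    "domain_stabilized": true,
    "eta_max_used": 10.0,
    "growth_steps": 0,
    "max_residual": 9.896244592737594e-09,
    "message": "The algorithm converged to the desired accuracy.",
    "n_nodes": 603
  },
  "name": "pseudoplastic_suction_stagnation",
  "params": {
    "M": 0.5,
    "Pr": 6.2,
    "a": 0.1,
    "epsilon": 0.01,
    "f_w": 1.0,
    "flags": {
      "energy_diffusivity_weight": "f_second_power",
      "energy_sign": "corrected",
      "wall_bc_sign": "corrected"
    },
    "n": 0.5,
    "ratios": {
      "A1": 1.0254441539222652,
      "A2": 0.9982536676294251,
      "A3": 1.0301627413673713,
      "A4": 1.0795898104503059,
      "alpha_bf": 1.5181486964920267e-07,
      "sigma_ratio": 1.030303030225994
    }
  },
  "settings": {
    "delta_reg": 1e-08,
    "domain_growth": 2.0,
    "eta_max": 10.0,
    "initial_nodes": 101,
    "max_growth_steps": 8,
    "max_nodes": 200000,
    "seed": 0,
    "tol": 1e-08,
    "wall_delta_factor": 10.0
  },
  "wall": {
    "cf_group": -2.683833897848253,
    "delta99": 4.98560641872666,
    "deltaT99": 1.0697776562131778,
    "fpp0": 1.7124868664631574,
    "nu_group": 0.09827236825508971,
    "theta0": 0.017276317449102803,
    "thetap0": -0.09539499373142668
  }
}
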