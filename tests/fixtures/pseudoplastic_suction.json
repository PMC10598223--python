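{
  "diagnostics": {
    "converged": true,
    "domain_stabilized": true,
    "eta_max_used": 640.0,
    "growth_steps": 6,
    "max_residual": 9.888181464811312e-09,
    "message": "The algorithm converged to the desired accuracy.",
    "n_nodes": 803
  },
  "name": "pseudoplastic_suction",
  "params": {
    "M": 0.5,
    "Pr": 6.2,
    "a": 0.1,
    "epsilon": 0.0,
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
    "cf_group": -2.6822767591106533,
    "delta99": 5.235133676276021,
    "deltaT99": 1.0706206197978905,
    "fpp0": 1.7105003008448005,
    "nu_group": 0.09827138955764068,
    "theta0": 0.01728610442359319,
    "thetap0": -0.09539404368983644
  }
}
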