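{
  "diagnostics": {
    "converged": true,
    "domain_stabilized": true,
    "eta_max_used": 20.0,
    "growth_steps": 1,
    "max_residual": 9.99318238172181e-09,
    "message": "The algorithm converged to the desired accuracy.",
    "n_nodes": 603
  },
  "name": "newtonian_injection_mhd",
  "params": {
    "M": 1.0,
    "Pr": 6.2,
    "a": 0.1,
    "epsilon": 0.0,
    "f_w": -0.5,
    "flags": {
      "energy_diffusivity_weight": "f_second_power",
      "energy_sign": "corrected",
      "wall_bc_sign": "corrected"
    },
    "n": 1.0,
    "ratios": {
      "A1": 1.0,
      "A2": 1.0,
      "A3": 1.0,
      "A4": 1.0,
      "alpha_bf": 1.4711e-07,
      "sigma_ratio": 1.0
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
    "cf_group": -1.8374743122551127,
    "delta99": 3.5841649379494105,
    "deltaT99": 2.6567131089398694,
    "fpp0": 0.9187371561275564,
    "nu_group": 0.06458211824475613,
    "theta0": 0.3541788175524388,
    "thetap0": -0.06458211824475613
  }
}
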