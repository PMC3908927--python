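{
 "units": {
  "U_ss": "eV",
  "U_pp": "eV",
  "U_dd": "eV",
  "zeta_s": "bohr^-1",
  "zeta_p": "bohr^-1",
  "zeta_d": "bohr^-1",
  "beta_s": "eV",
  "beta_p": "eV",
  "beta_d": "eV",
  "F0_sd": "eV",
  "G2_sd": "eV",
  "rho_core": "bohr",
  "alpha": "angstrom^-1",
  "zeta_s_prime": "bohr^-1",
  "zeta_p_prime": "bohr^-1",
  "zeta_d_prime": "bohr^-1",
  "a1": "dimensionless",
  "b1": "angstrom^-2",
  "c1": "angstrom",
  "a2": "dimensionless",
  "b2": "angstrom^-2",
  "c2": "angstrom"
 },
 "parameters": {
  "Dy3+": {
   "U_ss": -20.92623973,
   "U_pp": -7.66730575,
   "U_dd": -17.94081525,
   "zeta_s": 1.2952754,
   "zeta_p": 1.91210659,
   "zeta_d": 1.4133967,
   "beta_s": -7.60670536,
   "beta_p": 1.96173362,
   "beta_d": -4.36852734,
   "F0_sd": 8.30543139,
   "G2_sd": 1.31036509,
   "rho_core": 1.62505501,
   "alpha": 1.34825876,
   "zeta_s_prime": 1.37236617,
   "zeta_p_prime": 1.07407253,
   "zeta_d_prime": 0.8191436,
   "a1": 1.13071544,
   "b1": 7.71195583,
   "c1": 1.53665819,
   "a2": 0.06845575,
   "b2": 7.5065399,
   "c2": 3.23417102
  },
  "Ho3+": {
   "U_ss": -22.05745867,
   "U_pp": -7.59563761,
   "U_dd": -18.00040589,
   "zeta_s": 1.33055043,
   "zeta_p": 1.77955939,
   "zeta_d": 1.53652417,
   "beta_s": -5.64522644,
   "beta_p": 0.00653676,
   "beta_d": -4.31289917,
   "F0_sd": 8.24056943,
   "G2_sd": 1.24543189,
   "rho_core": 1.71955962,
   "alpha": 1.33007543,
   "zeta_s_prime": 1.49803844,
   "zeta_p_prime": 1.96749739,
   "zeta_d_prime": 0.66302146,
   "a1": 1.09070756,
   "b1": 7.57151625,
   "c1": 1.49095411,
   "a2": 0.00141941,
   "b2": 7.79969636,
   "c2": 3.25425084
  },
  "Er3+": {
   "U_ss": -21.97839904,
   "U_pp": -7.60784986,
   "U_dd": -17.97684107,
   "zeta_s": 1.34775672,
   "zeta_p": 1.80648084,
   "zeta_d": 1.46618905,
   "beta_s": -5.63471034,
   "beta_p": -0.01897203,
   "beta_d": -4.25067889,
   "F0_sd": 8.25732681,
   "G2_sd": 1.2487451,
   "rho_core": 2.71713627,
   "alpha": 1.32010273,
   "zeta_s_prime": 1.44675714,
   "zeta_p_prime": 1.97388315,
   "zeta_d_prime": 0.65046083,
   "a1": 1.17417665,
   "b1": 7.58325164,
   "c1": 1.50354881,
   "a2": 0.00864571,
   "b2": 7.81378785,
   "c2": 3.23359665
  }
 }
}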