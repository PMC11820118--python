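# SYNTHETIC parameter fixture for the Mpipi energy terms.
#
# The global constants (bond_k, bond_r0, eps_r, kappa) are the standard
# Mpipi values. The per-pair (eps, sigma, mu, nu) entries below are
# invented-but-plausible placeholder values for a handful of residues,
# shipped only so the module and its tests can run without the
# force-field release; they are NOT the published force-field parameters.
# Supply a full table in this schema for real evaluations.
globals:
  bond_k: 19.1      # kcal mol^-1 A^-2
  bond_r0: 3.81     # A
  eps_r: 80.0
  kappa: 0.126      # A^-1

residues:
  G: {mass: 57.05,  charge: 0.0,  sigma: 4.50}
  S: {mass: 87.08,  charge: 0.0,  sigma: 5.18}
  Y: {mass: 163.18, charge: 0.0,  sigma: 6.46}
  R: {mass: 156.19, charge: 1.0,  sigma: 6.56}
  K: {mass: 128.17, charge: 1.0,  sigma: 6.36}
  D: {mass: 115.09, charge: -1.0, sigma: 5.58}

pairs:
  - {i: G, j: G, eps: 0.10, sigma: 4.50, mu: 2, nu: 1}
  - {i: G, j: S, eps: 0.11, sigma: 4.84, mu: 2, nu: 1}
  - {i: G, j: Y, eps: 0.18, sigma: 5.48, mu: 2, nu: 1}
  - {i: G, j: R, eps: 0.15, sigma: 5.53, mu: 2, nu: 1}
  - {i: G, j: K, eps: 0.12, sigma: 5.43, mu: 2, nu: 1}
  - {i: G, j: D, eps: 0.11, sigma: 5.04, mu: 2, nu: 1}
  - {i: S, j: S, eps: 0.12, sigma: 5.18, mu: 2, nu: 1}
  - {i: S, j: Y, eps: 0.20, sigma: 5.82, mu: 2, nu: 1}
  - {i: S, j: R, eps: 0.16, sigma: 5.87, mu: 2, nu: 1}
  - {i: S, j: K, eps: 0.13, sigma: 5.77, mu: 2, nu: 1}
  - {i: S, j: D, eps: 0.12, sigma: 5.38, mu: 2, nu: 1}
  - {i: Y, j: Y, eps: 0.42, sigma: 6.46, mu: 2, nu: 1}
  - {i: Y, j: R, eps: 0.55, sigma: 6.51, mu: 2, nu: 1}
  - {i: Y, j: K, eps: 0.30, sigma: 6.41, mu: 2, nu: 1}
  - {i: Y, j: D, eps: 0.18, sigma: 6.02, mu: 2, nu: 1}
  - {i: R, j: R, eps: 0.20, sigma: 6.56, mu: 2, nu: 1}
  - {i: R, j: K, eps: 0.16, sigma: 6.46, mu: 2, nu: 1}
  - {i: R, j: D, eps: 0.35, sigma: 6.07, mu: 2, nu: 1}
  - {i: K, j: K, eps: 0.14, sigma: 6.36, mu: 2, nu: 1}
  - {i: K, j: D, eps: 0.30, sigma: 5.97, mu: 2, nu: 1}
  - {i: D, j: D, eps: 0.12, sigma: 5.58, mu: 2, nu: 1}
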