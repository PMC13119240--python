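# Reference potential: partial charges (e) and Lennard-Jones parameters
# (sigma in Å, epsilon in kJ/mol) for the dihydropyridine drugs and PVP.
# Atoms not matching any listed type keep zero charge and the per-element
# neutral defaults below.  Combination rule: Lorentz-Berthelot.
types:
  # dihydropyridine core
  N_NHR:          {q: -0.70, sigma: 3.25, epsilon: 0.170}   # ring N-H nitrogen (N1)
  N_pyridine:     {q: -0.70, sigma: 3.25, epsilon: 0.170}
  H_NHR:          {q:  0.00, sigma: 0.00, epsilon: 0.000}   # amine hydrogen
  C_pyridine_NIF: {q: +0.47, sigma: 3.75, epsilon: 0.105}   # ring carbons, nifedipine
  C_pyridine_FEL: {q: +0.13, sigma: 3.55, epsilon: 0.700}   # ring carbons, felodipine
  C_CH3_CH2:      {q: +0.20, sigma: 3.50, epsilon: 0.066}   # aliphatic CH3 / CH2
  # ester groups
  O_R2CO:         {q: -0.47, sigma: 2.96, epsilon: 0.210}   # carbonyl oxygen (O2; also PVP C=O)
  C_R2CO:         {q: +0.47, sigma: 3.75, epsilon: 0.105}   # carbonyl carbon
  O_ROR:          {q: -0.40, sigma: 2.90, epsilon: 0.140}   # ester ether oxygen (O1)
  C_CH3OR:        {q: +0.20, sigma: 3.50, epsilon: 0.066}   # O-methyl / O-methylene carbon
  # nitro group (nifedipine)
  N_CNO2:         {q: +0.45, sigma: 3.25, epsilon: 0.170}   # nitro nitrogen (N2)
  O_CNO2:         {q: -0.36, sigma: 2.96, epsilon: 0.210}   # nitro oxygens (O3)
  C_CNO2:         {q: +0.18, sigma: 3.75, epsilon: 0.105}   # aryl carbon bearing NO2
  # dichlorophenyl group (felodipine)
  Cl_aryl:        {q:  0.00, sigma: 3.20, epsilon: 0.800}

# Neutral fallbacks for atoms without a tabulated type (aryl CH carbons,
# generic hydrogens, PVP ring nitrogen, ...).  OPLS-like magnitudes.
element_defaults:
  H:  {q: 0.0, sigma: 2.50, epsilon: 0.125}
  C:  {q: 0.0, sigma: 3.55, epsilon: 0.290}
  N:  {q: 0.0, sigma: 3.25, epsilon: 0.170}
  O:  {q: 0.0, sigma: 2.96, epsilon: 0.210}
  Cl: {q: 0.0, sigma: 3.40, epsilon: 1.090}
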