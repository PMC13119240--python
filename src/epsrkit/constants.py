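"""Physical constants and small per-element data tables.

Only the elements occurring in dihydropyridine drugs and PVP (H, C, N, O, Cl)
are tabulated; :func:`require_element` raises a clear error for anything else.
"""

from __future__ import annotations

import numpy as np

#: Boltzmann constant in kJ mol^-1 K^-1.
K_B = 0.008314462618

#: Coulomb prefactor e^2/(4 pi eps0) in kJ Å mol^-1 e^-2.
COULOMB_KJ_A = 1389.35

#: Avogadro's number, mol^-1.
N_AVOGADRO = 6.02214076e23

#: Standard atomic masses, g/mol.
ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Cl": 35.45,
}

#: Atomic numbers (Q -> 0 limit of the X-ray form factor).
ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8, "Cl": 17}

#: Single-bond covalent radii in Å, used for bond perception (sum x 1.2).
COVALENT_RADIUS = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "Cl": 1.02}

# Cromer-Mann 4-Gaussian X-ray form-factor coefficients (International
# Tables for Crystallography C, table 6.1.1.4): f(s) = sum a_i exp(-b_i s^2) + c
# with s = sin(theta)/lambda = Q/(4 pi).  Cross-checked against gemmi's IT92
# table in the test suite.
CROMER_MANN = {
    "H": ([0.493002, 0.322912, 0.140191, 0.040810],
          [10.5109, 26.1257, 3.14236, 57.7997], 0.003038),
    "C": ([2.31000, 1.02000, 1.58860, 0.865000],
          [20.8439, 10.2075, 0.568700, 51.6512], 0.215600),
    "N": ([12.2126, 3.13220, 2.01250, 1.16630],
          [0.005700, 9.89330, 28.9975, 0.582600], -11.529),
    "O": ([3.04850, 2.28680, 1.54630, 0.867000],
          [13.2771, 5.70110, 0.323900, 32.9089], 0.250800),
    "Cl": ([11.4604, 7.19640, 6.25560, 1.64550],
           [0.010400, 1.16620, 18.5194, 47.7784], -9.5574),
}


def require_element(symbol: str) -> str:
    """Return *symbol* if it is a supported element, else raise ``ValueError``."""
    if symbol not in ATOMIC_MASS:
        raise ValueError(
            f"unsupported element {symbol!r}; supported: {sorted(ATOMIC_MASS)}"
        )
    return symbol


def xray_form_factor(element: str, Q: np.ndarray) -> np.ndarray:
    """Cromer-Mann X-ray atomic form factor f(Q), Q in Å^-1."""
    require_element(element)
    a, b, c = CROMER_MANN[element]
    s2 = (np.asarray(Q, dtype=float) / (4.0 * np.pi)) ** 2
    f = np.full_like(s2, c, dtype=float)
    for ai, bi in zip(a, b):
        f += ai * np.exp(-bi * s2)
    return f


def molecular_mass(formula_counts: dict[str, int]) -> float:
    """Molar mass in g/mol from an element->count mapping."""
    return sum(ATOMIC_MASS[require_element(el)] * n for el, n in formula_counts.items())
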