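"""Post-refinement structural observables.

Running coordination numbers n_ab(r), a geometric hydrogen-bond census,
drug-drug versus drug-polymer acceptor preference, and density unit
conversions.  The hydrogen-bond criteria (N···O distance ceiling and
N-H···O angle floor) are explicit inputs everywhere: X-ray refinement
constrains distances, so the bond census is a geometric diagnosis, not a
spectroscopic one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .boxes import Configuration, minimum_image
from .constants import ATOMIC_MASS, N_AVOGADRO
from .scattering import PairFunctionSet

__all__ = [
    "CoordinationCurve",
    "running_coordination",
    "HBondCriteria",
    "hbond_census",
    "default_acceptor_classes",
    "drug_polymer_preference",
    "PreferenceResult",
    "density_convert",
    "mass_density_to_number",
    "parse_formula",
]


@dataclass
class CoordinationCurve:
    """Running coordination number n(r): average b neighbors within r of a."""

    r: np.ndarray
    n: np.ndarray
    central: str
    neighbor: str

    def crossing(self, level: float) -> float:
        """First r at which n(r) reaches *level* (linear interpolation)."""
        idx = np.nonzero(self.n >= level)[0]
        if not len(idx):
            raise ValueError(f"n(r) never reaches {level}")
        i = idx[0]
        if i == 0:
            return float(self.r[0])
        return float(
            np.interp(level, [self.n[i - 1], self.n[i]], [self.r[i - 1], self.r[i]])
        )

    def at(self, r_query: float) -> float:
        return float(np.interp(r_query, self.r, self.n))


def running_coordination(pairset: PairFunctionSet, a: str, b: str) -> CoordinationCurve:
    """n_ab(r) = 4 pi rho c_b int_0^r g_ab(r') r'^2 dr' (trapezoidal)."""
    key = tuple(sorted((a, b)))
    if key not in pairset.g:
        raise KeyError(f"no partial for pair {a}-{b}")
    g = pairset.g[key]
    r = pairset.r
    rho_b = pairset.rho * pairset.c[b]
    integrand = g * r**2
    n = 4.0 * np.pi * rho_b * cumulative_trapezoid(integrand, r, initial=0.0)
    return CoordinationCurve(r=r, n=n, central=a, neighbor=b)


# ---------------------------------------------------------------------------
# hydrogen-bond census
# ---------------------------------------------------------------------------


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond definition.

    Defaults: N···O <= 3.5 Å and N-H···O angle >= 120 deg.  Every reported
    census should echo its criteria; the distances printed by structural
    studies depend on them.
    """

    donor_n_type: str = "N_NHR"
    d_max: float = 3.5
    angle_min: float = 120.0

    def __post_init__(self):
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not 0.0 <= self.angle_min <= 180.0:
            raise ValueError("angle_min must be within [0, 180]")


def default_acceptor_classes() -> dict:
    """Acceptor classification used throughout the drug/PVP analyses.

    Ester carbonyl oxygens (the crystal-phase acceptor), nitro oxygens
    (the competing acceptor in amorphous nifedipine) and PVP pyrrolidone
    carbonyls; distinguished by force-field type and host template.
    """

    def is_pvp(t):
        return "pvp" in t.name.lower() or "pyrrolidone" in t.name.lower()

    return {
        "ester_carbonyl": lambda t, a: a.type_key == "O_R2CO" and not is_pvp(t),
        "nitro": lambda t, a: a.type_key == "O_CNO2",
        "pvp_carbonyl": lambda t, a: a.type_key == "O_R2CO" and is_pvp(t),
    }


def _donor_sites(config: Configuration, donor_n_type: str):
    """(mol, N index, H index) triples for every donor N-H in the box."""
    out = []
    for imol, t in enumerate(config.templates):
        labels = t.labels
        idx = {lab: i for i, lab in enumerate(labels)}
        for a in t.atoms:
            if a.type_key != donor_n_type:
                continue
            for nb in t.bonded_labels(a.label):
                if t.atoms[idx[nb]].element == "H":
                    out.append((imol, idx[a.label], idx[nb]))
    return out


def _acceptor_sites(config: Configuration, classes: dict):
    out = []  # (mol, atom index, class name)
    for imol, t in enumerate(config.templates):
        for i, a in enumerate(t.atoms):
            for name, sel in classes.items():
                if sel(t, a):
                    out.append((imol, i, name))
                    break
    return out


def hbond_census(
    config: Configuration,
    criteria: HBondCriteria | None = None,
    acceptor_classes: dict | None = None,
) -> pd.DataFrame:
    """Enumerate intermolecular hydrogen bonds under geometric criteria.

    Returns one row per (donor, acceptor) contact satisfying d(N···O) <=
    d_max and angle(N-H···O) >= angle_min with minimum-image geometry;
    ``attrs`` carry the criteria, the number of donors and the mean number
    of bonds per donor, with per-class counts.
    """
    criteria = criteria or HBondCriteria()
    classes = acceptor_classes or default_acceptor_classes()
    donors = _donor_sites(config, criteria.donor_n_type)
    acceptors = _acceptor_sites(config, classes)
    L = config.box_edge
    rows = []
    for dm, ni, hi in donors:
        n_xyz = config.coords[dm][ni]
        h_xyz = config.coords[dm][hi]
        for am, ai, cls in acceptors:
            if am == dm:
                continue
            o_raw = config.coords[am][ai]
            # nearest image of the acceptor relative to the donor N
            shift = minimum_image(o_raw - n_xyz, L) - (o_raw - n_xyz)
            o_xyz = o_raw + shift
            d = float(np.linalg.norm(o_xyz - n_xyz))
            if d > criteria.d_max:
                continue
            v1 = n_xyz - h_xyz
            v2 = o_xyz - h_xyz
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle < criteria.angle_min:
                continue
            rows.append(
                {
                    "donor_mol": dm,
                    "donor_label": config.templates[dm].atoms[ni].label,
                    "acceptor_mol": am,
                    "acceptor_label": config.templates[am].atoms[ai].label,
                    "acceptor_template": config.templates[am].name,
                    "acceptor_class": cls,
                    "d_NO": d,
                    "angle_NHO": angle,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "donor_mol", "donor_label", "acceptor_mol", "acceptor_label",
            "acceptor_template", "acceptor_class", "d_NO", "angle_NHO",
        ],
    )
    df.attrs["criteria"] = criteria
    df.attrs["n_donors"] = len(donors)
    df.attrs["bonds_per_donor"] = len(df) / len(donors) if donors else float("nan")
    df.attrs["by_class"] = df.acceptor_class.value_counts().to_dict() if len(df) else {}
    return df


# ---------------------------------------------------------------------------
# drug-drug vs drug-polymer preference
# ---------------------------------------------------------------------------


@dataclass
class PreferenceResult:
    r: np.ndarray
    curves: dict[str, np.ndarray]  # class -> n(r) per donor
    n_at_cut: dict[str, float]
    r_cut: float
    ratio: float  # drug-drug / drug-polymer coordination at r_cut
    flag: str = ""

    def total(self) -> np.ndarray:
        return np.sum(list(self.curves.values()), axis=0)


def drug_polymer_preference(
    configs: Configuration | list[Configuration],
    r_cut: float = 5.0,
    criteria: HBondCriteria | None = None,
    acceptor_classes: dict | None = None,
    drug_classes: tuple[str, ...] = ("ester_carbonyl", "nitro"),
    polymer_classes: tuple[str, ...] = ("pvp_carbonyl",),
    dr: float = 0.05,
) -> PreferenceResult:
    """Class-resolved donor-N -> acceptor-O coordination in a mixture.

    Direct neighbor counting (ensemble-averaged) of acceptor oxygens around
    each donor nitrogen, split by acceptor class; the headline number is
    the drug-drug : drug-polymer coordination ratio at ``r_cut``.  A ratio
    with a zero denominator or numerator is flagged 'polymer-only' /
    'drug-only'.
    """
    if isinstance(configs, Configuration):
        configs = [configs]
    if not configs:
        raise ValueError("empty ensemble")
    criteria = criteria or HBondCriteria()
    classes = acceptor_classes or default_acceptor_classes()
    cfg0 = configs[0]
    donors = _donor_sites(cfg0, criteria.donor_n_type)
    acceptors = _acceptor_sites(cfg0, classes)
    present = {cls for _, _, cls in acceptors}
    for cls in drug_classes + polymer_classes:
        if cls not in present and cls in polymer_classes:
            raise ValueError(f"acceptor class {cls!r} absent from the box")
    if not donors:
        raise ValueError("no donor sites in the box")
    L = cfg0.box_edge
    r_max = min(L / 2.0, r_cut + 3.0)
    edges = np.arange(0.0, r_max + dr, dr)
    r = edges[1:]
    hists = {cls: np.zeros(len(r)) for cls in classes}
    for cfg in configs:
        for dm, ni, _ in donors:
            n_xyz = cfg.coords[dm][ni]
            for am, ai, cls in acceptors:
                if am == dm:
                    continue
                d = minimum_image(cfg.coords[am][ai] - n_xyz, L)
                dist = float(np.linalg.norm(d))
                if dist < r_max:
                    hists[cls][min(int(dist / dr), len(r) - 1)] += 1.0
    norm = len(configs) * len(donors)
    curves = {cls: np.cumsum(h) / norm for cls, h in hists.items()}
    n_at_cut = {cls: float(np.interp(r_cut, r, c)) for cls, c in curves.items()}
    n_drug = sum(n_at_cut.get(cls, 0.0) for cls in drug_classes)
    n_poly = sum(n_at_cut.get(cls, 0.0) for cls in polymer_classes)
    if n_poly == 0 and n_drug == 0:
        ratio, flag = float("nan"), "no contacts"
    elif n_poly == 0:
        ratio, flag = float("inf"), "drug-only"
    elif n_drug == 0:
        ratio, flag = 0.0, "polymer-only"
    else:
        ratio, flag = n_drug / n_poly, ""
    return PreferenceResult(r=r, curves=curves, n_at_cut=n_at_cut, r_cut=r_cut,
                            ratio=ratio, flag=flag)


# ---------------------------------------------------------------------------
# density conversions
# ---------------------------------------------------------------------------

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a simple molecular formula like ``C17H18N2O6``."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"unparseable formula {formula!r}")
        pos = m.end()
        el = m.group(1)
        if el not in ATOMIC_MASS:
            raise ValueError(f"unknown element {el!r} in formula {formula!r}")
        counts[el] = counts.get(el, 0) + (int(m.group(2)) if m.group(2) else 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"unparseable formula {formula!r}")
    return counts


def density_convert(n_atoms_per_A3: float, formula: str) -> float:
    """Atom number density (atoms/Å³) -> mass density (g/cm³)."""
    if n_atoms_per_A3 < 0:
        raise ValueError("number density must be non-negative")
    counts = parse_formula(formula)
    atoms_per_molecule = sum(counts.values())
    M = sum(ATOMIC_MASS[el] * n for el, n in counts.items())
    return n_atoms_per_A3 / atoms_per_molecule * M / N_AVOGADRO * 1e24


def mass_density_to_number(rho_g_cm3: float, formula: str) -> float:
    """Mass density (g/cm³) -> atom number density (atoms/Å³)."""
    if rho_g_cm3 < 0:
        raise ValueError("mass density must be non-negative")
    counts = parse_formula(formula)
    atoms_per_molecule = sum(counts.values())
    M = sum(ATOMIC_MASS[el] * n for el, n in counts.items())
    return rho_g_cm3 * atoms_per_molecule / M * N_AVOGADRO * 1e-24
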