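"""Shared fixtures: force fields, templates and small test systems."""

import numpy as np
import pytest

from epsrkit.boxes import Configuration
from epsrkit.molecules import (
    AtomSpec,
    FFEntry,
    ForceField,
    MolecularTemplate,
    load_bundled_template,
    load_default_forcefield,
)


@pytest.fixture(scope="session")
def ff():
    return load_default_forcefield()


@pytest.fixture(scope="session")
def nif():
    return load_bundled_template("nif_alpha")


@pytest.fixture(scope="session")
def nif_flipped():
    return load_bundled_template("nif_flipped")


@pytest.fixture(scope="session")
def fel():
    return load_bundled_template("fel_R")


@pytest.fixture(scope="session")
def lj_ff(ff):
    """Single-site Lennard-Jones force field (sigma 3.4 Å, epsilon 1 kJ/mol)."""
    return ForceField(entries={"LJS": FFEntry(0.0, 3.4, 1.0)},
                      element_defaults=ff.element_defaults)


@pytest.fixture(scope="session")
def lj_template():
    from epsrkit.synthetic_data import lj_site_template

    return lj_site_template()


def make_point_config(positions, box_edge, element="C", type_key="LJS",
                      temperature_K=300.0):
    """Box of single-atom molecules at the given positions."""
    tpl = MolecularTemplate(
        name=f"lj_{element}", conformer_id="site",
        atoms=[AtomSpec("X1", element, type_key, (0.0, 0.0, 0.0))],
        bonds=[], rotatable_groups=[],
    )
    positions = np.asarray(positions, dtype=float)
    return Configuration(
        box_edge=box_edge,
        templates=[tpl] * len(positions),
        coords=[p.reshape(1, 3) for p in positions],
        temperature_K=temperature_K,
    )


def _nerf(a, b, c, bond, angle_deg, torsion_deg):
    """Place the next chain atom from bond length, angle and torsion."""
    bc = c - b
    bc_u = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc_u)
    ang, tor = np.deg2rad(angle_deg), np.deg2rad(torsion_deg)
    d = np.array([-bond * np.cos(ang), bond * np.sin(ang) * np.cos(tor),
                  bond * np.sin(ang) * np.sin(tor)])
    return c + np.column_stack([bc_u, m, n]) @ d


def cl_chain_template(conformer="extended"):
    """Rigid Cl-C-C-C-Cl chain: 'extended' (all-trans, Cl···Cl 6.3 Å) vs
    'folded' (hairpin, Cl···Cl 3.1 Å).  The heavy chlorine termini give the
    two conformers strongly distinct X-ray-weighted intramolecular spectra,
    the same contrast that distinguishes aryl-flip conformers in the drugs."""
    t1, t2 = (180.0, 180.0) if conformer == "extended" else (30.0, 60.0)
    a1 = np.array([-1.75, 0.0, 0.0])
    a2 = np.zeros(3)
    a3 = np.array([1.5 * np.cos(np.deg2rad(70.5)),
                   1.5 * np.sin(np.deg2rad(70.5)), 0.0])
    a4 = _nerf(a1, a2, a3, 1.5, 109.5, t1)
    a5 = _nerf(a2, a3, a4, 1.75, 109.5, t2)
    pts = [a1, a2, a3, a4, a5]
    els = ["Cl", "C", "C", "C", "Cl"]
    labs = ["CL1", "C1", "C2", "C3", "CL2"]
    atoms = [AtomSpec(l, e, "LJS" if e == "C" else "default", tuple(p))
             for l, e, p in zip(labs, els, pts)]
    return MolecularTemplate(
        name=f"clchain_{conformer}", conformer_id=conformer, atoms=atoms,
        bonds=[("CL1", "C1"), ("C1", "C2"), ("C2", "C3"), ("C3", "CL2")],
        rotatable_groups=[],
    ).validate()


def toy_chain_template(conformer="trans", type_key="LJS"):
    """Rigid 4-site carbon chain; 'trans' and 'cis' differ in the dihedral,
    giving distinct intramolecular distance spectra."""
    b, ang = 1.5, np.deg2rad(109.5)
    p0 = np.array([0.0, 0.0, 0.0])
    p1 = np.array([b, 0.0, 0.0])
    p2 = p1 + b * np.array([-np.cos(ang), np.sin(ang), 0.0])
    if conformer == "trans":
        p3 = p2 + b * np.array([np.cos(ang), np.sin(ang), 0.0])
    else:  # cis: fold back
        p3 = p2 + b * np.array([-np.cos(ang), -np.sin(ang) * np.cos(1.0),
                                np.sin(ang) * np.sin(1.0)])
        p3 = p2 + b * (p1 - p2 + np.array([0, 0, 1.2])) / np.linalg.norm(
            p1 - p2 + np.array([0, 0, 1.2])
        )
    atoms = [
        AtomSpec("C1", "C", type_key, tuple(p0)),
        AtomSpec("C2", "C", type_key, tuple(p1)),
        AtomSpec("C3", "C", type_key, tuple(p2)),
        AtomSpec("C4", "C", type_key, tuple(p3)),
    ]
    return MolecularTemplate(
        name=f"chain_{conformer}", conformer_id=conformer, atoms=atoms,
        bonds=[("C1", "C2"), ("C2", "C3"), ("C3", "C4")],
        rotatable_groups=[],
    ).validate()
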