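"""Semi-rigid molecular templates and the reference force field.

A :class:`MolecularTemplate` is a rigid molecular skeleton plus a small set of
rotatable groups (ester, nitro and methyl torsions for the dihydropyridine
drugs) — the "semi-rigid" molecule model used throughout the refinement.
Force-field assignment is by ``type_key``: each atom carries the name of a
row in the reference potential table (partial charge q, Lennard-Jones sigma
and epsilon); unlisted atoms fall back to neutral per-element defaults.

Bundled templates (``epsrkit/data/templates``): nifedipine in its alpha-,
beta- and aryl-ring-flipped conformations, the R- and S-enantiomers of
felodipine, and a capped vinylpyrrolidone monomer from which PVP oligomers
are grown.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import yaml

from .constants import ATOMIC_MASS, require_element

__all__ = [
    "AtomSpec",
    "RotatableGroup",
    "MolecularTemplate",
    "ForceField",
    "FFEntry",
    "ConformerMixture",
    "load_template",
    "save_template",
    "load_bundled_template",
    "bundled_template_names",
    "load_default_forcefield",
    "rotate_group",
    "build_pvp_oligomer",
    "lj_coulomb_energy",
    "rotation_matrix",
]

BOND_MIN = 0.9  # Å, sanity bounds on covalent bonds in a template
BOND_MAX = 1.9


@dataclass(frozen=True)
class AtomSpec:
    """One atom of a template: identity, force-field type and position (Å)."""

    label: str
    element: str
    type_key: str
    position: tuple[float, float, float]

    def __post_init__(self):
        require_element(self.element)


@dataclass(frozen=True)
class RotatableGroup:
    """A torsion: rotation about the ``axis`` bond moves the ``moved`` atoms."""

    axis: tuple[str, str]
    moved: frozenset[str]


@dataclass
class MolecularTemplate:
    """A semi-rigid molecule: atoms, bond graph and rotatable groups."""

    name: str
    conformer_id: str
    atoms: list[AtomSpec]
    bonds: list[tuple[str, str]]
    rotatable_groups: list[RotatableGroup] = field(default_factory=list)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def labels(self) -> list[str]:
        return [a.label for a in self.atoms]

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no atom labelled {label!r} in template {self.name}")

    def positions(self) -> np.ndarray:
        """Template-frame coordinates as an (n, 3) float array."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def formula_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a in self.atoms:
            counts[a.element] = counts.get(a.element, 0) + 1
        return counts

    def formula(self) -> str:
        """Hill-order molecular formula, e.g. ``C18H19Cl2NO4``."""
        counts = self.formula_counts()
        order = ["C", "H"] + sorted(set(counts) - {"C", "H"})
        return "".join(
            f"{el}{counts[el] if counts[el] > 1 else ''}" for el in order if el in counts
        )

    def molar_mass(self) -> float:
        return sum(ATOMIC_MASS[a.element] for a in self.atoms)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        g.add_edges_from(self.bonds)
        return g

    def bonded_labels(self, label: str) -> list[str]:
        return sorted(self.graph().neighbors(label))

    # -- exclusions --------------------------------------------------------

    def intra_nonbonded_mask(self) -> np.ndarray:
        """Boolean (n, n) matrix of intramolecular pairs in the nonbonded sum.

        1-2 and 1-3 pairs (graph distance <= 2) are excluded; 1-4 and beyond
        are included at full strength.
        """
        n = self.n_atoms
        g = nx.Graph()
        g.add_nodes_from(range(n))
        idx = {lab: i for i, lab in enumerate(self.labels)}
        g.add_edges_from((idx[a], idx[b]) for a, b in self.bonds)
        mask = np.ones((n, n), dtype=bool)
        np.fill_diagonal(mask, False)
        lengths = dict(nx.all_pairs_shortest_path_length(g, cutoff=2))
        for i, d in lengths.items():
            for j in d:
                if i != j:
                    mask[i, j] = False
        return mask

    # -- validation --------------------------------------------------------

    def validate(self) -> "MolecularTemplate":
        """Check all template invariants; return self or raise ``ValueError``."""
        labels = self.labels
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate atom labels in template {self.name}")
        for a, b in self.bonds:
            if a not in labels or b not in labels:
                raise ValueError(f"bond ({a}, {b}) references unknown atom")
        g = self.graph()
        if self.n_atoms and not nx.is_connected(g):
            raise ValueError(f"bond graph of {self.name} is disconnected")
        pos = self.positions()
        idx = {lab: i for i, lab in enumerate(labels)}
        for a, b in self.bonds:
            d = float(np.linalg.norm(pos[idx[a]] - pos[idx[b]]))
            if not (BOND_MIN <= d <= BOND_MAX):
                raise ValueError(
                    f"bond {a}-{b} in {self.name} has length {d:.3f} Å "
                    f"outside [{BOND_MIN}, {BOND_MAX}]"
                )
        for k, grp in enumerate(self.rotatable_groups):
            a, b = grp.axis
            if a in grp.moved or b in grp.moved:
                raise ValueError(f"group {k}: axis atom inside moved set")
            h = g.copy()
            if not h.has_edge(a, b):
                raise ValueError(f"group {k}: axis ({a}, {b}) is not a bond")
            h.remove_edge(a, b)
            comp_b = nx.node_connected_component(h, b)
            if comp_b == set(g.nodes):
                raise ValueError(f"group {k}: axis bond is in a ring")
            if frozenset(comp_b - {b}) != grp.moved:
                raise ValueError(
                    f"group {k}: moved set does not match the fragment cut off "
                    f"by removing the axis bond"
                )
        return self


@dataclass(frozen=True)
class FFEntry:
    """Reference-potential parameters for one atom type."""

    q: float  # partial charge, e
    sigma: float  # Å
    epsilon: float  # kJ/mol

    def __post_init__(self):
        if self.sigma < 0 or self.epsilon < 0:
            raise ValueError("sigma and epsilon must be non-negative")


@dataclass
class ForceField:
    """Type-keyed reference potential with per-element neutral defaults.

    Combination is Lorentz-Berthelot (arithmetic sigma, geometric epsilon).
    """

    entries: dict[str, FFEntry]
    element_defaults: dict[str, FFEntry] = field(default_factory=dict)
    combining_rule: str = "lorentz-berthelot"

    def resolve(self, type_key: str, element: str) -> FFEntry:
        if type_key in self.entries:
            return self.entries[type_key]
        if type_key == "default" and element in self.element_defaults:
            return self.element_defaults[element]
        if element in self.element_defaults:
            return self.element_defaults[element]
        raise KeyError(f"cannot resolve force-field type {type_key!r} ({element})")

    def raw_charges(self, template: MolecularTemplate) -> np.ndarray:
        return np.array(
            [self.resolve(a.type_key, a.element).q for a in template.atoms]
        )

    def charges(self, template: MolecularTemplate) -> np.ndarray:
        """Per-atom charges with a uniform neutralizing correction.

        A molecule whose tabulated charges do not sum to zero gets the excess
        removed evenly from its zero-charge atoms, so each molecule is exactly
        neutral — a requirement for box-size-independent cutoff
        electrostatics.  A template with no zero-charge atoms keeps its
        charges untouched (there is nowhere to absorb the correction).
        """
        q = self.raw_charges(template)
        net = q.sum()
        neutral = np.abs(q) < 1e-12
        if abs(net) < 1e-12 or not neutral.any():
            return q
        q = q.copy()
        q[neutral] -= net / neutral.sum()
        return q

    def lj_params(self, template: MolecularTemplate) -> tuple[np.ndarray, np.ndarray]:
        sig = np.array(
            [self.resolve(a.type_key, a.element).sigma for a in template.atoms]
        )
        eps = np.array(
            [self.resolve(a.type_key, a.element).epsilon for a in template.atoms]
        )
        return sig, eps


@dataclass
class ConformerMixture:
    """A mixture of conformer templates with fixed composition.

    ``counts`` realizes the fractions for ``total`` molecules: largest-
    remainder rounding keeps the counts integer while summing to ``total``.
    """

    components: list[tuple[MolecularTemplate, float]]
    total: int

    def __post_init__(self):
        fracs = np.array([f for _, f in self.components], dtype=float)
        if np.any(fracs < 0):
            raise ValueError("fractions must be non-negative")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if self.total < 0:
            raise ValueError("total must be non-negative")

    def counts(self) -> list[int]:
        fracs = np.array([f for _, f in self.components], dtype=float)
        ideal = fracs * self.total
        base = np.floor(ideal).astype(int)
        short = self.total - base.sum()
        order = np.argsort(-(ideal - base))
        base[order[:short]] += 1
        return base.tolist()

    def templates_expanded(self) -> list[MolecularTemplate]:
        out: list[MolecularTemplate] = []
        for (tpl, _), n in zip(self.components, self.counts()):
            out.extend([tpl] * n)
        return out


# ---------------------------------------------------------------------------
# template I/O
# ---------------------------------------------------------------------------


def _template_from_dict(doc: dict) -> MolecularTemplate:
    atoms = [
        AtomSpec(str(lab), str(el), str(tk), (float(x), float(y), float(z)))
        for lab, el, tk, x, y, z in doc["atoms"]
    ]
    bonds = [(str(a), str(b)) for a, b in doc.get("bonds", [])]
    groups = [
        RotatableGroup(
            (str(g["axis"][0]), str(g["axis"][1])),
            frozenset(str(m) for m in g["moved"]),
        )
        for g in doc.get("rotatable_groups", [])
    ]
    tpl = MolecularTemplate(
        name=str(doc.get("name", "molecule")),
        conformer_id=str(doc.get("conformer_id", "")),
        atoms=atoms,
        bonds=bonds,
        rotatable_groups=groups,
    )
    return tpl.validate()


def load_template(source) -> MolecularTemplate:
    """Load and validate a template from a YAML file path or open stream."""
    if hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    return _template_from_dict(doc)


def save_template(template: MolecularTemplate, path) -> None:
    """Write a template to the structured-text (YAML) format."""
    doc = {
        "name": template.name,
        "conformer_id": template.conformer_id,
        "atoms": [
            [a.label, a.element, a.type_key] + [round(float(x), 4) for x in a.position]
            for a in template.atoms
        ],
        "bonds": [list(b) for b in template.bonds],
        "rotatable_groups": [
            {"axis": list(g.axis), "moved": sorted(g.moved)}
            for g in template.rotatable_groups
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, default_flow_style=None)


_DATA = importlib.resources.files("epsrkit") / "data"


def bundled_template_names() -> list[str]:
    return sorted(
        p.name[: -len(".yaml")]
        for p in (_DATA / "templates").iterdir()
        if p.name.endswith(".yaml")
    )


def load_bundled_template(name: str) -> MolecularTemplate:
    """Load one of the shipped templates by name (see ``bundled_template_names``)."""
    res = _DATA / "templates" / f"{name}.yaml"
    with res.open() as fh:
        return load_template(fh)


def load_default_forcefield() -> ForceField:
    """The bundled reference potential (tabulated charges + LJ parameters)."""
    with (_DATA / "forcefield.yaml").open() as fh:
        doc = yaml.safe_load(fh)
    entries = {
        k: FFEntry(float(v["q"]), float(v["sigma"]), float(v["epsilon"]))
        for k, v in doc["types"].items()
    }
    defaults = {
        k: FFEntry(float(v["q"]), float(v["sigma"]), float(v["epsilon"]))
        for k, v in doc["element_defaults"].items()
    }
    return ForceField(entries=entries, element_defaults=defaults)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about *axis* (need not be normalized)."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("zero rotation axis")
    k = axis / norm
    th = np.deg2rad(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def rotate_group(
    template: MolecularTemplate,
    coords: np.ndarray,
    group_index: int,
    angle_deg: float,
) -> np.ndarray:
    """Rotate one rotatable group of a template instance.

    Parameters
    ----------
    coords : (n, 3) array
        Instance coordinates ordered as ``template.atoms``.
    group_index : int
        Index into ``template.rotatable_groups``.
    angle_deg : float
        Rotation angle about the axis bond, in degrees.

    Returns a new coordinate array; only the moved-set atoms change.
    """
    if not 0 <= group_index < len(template.rotatable_groups):
        raise IndexError(f"invalid rotatable-group index {group_index}")
    grp = template.rotatable_groups[group_index]
    coords = np.array(coords, dtype=float)
    ia = template.index_of(grp.axis[0])
    ib = template.index_of(grp.axis[1])
    origin = coords[ib]
    R = rotation_matrix(coords[ib] - coords[ia], angle_deg)
    moved_idx = [template.index_of(lab) for lab in sorted(grp.moved)]
    coords[moved_idx] = (coords[moved_idx] - origin) @ R.T + origin
    return coords


# ---------------------------------------------------------------------------
# PVP oligomer builder
# ---------------------------------------------------------------------------

_HEAD, _TAIL = "CB1", "CB2"  # backbone CH2 / CH carbons of the monomer
_HEAD_CAP, _TAIL_CAP = "HB1c", "HB2c"  # cap hydrogens removed on linking


def build_pvp_oligomer(n_monomers: int, monomer: MolecularTemplate | None = None) -> MolecularTemplate:
    """Grow a hydrogen-capped poly(vinylpyrrolidone) chain.

    Each vinylpyrrolidone repeat unit contributes a -CH2-CH(pyrrolidone)-
    backbone segment (C6H9NO, 17 atoms); the chain ends keep one extra cap
    hydrogen each, so an ``n``-mer has ``17 n + 2`` atoms.  Successive
    monomers are attached along the direction of the removed cap hydrogen,
    with the roll angle about each new backbone bond chosen (deterministically)
    to maximize clearance from the already-built chain.

    The pyrrolidone carbonyl oxygen of every monomer carries the carbonyl
    acceptor type (``O_R2CO``), so hydrogen-bond analyses see it as an
    acceptor without further configuration.
    """
    if n_monomers < 1:
        raise ValueError("n_monomers must be >= 1")
    if monomer is None:
        monomer = load_bundled_template("pvp_monomer")
    mlabels = monomer.labels
    mpos = monomer.positions()
    midx = {lab: i for i, lab in enumerate(mlabels)}

    atoms: list[AtomSpec] = []
    bonds: list[tuple[str, str]] = []
    groups: list[RotatableGroup] = []

    def unit(v):
        return v / np.linalg.norm(v)

    placed_pos: list[np.ndarray] = []  # grows as monomers are placed
    prev_tail_label = None
    for m in range(n_monomers):
        suffix = f"_m{m + 1}"
        drop = set()
        if m > 0:
            drop.add(_HEAD_CAP)
        if m < n_monomers - 1:
            drop.add(_TAIL_CAP)

        if m == 0:
            coords = mpos.copy()
        else:
            # attach: head carbon goes where the previous tail cap pointed
            tail_xyz = cur_tail_xyz
            bond_dir = unit(cur_tailcap_xyz - tail_xyz)
            target_head = tail_xyz + 1.54 * bond_dir
            # orient: the monomer's head->headcap direction must point back
            a = unit(mpos[midx[_HEAD_CAP]] - mpos[midx[_HEAD]])
            b = -bond_dir
            v = np.cross(a, b)
            c = float(np.dot(a, b))
            if np.linalg.norm(v) < 1e-12:
                R0 = np.eye(3) if c > 0 else rotation_matrix(_any_perp(a), 180.0)
            else:
                K = np.array(
                    [[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]]
                )
                R0 = np.eye(3) + K + K @ K * (1 / (1 + c))
            base = (mpos - mpos[midx[_HEAD]]) @ R0.T
            # roll about the new bond to maximize clearance from the chain
            best, best_score = None, -np.inf
            chain = np.vstack(placed_pos)
            for roll in range(0, 360, 30):
                Rr = rotation_matrix(b, float(roll))
                cand = base @ Rr.T + target_head
                d = np.linalg.norm(cand[:, None, :] - chain[None, :, :], axis=-1)
                score = float(np.partition(d.ravel(), 4)[:5].sum())
                if score > best_score:
                    best, best_score = cand, score
            coords = best

        keep = [lab for lab in mlabels if lab not in drop]
        for lab in keep:
            a = monomer.atoms[midx[lab]]
            atoms.append(
                AtomSpec(lab + suffix, a.element, a.type_key, tuple(coords[midx[lab]]))
            )
        placed_pos.append(coords[[midx[lab] for lab in keep]])
        for a, b2 in monomer.bonds:
            if a in drop or b2 in drop:
                continue
            bonds.append((a + suffix, b2 + suffix))
        if m > 0:
            bonds.append((prev_tail_label, _HEAD + suffix))
        for g in monomer.rotatable_groups:
            if any(lab in drop for lab in (*g.axis, *g.moved)):
                continue
            groups.append(
                RotatableGroup(
                    (g.axis[0] + suffix, g.axis[1] + suffix),
                    frozenset(lab + suffix for lab in g.moved),
                )
            )
        prev_tail_label = _TAIL + suffix
        cur_tail_xyz = coords[midx[_TAIL]]
        cur_tailcap_xyz = coords[midx[_TAIL_CAP]]

    tpl = MolecularTemplate(
        name=f"pvp_{n_monomers}mer",
        conformer_id=f"{n_monomers}mer",
        atoms=atoms,
        bonds=bonds,
        rotatable_groups=groups,
    )
    return tpl.validate()


def _any_perp(v: np.ndarray) -> np.ndarray:
    w = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(v, w)) > 0.9:
        w = np.array([0.0, 1.0, 0.0])
    return np.cross(v, w)


# ---------------------------------------------------------------------------
# reference energy
# ---------------------------------------------------------------------------


def lj_coulomb_energy(config, ff: ForceField, coulomb: str = "plain",
                      cutoff: float | None = None) -> float:
    """Total reference (Lennard-Jones + Coulomb) energy of a configuration.

    ``coulomb='plain'`` evaluates the bare 1/r sum over all minimum-image
    pairs; ``coulomb='shifted'`` applies the cutoff-shifted form used by the
    Monte Carlo engine (see :mod:`epsrkit.energy`).  Intramolecular 1-2 and
    1-3 pairs are excluded; 1-4 and beyond are included at full strength.
    """
    from .energy import total_reference_energy

    return total_reference_energy(config, ff, coulomb=coulomb, cutoff=cutoff)
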