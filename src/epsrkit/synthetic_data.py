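"""Ground-truth synthetic problems for the refinement pipeline.

Every input the pipeline consumes can be generated here without external
data: equilibrated molecular fluids under the reference potential (with an
optional planted perturbation potential), pseudo-experimental X-ray S(Q)
on the instrument-like Q range 0.6-25.0 Å^-1 with Gaussian noise, and toy
P1 crystals with a planted shortest N···O contact.  Each dataset carries
its ground truth so recovery tests score against what was actually
generated, never against published values.

All generators are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boxes import Configuration, box_edge_for_density
from .crystal_ref import CrystalSite, CrystalStructure
from .molecules import ForceField, MolecularTemplate
from .refine import (
    ConstraintSet,
    EmpiricalPotentialState,
    MCEngine,
    random_configuration,
)
from .scattering import PairFunctionSet, ScatteringPattern, compute_partial_gr, xray_total_sq

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_reference_fluid",
    "make_pseudo_experiment",
    "make_toy_crystal",
    "lj_site_template",
]


def lj_site_template(element: str = "C", type_key: str = "LJS") -> MolecularTemplate:
    """A single-site 'molecule' — the minimal fluid for engine validation."""
    from .molecules import AtomSpec

    return MolecularTemplate(
        name=f"lj_{element}",
        conformer_id="site",
        atoms=[AtomSpec("X1", element, type_key, (0.0, 0.0, 0.0))],
        bonds=[],
        rotatable_groups=[],
    )


@dataclass
class SyntheticSpec:
    """Study conditions for a synthetic fluid + pseudo-experiment."""

    components: list[tuple[MolecularTemplate, float]]
    n_molecules: int = 16
    density: float = 0.02  # atoms/Å³
    temperature_K: float = 300.0
    perturbation: dict | None = None  # (el, el) -> (r_grid, u) in kJ/mol
    noise_sigma: float = 0.005
    q_min: float = 0.6
    q_max: float = 25.0
    dq: float = 0.02
    seed: int = 0
    max_equil_sweeps: int = 400
    check_every: int = 25
    n_snapshots: int = 50
    snapshot_stride: int = 2
    constraints: ConstraintSet | None = None

    def __post_init__(self):
        fr = sum(f for _, f in self.components)
        if abs(fr - 1.0) > 1e-9:
            raise ValueError("component fractions must sum to 1")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if not (0 < self.q_min < self.q_max):
            raise ValueError("bad Q range")

    def q_grid(self) -> np.ndarray:
        return np.arange(self.q_min, self.q_max + 0.5 * self.dq, self.dq)

    def templates_expanded(self) -> list[MolecularTemplate]:
        from .molecules import ConformerMixture

        return ConformerMixture(self.components, self.n_molecules).templates_expanded()


@dataclass
class GroundTruth:
    """What a synthetic dataset was generated from — the recovery target."""

    density: float
    box_edge: float
    temperature_K: float
    seed: int
    pairset: PairFunctionSet | None = None
    S_clean: ScatteringPattern | None = None
    perturbation: dict | None = None
    conformer_fraction: float | None = None
    extras: dict = field(default_factory=dict)


def _perturbation_state(spec: SyntheticSpec, box_edge: float):
    if spec.perturbation is None:
        return None
    r_max = box_edge / 2.0
    r = np.arange(0.05, r_max + 0.05, 0.05)
    tables = {}
    for pair, (rg, u) in spec.perturbation.items():
        tables[tuple(sorted(pair))] = np.interp(r, rg, u, left=u[0], right=0.0)
    return EmpiricalPotentialState(r=r, tables=tables, amplitude_cap=1e9)


def generate_reference_fluid(
    spec: SyntheticSpec, ff: ForceField, return_engine: bool = False
):
    """Equilibrated ensemble of configurations under the reference potential.

    The box is initialized by random insertion at 60% of the target density,
    compressed to the target in a few rescale-and-relax steps, equilibrated
    until the running energy trend is statistically flat (slope within two
    standard errors of zero over the checking window), and sampled every
    ``snapshot_stride`` sweeps.  A planted perturbation potential, when
    present, acts during both equilibration and sampling.
    """
    templates = spec.templates_expanded()
    edge = box_edge_for_density([(t, 1) for t in templates], spec.density)
    start_edge = edge * (1.0 / 0.6) ** (1 / 3)
    cfg = random_configuration(
        templates, start_edge, spec.temperature_K, ff,
        constraints=spec.constraints, seed=spec.seed,
    )
    ep = _perturbation_state(spec, edge)
    engine = MCEngine(cfg, ff, ep_state=ep, constraints=spec.constraints,
                      seed=spec.seed + 1)
    engine.run(10)
    # gentle compression to the target density
    for step_edge in np.linspace(start_edge, edge, 6)[1:]:
        engine.config.coords = engine.config.rescale(step_edge).coords
        engine.config.box_edge = step_edge
        engine.run(5)
    # re-bind the energy model cutoff to the final box
    engine = MCEngine(engine.config, ff, ep_state=ep,
                      constraints=spec.constraints, seed=spec.seed + 2)
    energies = []
    for sweep in range(spec.max_equil_sweeps):
        engine.sweep()
        energies.append(engine.model.total())
        if sweep >= 2 * spec.check_every and (sweep + 1) % spec.check_every == 0:
            y = np.array(energies[-2 * spec.check_every:])
            x = np.arange(len(y), dtype=float)
            slope, intercept = np.polyfit(x, y, 1)
            resid = y - (slope * x + intercept)
            se = np.std(resid) / (np.std(x) * np.sqrt(len(y))) + 1e-30
            if abs(slope) < 2.0 * se:
                break
    ensemble = []
    for _ in range(spec.n_snapshots):
        engine.run(spec.snapshot_stride)
        ensemble.append(engine.config.copy())
    if return_engine:
        return ensemble, engine
    return ensemble


def make_pseudo_experiment(
    ensemble: list[Configuration],
    spec: SyntheticSpec,
    conformer_fraction: float | None = None,
) -> tuple[ScatteringPattern, GroundTruth]:
    """Ensemble-averaged X-ray S(Q) with additive Gaussian noise + truth record."""
    if not ensemble:
        raise ValueError("empty ensemble")
    Q = spec.q_grid()
    S_clean = xray_total_sq(ensemble, Q, temperature_K=spec.temperature_K)
    rng = np.random.default_rng(spec.seed + 1000)
    noise = rng.normal(0.0, spec.noise_sigma, len(Q)) if spec.noise_sigma > 0 else 0.0
    pattern = ScatteringPattern(
        Q=Q,
        S=S_clean.S + noise,
        sigma=np.full(len(Q), float(spec.noise_sigma)),
        temperature_K=spec.temperature_K,
    )
    cfg0 = ensemble[0]
    truth = GroundTruth(
        density=cfg0.number_density,
        box_edge=cfg0.box_edge,
        temperature_K=spec.temperature_K,
        seed=spec.seed,
        pairset=compute_partial_gr(ensemble),
        S_clean=S_clean,
        perturbation=spec.perturbation,
        conformer_fraction=conformer_fraction,
    )
    return pattern, truth


def make_toy_crystal(
    contact_distance: float = 3.0,
    cell_edge: float | None = None,
    name: str = "toy_nh_o",
) -> CrystalStructure:
    """A P1 toy crystal with a planted shortest intermolecular N···O contact.

    Two rigid fragments per cell: an N-H donor diatomic and a C=O acceptor,
    collinear along *a* so the N-H···O geometry is exactly linear with
    d(N···O) equal to ``contact_distance``.  Everything else in the packing
    sits farther away, so contact searches must recover the planted value.
    """
    d = float(contact_distance)
    if d <= 1.2:
        raise ValueError("contact distance too short for a sane motif")
    a = cell_edge if cell_edge is not None else max(8.0, 2.0 * d + 3.0)
    # cartesian motif along x
    atoms = [
        ("N1", "N", 0.0),
        ("H1", "H", 1.01),
        ("O1", "O", d),
        ("C1", "C", d + 1.22),
    ]
    sites = [
        CrystalSite(lab, el, (x / a + 0.1, 0.25, 0.25), 1.0)
        for lab, el, x in atoms
    ]
    return CrystalStructure(
        cell=(a, a, a, 90.0, 90.0, 90.0),
        operators=["x,y,z"],
        sites=sites,
        Z=1,
        name=name,
    )
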