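"""Periodic simulation boxes of molecule instances.

A :class:`Configuration` is the state evolved by the Monte Carlo engine: a
cubic box with a list of molecule instances (template reference + Cartesian
coordinates).  Molecules are stored whole (unwrapped); minimum-image
conventions are applied when distances are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .molecules import MolecularTemplate

__all__ = ["Configuration", "box_edge_for_density"]


def box_edge_for_density(templates_counts, rho_atoms_per_A3: float) -> float:
    """Cubic box edge (Å) holding the given molecules at an atom number density.

    ``templates_counts`` is an iterable of (template, count) pairs;
    ``rho_atoms_per_A3`` is the total atom number density in atoms/Å³.
    """
    if rho_atoms_per_A3 <= 0:
        raise ValueError("density must be positive")
    n_atoms = sum(t.n_atoms * c for t, c in templates_counts)
    return (n_atoms / rho_atoms_per_A3) ** (1.0 / 3.0)


@dataclass
class Configuration:
    """A periodic cubic box of molecule instances."""

    box_edge: float
    templates: list[MolecularTemplate]
    coords: list[np.ndarray]  # per-molecule (n_i, 3) arrays, unwrapped
    temperature_K: float = 300.0
    rng_seed: int | None = None

    def __post_init__(self):
        if len(self.templates) != len(self.coords):
            raise ValueError("templates and coords length mismatch")
        self.coords = [np.array(c, dtype=float) for c in self.coords]
        for t, c in zip(self.templates, self.coords):
            if c.shape != (t.n_atoms, 3):
                raise ValueError(
                    f"coordinate block {c.shape} does not match template "
                    f"{t.name} ({t.n_atoms} atoms)"
                )

    @property
    def n_molecules(self) -> int:
        return len(self.templates)

    @property
    def n_atoms(self) -> int:
        return sum(t.n_atoms for t in self.templates)

    @property
    def volume(self) -> float:
        return self.box_edge**3

    @property
    def number_density(self) -> float:
        """Atom number density in atoms/Å³."""
        return self.n_atoms / self.volume

    def flat_positions(self) -> np.ndarray:
        return np.concatenate(self.coords, axis=0)

    def mol_slices(self) -> list[slice]:
        out, start = [], 0
        for t in self.templates:
            out.append(slice(start, start + t.n_atoms))
            start += t.n_atoms
        return out

    def elements(self) -> list[str]:
        out: list[str] = []
        for t in self.templates:
            out.extend(t.elements)
        return out

    def copy(self) -> "Configuration":
        return Configuration(
            box_edge=self.box_edge,
            templates=list(self.templates),
            coords=[c.copy() for c in self.coords],
            temperature_K=self.temperature_K,
            rng_seed=self.rng_seed,
        )

    def rescale(self, new_edge: float) -> "Configuration":
        """Return a copy with molecular centroids affinely rescaled to a new box.

        Intramolecular geometry is preserved; only centre-of-geometry
        positions scale with the box edge.
        """
        s = new_edge / self.box_edge
        new_coords = []
        for c in self.coords:
            cen = c.mean(axis=0)
            new_coords.append(c + (s - 1.0) * cen)
        out = self.copy()
        out.box_edge = new_edge
        out.coords = new_coords
        return out

    def wrapped_positions(self) -> np.ndarray:
        """Atom positions folded into [0, L)^3 (for output only)."""
        return np.mod(self.flat_positions(), self.box_edge)


def minimum_image(d: np.ndarray, box_edge: float) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    return d - box_edge * np.round(d / box_edge)


def write_extxyz(configs, path, comment_extra: str = "") -> None:
    """Write one or more configurations as an extended-XYZ trajectory."""
    if isinstance(configs, Configuration):
        configs = [configs]
    with open(path, "w") as fh:
        for cfg in configs:
            L = cfg.box_edge
            fh.write(f"{cfg.n_atoms}\n")
            props = (
                f'Lattice="{L} 0 0 0 {L} 0 0 0 {L}" '
                f"Properties=species:S:1:pos:R:3:mol:I:1 "
                f"Temperature={cfg.temperature_K}"
            )
            if comment_extra:
                props += " " + comment_extra
            fh.write(props + "\n")
            for imol, (t, xyz) in enumerate(zip(cfg.templates, cfg.coords)):
                for el, p in zip(t.elements, xyz):
                    fh.write(
                        f"{el} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {imol}\n"
                    )
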