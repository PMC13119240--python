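"""Vectorized reference-potential and empirical-potential energy kernels.

The reference potential is pairwise Lennard-Jones + Coulomb with
Lorentz-Berthelot combining.  Intramolecular 1-2 and 1-3 pairs are excluded;
1-4 and beyond count at full strength.  The Monte Carlo engine uses the
cutoff-shifted Coulomb form (neutral molecules make the result box-size
independent); ``coulomb='plain'`` evaluates the bare sum.

The empirical potential is a per-element-pair tabulated correction applied
to intermolecular pairs only, looked up by linear interpolation.
"""

from __future__ import annotations

import numpy as np

from .boxes import Configuration, minimum_image
from .constants import COULOMB_KJ_A
from .molecules import ForceField

__all__ = ["ParameterTables", "EnergyModel", "total_reference_energy"]

DEFAULT_CUTOFF = 12.0  # Å


class ParameterTables:
    """Per-atom force-field arrays for one configuration's composition."""

    def __init__(self, config: Configuration, ff: ForceField):
        sig, eps, q, elem, mol = [], [], [], [], []
        self.intra_masks = []  # per molecule: included intramolecular pair mask
        for i, t in enumerate(config.templates):
            s, e = ff.lj_params(t)
            sig.append(s)
            eps.append(e)
            q.append(ff.charges(t))
            elem.extend(t.elements)
            mol.extend([i] * t.n_atoms)
            self.intra_masks.append(t.intra_nonbonded_mask())
        self.sigma = np.concatenate(sig)
        self.epsilon = np.concatenate(eps)
        self.q = np.concatenate(q)
        self.elements = elem
        self.mol_id = np.asarray(mol)
        self.slices = config.mol_slices()


def _pair_terms(r, sig_ab, eps_ab, qq, coulomb, cutoff):
    if np.any(r < 1e-10):
        raise ValueError("zero interatomic distance in energy evaluation")
    u = np.zeros_like(r)
    live = eps_ab > 0
    if cutoff is not None:
        live = live & (r < cutoff)
    if np.any(live):
        x = (sig_ab[live] / r[live]) ** 6
        u[live] = 4.0 * eps_ab[live] * (x * x - x)
    if coulomb == "plain":
        u += COULOMB_KJ_A * qq / r
    elif coulomb == "shifted":
        rc = cutoff if cutoff is not None else DEFAULT_CUTOFF
        inside = r < rc
        u[inside] += COULOMB_KJ_A * qq[inside] * (1.0 / r[inside] - 1.0 / rc)
    else:
        raise ValueError(f"unknown coulomb scheme {coulomb!r}")
    return u


class EnergyModel:
    """Energy evaluator bound to one configuration's composition.

    Geometry may change between calls; composition (templates, order) must
    not.  ``ep_tables`` is an optional mapping ``(el_a, el_b) -> (r_grid, u)``
    of empirical-potential corrections (sorted element pairs), applied to
    intermolecular pairs.
    """

    def __init__(
        self,
        config: Configuration,
        ff: ForceField,
        coulomb: str = "shifted",
        cutoff: float | None = DEFAULT_CUTOFF,
        ep_tables: dict | None = None,
    ):
        self.config = config
        self.tables = ParameterTables(config, ff)
        self.coulomb = coulomb
        self.cutoff = cutoff
        self.ep_tables = ep_tables or {}
        # integer element codes for fast EP grouping
        uniq = sorted(set(self.tables.elements))
        self._ecode = {e: i for i, e in enumerate(uniq)}
        self._elems = uniq
        self._codes = np.array([self._ecode[e] for e in self.tables.elements])

    # -- reference energy --------------------------------------------------

    def total(self) -> float:
        """Total reference energy over all minimum-image pairs."""
        cfg, t = self.config, self.tables
        pos = cfg.flat_positions()
        L = cfg.box_edge
        n = len(pos)
        e = 0.0
        block = 512
        for i0 in range(0, n, block):
            i1 = min(i0 + block, n)
            d = minimum_image(pos[i0:i1, None, :] - pos[None, :, :], L)
            r = np.linalg.norm(d, axis=-1)
            idx = np.arange(i0, i1)
            mask = t.mol_id[None, :] != t.mol_id[idx, None]
            # intramolecular included pairs
            for m, sl in enumerate(t.slices):
                rows = (idx >= sl.start) & (idx < sl.stop)
                if rows.any():
                    sub = t.intra_masks[m][idx[rows] - sl.start]
                    mask[np.ix_(rows, range(sl.start, sl.stop))] = sub
            # upper triangle only
            mask &= np.arange(n)[None, :] > idx[:, None]
            ii, jj = np.nonzero(mask)
            rr = r[ii, jj]
            gi = idx[ii]
            sig_ab = 0.5 * (t.sigma[gi] + t.sigma[jj])
            eps_ab = np.sqrt(t.epsilon[gi] * t.epsilon[jj])
            qq = t.q[gi] * t.q[jj]
            e += _pair_terms(rr, sig_ab, eps_ab, qq, self.coulomb, self.cutoff).sum()
            # EP (intermolecular only)
            if self.ep_tables:
                inter = t.mol_id[gi] != t.mol_id[jj]
                e += self._ep_sum(rr[inter], gi[inter], jj[inter])
        return float(e)

    def molecule_env(self, imol: int, pos_i: np.ndarray | None = None) -> float:
        """Energy of molecule *imol* with its environment plus its own
        included intramolecular pairs.  ``pos_i`` overrides its coordinates."""
        cfg, t = self.config, self.tables
        L = cfg.box_edge
        sl = t.slices[imol]
        pi = cfg.coords[imol] if pos_i is None else pos_i
        pos = cfg.flat_positions()
        other = np.ones(len(pos), dtype=bool)
        other[sl] = False
        pj = pos[other]
        d = minimum_image(pi[:, None, :] - pj[None, :, :], L)
        r = np.linalg.norm(d, axis=-1)
        oi = np.nonzero(other)[0]
        ni = sl.stop - sl.start
        gi = np.repeat(np.arange(sl.start, sl.stop), len(oi))
        gj = np.tile(oi, ni)
        rr = r.ravel()
        sig_ab = 0.5 * (t.sigma[gi] + t.sigma[gj])
        eps_ab = np.sqrt(t.epsilon[gi] * t.epsilon[gj])
        qq = t.q[gi] * t.q[gj]
        e = _pair_terms(rr, sig_ab, eps_ab, qq, self.coulomb, self.cutoff).sum()
        if self.ep_tables:
            e += self._ep_sum(rr, gi, gj)
        # intramolecular included pairs of this molecule (no minimum image:
        # molecules are stored whole)
        m = t.intra_masks[imol]
        iu, ju = np.nonzero(np.triu(m))
        if len(iu):
            rin = np.linalg.norm(pi[iu] - pi[ju], axis=-1)
            sig_ab = 0.5 * (t.sigma[sl.start + iu] + t.sigma[sl.start + ju])
            eps_ab = np.sqrt(t.epsilon[sl.start + iu] * t.epsilon[sl.start + ju])
            qq = t.q[sl.start + iu] * t.q[sl.start + ju]
            e += _pair_terms(rin, sig_ab, eps_ab, qq, self.coulomb, self.cutoff).sum()
        return float(e)

    def delta_move(self, imol: int, new_pos: np.ndarray) -> float:
        """Energy change for replacing molecule *imol*'s coordinates."""
        return self.molecule_env(imol, new_pos) - self.molecule_env(imol)

    # -- empirical potential ----------------------------------------------

    def _ep_sum(self, r, gi, gj) -> float:
        if not len(r):
            return 0.0
        ci, cj = self._codes[gi], self._codes[gj]
        lo = np.minimum(ci, cj)
        hi = np.maximum(ci, cj)
        pid = lo * len(self._elems) + hi
        e = 0.0
        for (ea, eb), (rg, u) in self.ep_tables.items():
            a, b = sorted((ea, eb))
            if a not in self._ecode or b not in self._ecode:
                continue
            key = self._ecode[a] * len(self._elems) + self._ecode[b]
            sel = pid == key
            if sel.any():
                e += np.interp(r[sel], rg, u, left=u[0], right=0.0).sum()
        return float(e)


def total_reference_energy(
    config: Configuration,
    ff: ForceField,
    coulomb: str = "plain",
    cutoff: float | None = None,
) -> float:
    """One-shot total reference energy (see :func:`epsrkit.molecules.lj_coulomb_energy`)."""
    return EnergyModel(config, ff, coulomb=coulomb, cutoff=cutoff).total()
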