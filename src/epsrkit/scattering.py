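"""Pair distribution functions, X-ray-weighted structure factors and transforms.

Conventions
-----------
Faber-Ziman partials: ``S_ab(Q) - 1 = 4 pi rho int r^2 [g_ab(r) - 1]
sinc(Qr) dr``; the X-ray total is the concentration- and form-factor-
weighted sum ``S_X(Q) = sum_ab c_a c_b f_a f_b [S_ab - 1] / <f>^2 + 1``
with ``<f> = sum_a c_a f_a(Q)``.  The differential pair distribution
function is ``D(r) = (2/pi) int Q [S(Q) - 1] sin(Qr) dQ = 4 pi rho r
[g(r) - 1]``.

When a structure factor is computed directly from a configuration, the
intramolecular contribution is evaluated exactly (a Debye sum over
intramolecular distances) and the intermolecular contribution from
minimum-image histograms, matching how semi-rigid refinement treats the
two parts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boxes import Configuration, minimum_image
from .constants import ATOMIC_NUMBER, xray_form_factor

__all__ = [
    "ScatteringPattern",
    "PairFunctionSet",
    "DifferentialPDF",
    "compute_partial_gr",
    "xray_total_sq",
    "sq_to_dr",
    "intramolecular_pair_pdf",
    "fsdp_metrics",
    "PeakNotFoundError",
    "default_q_grid",
    "read_sq",
    "write_sq",
]

Q_MIN_DEFAULT = 0.6  # Å^-1, instrument range
Q_MAX_DEFAULT = 25.0
DQ_DEFAULT = 0.02
DR_DEFAULT = 0.02


def default_q_grid(q_min: float = Q_MIN_DEFAULT, q_max: float = Q_MAX_DEFAULT,
                   dq: float = DQ_DEFAULT) -> np.ndarray:
    return np.arange(q_min, q_max + 0.5 * dq, dq)


@dataclass
class ScatteringPattern:
    """A total structure factor S(Q) on an ascending Q grid (Å^-1)."""

    Q: np.ndarray
    S: np.ndarray
    sigma: np.ndarray | None = None
    temperature_K: float | None = None
    scale: float = 1.0

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if self.Q.ndim != 1 or self.Q.shape != self.S.shape:
            raise ValueError("Q and S must be matching 1-D arrays")
        if len(self.Q) and self.Q[0] <= 0:
            raise ValueError("Q grid must be strictly positive")
        if np.any(np.diff(self.Q) <= 0):
            raise ValueError("Q grid must be strictly ascending")
        if not (np.all(np.isfinite(self.Q)) and np.all(np.isfinite(self.S))):
            raise ValueError("non-finite values in pattern")

    def high_q_level(self, top_fraction: float = 0.1) -> float:
        """Mean of S over the top *top_fraction* of the Q range."""
        n = max(1, int(len(self.Q) * top_fraction))
        return float(self.S[-n:].mean())

    def is_normalized(self, tol: float = 0.05) -> bool:
        return abs(self.high_q_level() - 1.0) <= tol

    def interp_to(self, Q: np.ndarray) -> "ScatteringPattern":
        return ScatteringPattern(Q, np.interp(Q, self.Q, self.S),
                                 temperature_K=self.temperature_K, scale=self.scale)


@dataclass
class PairFunctionSet:
    """Partial pair distribution functions g_ab(r) with composition metadata.

    ``g`` maps sorted site-pair tuples to curves on ``r``; ``c`` maps sites
    to concentrations (fractions of all atoms); ``element_of`` maps sites to
    chemical elements (for X-ray weighting); ``counts`` keeps the raw
    unordered pair histograms for oracle cross-checks.
    """

    r: np.ndarray
    g: dict[tuple[str, str], np.ndarray]
    rho: float
    c: dict[str, float]
    element_of: dict[str, str]
    counts: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    n_configs: int = 1

    def pair(self, a: str, b: str) -> np.ndarray:
        return self.g[tuple(sorted((a, b)))]


@dataclass
class DifferentialPDF:
    """D(r) = 4 pi rho r [g(r) - 1] in Å^-2."""

    r: np.ndarray
    D: np.ndarray
    rho: float

    def total_g(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            g = 1.0 + self.D / (4.0 * np.pi * self.rho * self.r)
        if len(g):
            g[0] = 0.0 if self.r[0] == 0 else g[0]
        return g


# ---------------------------------------------------------------------------
# partial g(r)
# ---------------------------------------------------------------------------


def _site_arrays(config: Configuration, site_of):
    sites, elems = [], []
    for t in config.templates:
        for a in t.atoms:
            s = site_of(t, a)
            sites.append(s)
            elems.append(a.element)
    return sites, elems


def compute_partial_gr(
    configs: Configuration | list[Configuration],
    r_max: float | None = None,
    dr: float = DR_DEFAULT,
    site_of=None,
    include_intra: bool = False,
) -> PairFunctionSet:
    """Histogram estimator of partial pair distribution functions.

    Parameters
    ----------
    configs : Configuration or list of Configuration
        A single snapshot or an ensemble (averaged) with identical
        composition and box.
    site_of : callable(template, AtomSpec) -> str or None, optional
        Maps each atom to a site name (``None`` excludes the atom).  The
        default groups atoms by chemical element.
    include_intra : bool
        Include intramolecular pairs in the histograms (default:
        intermolecular only).
    """
    if isinstance(configs, Configuration):
        configs = [configs]
    if not configs:
        raise ValueError("empty ensemble")
    cfg0 = configs[0]
    if cfg0.n_atoms == 0:
        raise ValueError("empty configuration")
    L = cfg0.box_edge
    if r_max is None:
        r_max = L / 2.0
    if r_max > L / 2.0 + 1e-9:
        raise ValueError(f"r_max {r_max} exceeds half the box edge {L / 2}")
    if dr <= 0:
        raise ValueError("dr must be positive")
    if site_of is None:
        site_of = lambda t, a: a.element  # noqa: E731

    sites, elems = _site_arrays(cfg0, site_of)
    names = sorted({s for s in sites if s is not None})
    element_of: dict[str, str] = {}
    for s, e in zip(sites, elems):
        if s is None:
            continue
        if element_of.setdefault(s, e) != e:
            raise ValueError(f"site {s!r} maps atoms of different elements")
    code = {s: i for i, s in enumerate(names)}
    scode = np.array([code[s] if s is not None else -1 for s in sites])
    n_total = cfg0.n_atoms
    n_site = {s: int((scode == code[s]).sum()) for s in names}

    edges = np.arange(0.0, r_max + dr, dr)
    nb = len(edges) - 1
    r = 0.5 * (edges[:-1] + edges[1:])
    nk = len(names)
    counts = np.zeros((nk, nk, nb))

    for cfg in configs:
        pos = cfg.flat_positions()
        mol_id = np.repeat(np.arange(cfg.n_molecules),
                           [t.n_atoms for t in cfg.templates])
        sel = scode >= 0
        p = pos[sel]
        sc = scode[sel]
        mid = mol_id[sel]
        n = len(p)
        block = 512
        for i0 in range(0, n, block):
            i1 = min(i0 + block, n)
            d = minimum_image(p[i0:i1, None, :] - p[None, :, :], L)
            rr = np.linalg.norm(d, axis=-1)
            take = np.arange(n)[None, :] > np.arange(i0, i1)[:, None]
            if not include_intra:
                take &= mid[None, :] != mid[i0:i1, None]
            take &= rr < r_max
            ii, jj = np.nonzero(take)
            if not len(ii):
                continue
            a = np.minimum(sc[i0 + ii], sc[jj])
            b = np.maximum(sc[i0 + ii], sc[jj])
            bins = np.minimum((rr[ii, jj] / dr).astype(int), nb - 1)
            np.add.at(counts, (a, b, bins), 1.0)

    rho = cfg0.number_density
    shell = 4.0 * np.pi * r**2 * dr
    g: dict[tuple[str, str], np.ndarray] = {}
    raw: dict[tuple[str, str], np.ndarray] = {}
    for ia, a in enumerate(names):
        for ib in range(ia, nk):
            b = names[ib]
            h = counts[ia, ib] / len(configs)
            raw[(a, b)] = h
            ordered = h * (2.0 if a == b else 1.0)
            denom = n_site[a] * shell * rho * (n_site[b] / n_total)
            g[(a, b)] = ordered / denom
    return PairFunctionSet(
        r=r, g=g, rho=rho,
        c={s: n_site[s] / n_total for s in names},
        element_of=element_of, counts=raw, n_configs=len(configs),
    )


# ---------------------------------------------------------------------------
# structure factors
# ---------------------------------------------------------------------------


def _fz_weights(pairset: PairFunctionSet, Q: np.ndarray):
    names = sorted(pairset.c)
    f = {s: xray_form_factor(pairset.element_of[s], Q) for s in names}
    mean_f = sum(pairset.c[s] * f[s] for s in names)
    return names, f, mean_f


def _sinc_transform(r, y, Q):
    """4 pi rho-free kernel: int r^2 y(r) sin(Qr)/(Qr) dr by trapezoid."""
    Qr = np.outer(Q, r)
    with np.errstate(invalid="ignore"):
        k = np.where(Qr == 0, 1.0, np.sin(Qr) / Qr)
    return np.trapezoid(r**2 * y * k, r, axis=-1)


def xray_total_sq(
    source,
    Q: np.ndarray | None = None,
    dr: float = DR_DEFAULT,
    include_intermolecular: bool = True,
    temperature_K: float | None = None,
) -> ScatteringPattern:
    """X-ray-weighted total structure factor.

    ``source`` may be a :class:`PairFunctionSet` (pure Faber-Ziman
    construction from the stored partials) or a
    :class:`Configuration`/ensemble (exact intramolecular Debye sum plus
    Fourier-transformed intermolecular histograms).
    """
    if Q is None:
        Q = default_q_grid()
    Q = np.asarray(Q, dtype=float)
    if np.any(Q <= 0):
        raise ValueError("Q grid must be strictly positive")

    if isinstance(source, PairFunctionSet):
        ps = source
        names, f, mean_f = _fz_weights(ps, Q)
        S = np.ones_like(Q)
        for i, a in enumerate(names):
            for b in names[i:]:
                h = ps.pair(a, b) - 1.0
                t = 4.0 * np.pi * ps.rho * _sinc_transform(ps.r, h, Q)
                w = (2.0 - (a == b)) * ps.c[a] * ps.c[b] * f[a] * f[b] / mean_f**2
                S += w * t
        return ScatteringPattern(Q, S, temperature_K=temperature_K)

    configs = [source] if isinstance(source, Configuration) else list(source)
    if not configs:
        raise ValueError("empty ensemble")
    cfg0 = configs[0]
    elems = cfg0.elements()
    c = {e: elems.count(e) / len(elems) for e in sorted(set(elems))}
    f = {e: xray_form_factor(e, Q) for e in c}
    mean_f = sum(c[e] * f[e] for e in c)
    n_atoms = cfg0.n_atoms

    # intramolecular (Debye) part, averaged over the ensemble: distances are
    # accumulated into fine per-element-pair histograms (linear-split
    # binning, second-order accurate) so the sine transform runs once per
    # ensemble instead of once per pair per snapshot
    dr_intra = 0.002
    r_intra_max = 0.0
    pair_codes_cache = {}
    for t, xyz in zip(cfg0.templates, cfg0.coords):
        if t.n_atoms > 1:
            dm = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
            r_intra_max = max(r_intra_max, float(dm.max()))
    nbins = int(np.ceil((r_intra_max * 1.3 + 1.0) / dr_intra)) + 2
    elems_sorted = sorted(c)
    ecode = {e: i for i, e in enumerate(elems_sorted)}
    ne = len(elems_sorted)
    hist = np.zeros((ne * ne, nbins))

    def _pair_arrays(t):
        key = id(t)
        if key not in pair_codes_cache:
            iu, ju = np.triu_indices(t.n_atoms, k=1)
            codes = np.array(
                [ecode[t.elements[i]] * ne + ecode[t.elements[j]]
                 if ecode[t.elements[i]] <= ecode[t.elements[j]]
                 else ecode[t.elements[j]] * ne + ecode[t.elements[i]]
                 for i, j in zip(iu, ju)]
            )
            pair_codes_cache[key] = (iu, ju, codes)
        return pair_codes_cache[key]

    for cfg in configs:
        for t, xyz in zip(cfg.templates, cfg.coords):
            if t.n_atoms < 2:
                continue
            iu, ju, codes = _pair_arrays(t)
            d = np.linalg.norm(xyz[iu] - xyz[ju], axis=-1)
            x = d / dr_intra
            lo = np.floor(x).astype(int)
            frac = x - lo
            np.add.at(hist, (codes, np.minimum(lo, nbins - 1)), 1.0 - frac)
            np.add.at(hist, (codes, np.minimum(lo + 1, nbins - 1)), frac)
    hist /= len(configs)
    r_bins = np.arange(nbins) * dr_intra
    S_intra = np.zeros_like(Q)
    for i, a in enumerate(elems_sorted):
        for j in range(i, ne):
            b = elems_sorted[j]
            h = hist[i * ne + j]
            nz = np.nonzero(h)[0]
            if not len(nz):
                continue
            Qr = np.outer(Q, r_bins[nz])
            k = np.where(Qr == 0, 1.0, np.sin(Qr) / np.maximum(Qr, 1e-300))
            S_intra += 2.0 * f[a] * f[b] * (k * h[nz][None, :]).sum(axis=1)
    S_intra /= n_atoms * mean_f**2

    S = 1.0 + S_intra
    if include_intermolecular and cfg0.n_molecules > 1:
        ps = compute_partial_gr(configs, dr=dr, include_intra=False)
        inter = xray_total_sq(ps, Q)
        S = S + (inter.S - 1.0)
    return ScatteringPattern(Q, S, temperature_K=temperature_K)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def sq_to_dr(
    pattern: ScatteringPattern,
    rho: float,
    r_grid: np.ndarray | None = None,
    window: str = "none",
    require_normalized: bool = True,
) -> DifferentialPDF:
    """Sine-transform S(Q) to the differential PDF D(r).

    ``window='lorch'`` applies the Lorch modification function
    ``sin(pi Q / Q_max) / (pi Q / Q_max)`` to suppress termination ripples.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    if require_normalized and not pattern.is_normalized():
        raise ValueError(
            f"pattern is not normalized (high-Q level {pattern.high_q_level():.3f})"
        )
    if r_grid is None:
        r_grid = np.arange(0.0, 20.0 + DR_DEFAULT, DR_DEFAULT)
    Q, S = pattern.Q, pattern.S
    y = Q * (S - 1.0)
    if window.lower() == "lorch":
        x = np.pi * Q / Q[-1]
        y = y * np.where(x == 0, 1.0, np.sin(x) / np.maximum(x, 1e-300))
    elif window.lower() != "none":
        raise ValueError(f"unknown window {window!r}")
    Qr = np.outer(r_grid, Q)
    D = (2.0 / np.pi) * np.trapezoid(y * np.sin(Qr), Q, axis=-1)
    D[r_grid == 0] = 0.0
    return DifferentialPDF(r=r_grid, D=D, rho=rho)


# ---------------------------------------------------------------------------
# intramolecular stick spectra
# ---------------------------------------------------------------------------


def intramolecular_pair_pdf(
    template,
    pair_selector,
    broadening_sigma: float = 0.1,
    r_grid: np.ndarray | None = None,
):
    """X-ray-weighted, Gaussian-broadened intramolecular distance spectrum.

    ``pair_selector`` is either a pair of element symbols / label prefixes
    (e.g. ``("Cl", "Cl")``) or a callable taking two ``AtomSpec`` and
    returning True for pairs to include.  Weights are the Q -> 0 X-ray
    weights (atomic-number products).  Returns ``(r, y, sticks)`` where
    sticks is the list of (distance, weight).
    """
    if broadening_sigma <= 0:
        raise ValueError("broadening_sigma must be positive")
    if callable(pair_selector):
        match = pair_selector
    else:
        sa, sb = pair_selector

        def match(x, y_):
            def hit(atom, s):
                return atom.element == s or atom.label.startswith(s)

            return (hit(x, sa) and hit(y_, sb)) or (hit(x, sb) and hit(y_, sa))

    pos = template.positions()
    sticks = []
    for i in range(template.n_atoms):
        for j in range(i + 1, template.n_atoms):
            ai, aj = template.atoms[i], template.atoms[j]
            if match(ai, aj):
                d = float(np.linalg.norm(pos[i] - pos[j]))
                w = ATOMIC_NUMBER[ai.element] * ATOMIC_NUMBER[aj.element]
                sticks.append((d, float(w)))
    if not sticks:
        raise ValueError("pair selector matched no intramolecular pairs")
    if r_grid is None:
        dmax = max(d for d, _ in sticks)
        r_grid = np.arange(0.0, dmax + 5 * broadening_sigma + 1.0, 0.005)
    y = np.zeros_like(r_grid)
    for d, w in sticks:
        y += w * np.exp(-0.5 * ((r_grid - d) / broadening_sigma) ** 2)
    y /= broadening_sigma * np.sqrt(2.0 * np.pi)
    return r_grid, y, sticks


def peak_position(x: np.ndarray, y: np.ndarray) -> float:
    """Position of the global maximum, refined by 3-point parabola."""
    i = int(np.argmax(y))
    if 0 < i < len(x) - 1:
        denom = y[i - 1] - 2 * y[i] + y[i + 1]
        if denom != 0:
            return float(x[i] + 0.5 * (y[i - 1] - y[i + 1]) / denom * (x[i + 1] - x[i]))
    return float(x[i])


# ---------------------------------------------------------------------------
# first sharp diffraction peak
# ---------------------------------------------------------------------------


class PeakNotFoundError(ValueError):
    pass


def fsdp_metrics(
    pattern: ScatteringPattern,
    window: tuple[float, float] = (0.6, 2.0),
    prominence: float = 0.02,
) -> tuple[float, float, float]:
    """Position (Å^-1), height (S - 1) and FWHM of the first sharp
    diffraction peak: the lowest-Q local maximum of S(Q) in *window* with
    at least *prominence* (which rejects noise wiggles), refined by
    three-point parabolic interpolation."""
    from scipy.signal import find_peaks

    Q, S = pattern.Q, pattern.S
    lo, hi = window
    sel = np.nonzero((Q >= lo) & (Q <= hi))[0]
    if len(sel) < 3:
        raise PeakNotFoundError("pattern does not cover the FSDP window")
    peaks, _ = find_peaks(S, prominence=prominence)
    # truncation ripples can produce prominent minima-side maxima below the
    # S = 1 baseline; a diffraction peak must rise above it
    peaks = [i for i in peaks
             if lo <= Q[i] <= hi and 0 < i < len(Q) - 1 and S[i] > 1.0]
    if not peaks:
        raise PeakNotFoundError("no local maximum of S(Q) in the FSDP window")
    peak_i = peaks[0]  # FSDP is by definition the first (lowest-Q) maximum
    i = peak_i
    denom = S[i - 1] - 2 * S[i] + S[i + 1]
    if denom != 0:
        dx = 0.5 * (S[i - 1] - S[i + 1]) / denom
        pos = Q[i] + dx * (Q[i + 1] - Q[i])
        height = S[i] - 0.25 * (S[i - 1] - S[i + 1]) * dx - 1.0
    else:
        pos, height = Q[i], S[i] - 1.0
    # FWHM of S-1 around the peak via linear interpolation
    half = height / 2.0
    y = S - 1.0
    left = right = np.nan
    for j in range(i, 0, -1):
        if y[j - 1] <= half <= y[j]:
            left = np.interp(half, [y[j - 1], y[j]], [Q[j - 1], Q[j]])
            break
    for j in range(i, len(Q) - 1):
        if y[j + 1] <= half <= y[j]:
            right = np.interp(half, [y[j + 1], y[j]], [Q[j + 1], Q[j]])
            break
    width = float(right - left) if np.isfinite(left) and np.isfinite(right) else float("nan")
    return float(pos), float(height), width


# ---------------------------------------------------------------------------
# ASCII I/O
# ---------------------------------------------------------------------------


def read_sq(path) -> ScatteringPattern:
    """Read a two- or three-column ASCII S(Q) file (# comments allowed)."""
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("expected two or three columns: Q, S(Q)[, sigma]")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return ScatteringPattern(data[:, 0], data[:, 1], sigma=sigma)


def write_sq(pattern: ScatteringPattern, path, header: str = "") -> None:
    cols = [pattern.Q, pattern.S]
    if pattern.sigma is not None:
        cols.append(pattern.sigma)
    head = "Q(1/A)  S(Q)" + ("  sigma" if pattern.sigma is not None else "")
    if header:
        head = header + "\n" + head
    np.savetxt(path, np.column_stack(cols), header=head)
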