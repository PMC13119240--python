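"""Pair distributions, structure factors, transforms and FSDP metrics."""

import gemmi
import numpy as np
import pytest

from epsrkit.boxes import Configuration, minimum_image
from epsrkit.constants import CROMER_MANN, xray_form_factor
from epsrkit.scattering import (
    DifferentialPDF,
    PairFunctionSet,
    PeakNotFoundError,
    ScatteringPattern,
    compute_partial_gr,
    default_q_grid,
    fsdp_metrics,
    intramolecular_pair_pdf,
    peak_position,
    read_sq,
    sq_to_dr,
    write_sq,
    xray_total_sq,
)

from conftest import make_point_config, toy_chain_template


# ---------------------------------------------------------------------------
# form factors
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("element", sorted(CROMER_MANN))
def test_form_factors_match_gemmi(element):
    """Embedded Cromer-Mann table agrees with gemmi's IT92 coefficients."""
    Q = np.linspace(0.1, 25.0, 60)
    ours = xray_form_factor(element, Q)
    ref = np.array(
        [gemmi.Element(element).it92.calculate_sf((q / (4 * np.pi)) ** 2) for q in Q]
    )
    assert np.abs(ours - ref).max() < 1e-4


# ---------------------------------------------------------------------------
# partial g(r)
# ---------------------------------------------------------------------------


def test_ideal_gas_gr_is_unity():
    """Uniform random points: g(r) = 1 within 3 Poisson sigma per bin."""
    rng = np.random.default_rng(0)
    L, n = 20.0, 1000
    cfg = make_point_config(rng.uniform(0, L, (n, 3)), L)
    ps = compute_partial_gr(cfg, dr=0.25)
    rho_pair = cfg.number_density
    for r, g in zip(ps.r, ps.g[("C", "C")]):
        if r < 1.0:
            continue
        shell = 4 * np.pi * r**2 * 0.25
        mean_count = n * rho_pair * shell  # ordered pairs per bin
        sigma_rel = 1.0 / np.sqrt(mean_count * n / 2 / n)  # Poisson on pair count
        assert abs(g - 1.0) < 3.5 * np.sqrt(2.0 / (n * rho_pair * shell)), r


def test_single_pair_lands_in_its_bin():
    cfg = make_point_config([[0, 0, 0], [3.0, 0, 0]], 12.0)
    ps = compute_partial_gr(cfg, dr=0.1)
    counts = ps.counts[("C", "C")]
    hit = np.nonzero(counts)[0]
    assert len(hit) == 1
    assert ps.r[hit[0]] == pytest.approx(3.05, abs=0.051)


def test_histogram_matches_brute_force_oracle():
    """Histogram estimator equals an O(N^2) minimum-image double loop,
    bin by bin, as integer counts."""
    rng = np.random.default_rng(1)
    L, dr = 14.0, 0.2
    tpl = toy_chain_template("trans")
    coords = [tpl.positions() + rng.uniform(0, L, 3) for _ in range(50)]
    cfg = Configuration(L, [tpl] * 50, coords)
    ps = compute_partial_gr(cfg, dr=dr)
    # oracle: explicit double loop over atoms, intermolecular only
    pos = cfg.flat_positions()
    mol = np.repeat(np.arange(50), 4)
    nb = len(ps.r)
    oracle = np.zeros(nb)
    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            if mol[i] == mol[j]:
                continue
            d = pos[i] - pos[j]
            d -= L * np.round(d / L)
            r = np.linalg.norm(d)
            if r < L / 2:
                oracle[min(int(r / dr), nb - 1)] += 1
    assert np.array_equal(ps.counts[("C", "C")], oracle)


def test_r_max_beyond_half_box_rejected():
    cfg = make_point_config([[0, 0, 0], [3, 0, 0]], 10.0)
    with pytest.raises(ValueError, match="half the box"):
        compute_partial_gr(cfg, r_max=6.0)


# ---------------------------------------------------------------------------
# structure factors
# ---------------------------------------------------------------------------


def test_flat_partials_give_flat_sq():
    r = np.arange(0.01, 12, 0.02)
    ps = PairFunctionSet(
        r=r, g={("C", "C"): np.ones_like(r)}, rho=0.05,
        c={"C": 1.0}, element_of={"C": "C"},
    )
    S = xray_total_sq(ps, default_q_grid(dq=0.1))
    assert np.allclose(S.S, 1.0, atol=1e-12)


def test_single_type_weights_collapse():
    """One atom type: the Faber-Ziman weight is 1 regardless of f(Q)."""
    rng = np.random.default_rng(3)
    r = np.arange(0.01, 12, 0.02)
    h = 0.4 * np.exp(-0.5 * ((r - 4.0) / 0.5) ** 2)
    Q = default_q_grid(dq=0.1)
    out = {}
    for el in ("C", "Cl"):  # very different form factors
        ps = PairFunctionSet(
            r=r, g={(el, el): 1.0 + h}, rho=0.03, c={el: 1.0},
            element_of={el: el},
        )
        out[el] = xray_total_sq(ps, Q).S
    assert np.allclose(out["C"], out["Cl"], atol=1e-12)


def test_cluster_sq_matches_debye_sum_oracle(nif):
    """Single rigid molecule: package S(Q) equals the direct Debye sum."""
    cfg = Configuration(40.0, [nif], [nif.positions() + 20.0])
    Q = np.arange(0.6, 25.0, 0.1)
    S = xray_total_sq(cfg, Q, include_intermolecular=False)
    pos = nif.positions()
    els = nif.elements
    f = np.array([xray_form_factor(e, Q) for e in els])
    mean_f = f.mean(axis=0)
    acc = np.zeros_like(Q)
    for i in range(len(els)):
        for j in range(len(els)):
            if i == j:
                continue
            rij = np.linalg.norm(pos[i] - pos[j])
            acc += f[i] * f[j] * np.sin(Q * rij) / (Q * rij)
    oracle = 1.0 + acc / (len(els) * mean_f**2)
    assert np.abs(S.S - oracle).max() < 1e-3


def test_high_q_limit_is_unity(nif):
    """S_X(Q) -> 1 at high Q for a many-molecule configuration."""
    rng = np.random.default_rng(5)
    coords = [nif.positions() + rng.uniform(0, 24, 3) for _ in range(8)]
    cfg = Configuration(24.0, [nif] * 8, coords)
    S = xray_total_sq(cfg, default_q_grid(dq=0.05))
    assert abs(S.high_q_level() - 1.0) < 0.02


def test_label_swap_of_identical_types_leaves_sq_unchanged():
    rng = np.random.default_rng(8)
    L = 15.0
    pts = rng.uniform(0, L, (40, 3))
    cfg = make_point_config(pts, L)
    cfg_swapped = make_point_config(pts[::-1], L)
    Q = default_q_grid(dq=0.2)
    assert np.allclose(xray_total_sq(cfg, Q).S, xray_total_sq(cfg_swapped, Q).S)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def test_flat_sq_transforms_to_zero():
    Q = default_q_grid(dq=0.05)
    pat = ScatteringPattern(Q, np.ones_like(Q))
    D = sq_to_dr(pat, rho=0.05)
    assert np.allclose(D.D, 0.0, atol=1e-12)


def test_transform_round_trip_recovers_differential_pdf():
    """g -> S (Faber-Ziman) -> D recovers 4 pi rho r (g - 1)."""
    rho = 0.03
    r = np.arange(0.005, 30, 0.01)
    g = 1.0 + 0.5 * np.exp(-0.5 * ((r - 4.0) / 0.45) ** 2)
    ps = PairFunctionSet(r=r, g={("C", "C"): g}, rho=rho, c={"C": 1.0},
                         element_of={"C": "C"})
    Q = np.arange(0.02, 30.0, 0.02)
    S = xray_total_sq(ps, Q)
    rg = np.arange(0.0, 10.0, 0.02)
    D = sq_to_dr(S, rho, r_grid=rg, require_normalized=False)
    expect = 4 * np.pi * rho * rg * (np.interp(rg, r, g) - 1.0)
    sel = rg > 1.0  # below 1 Å only termination ripples live
    assert np.abs(D.D - expect)[sel].max() < 1e-3


def test_transform_linearity():
    Q = default_q_grid(dq=0.05)
    S1 = 1.0 + 0.3 * np.exp(-0.5 * ((Q - 2.0) / 0.3) ** 2)
    a = 2.5
    D1 = sq_to_dr(ScatteringPattern(Q, S1), 0.05, require_normalized=False)
    Da = sq_to_dr(ScatteringPattern(Q, 1 + a * (S1 - 1)), 0.05,
                  require_normalized=False)
    assert np.allclose(Da.D, a * D1.D, atol=1e-10)


def test_lorch_window_suppresses_low_r_ripples():
    """Truncated hard-sphere-like S(Q): Lorch reduces spurious D(r) below 1 Å."""
    Q = np.arange(0.05, 10.0, 0.02)  # deliberately truncated
    S = 1.0 + np.sin(Q * 3.5) / (Q * 3.5) * 2.0
    rg = np.arange(0.0, 1.0, 0.01)
    raw = sq_to_dr(ScatteringPattern(Q, S), 0.05, r_grid=rg,
                   require_normalized=False)
    win = sq_to_dr(ScatteringPattern(Q, S), 0.05, r_grid=rg, window="lorch",
                   require_normalized=False)
    assert np.abs(win.D).max() < np.abs(raw.D).max()


def test_unnormalized_pattern_rejected():
    Q = default_q_grid(dq=0.1)
    pat = ScatteringPattern(Q, np.full_like(Q, 1.5))
    with pytest.raises(ValueError, match="not normalized"):
        sq_to_dr(pat, 0.05)


def test_total_g_from_differential():
    rg = np.arange(0.0, 5.0, 0.1)
    rho = 0.04
    g = 1.0 + 0.2 * np.sin(rg)
    D = DifferentialPDF(rg, 4 * np.pi * rho * rg * (g - 1.0), rho)
    assert np.allclose(D.total_g()[1:], g[1:])


# ---------------------------------------------------------------------------
# intramolecular stick spectra
# ---------------------------------------------------------------------------


def test_stick_spectrum_tiny_broadening_peaks_at_distance(fel):
    r, y, sticks = intramolecular_pair_pdf(fel, ("Cl", "Cl"), 0.002)
    assert len(sticks) == 1
    assert peak_position(r, y) == pytest.approx(sticks[0][0], abs=1e-3)


def test_clcl_peak_position_and_rotation_invariance(fel):
    """The Cl-Cl peak sits at ~3.1 Å and is unmoved by ester torsions."""
    from epsrkit.molecules import MolecularTemplate, rotate_group

    r, y, _ = intramolecular_pair_pdf(fel, ("Cl", "Cl"), 0.1)
    p0 = peak_position(r, y)
    assert round(p0, 1) == 3.1
    pos = rotate_group(fel, fel.positions(), 0, 120.0)
    atoms = [
        type(a)(a.label, a.element, a.type_key, tuple(p))
        for a, p in zip(fel.atoms, pos)
    ]
    rotated = MolecularTemplate(fel.name, fel.conformer_id, atoms, fel.bonds,
                                fel.rotatable_groups)
    r2, y2, _ = intramolecular_pair_pdf(rotated, ("Cl", "Cl"), 0.1)
    assert peak_position(r2, y2) == pytest.approx(p0, abs=1e-6)


def test_empty_selector_rejected(fel):
    with pytest.raises(ValueError, match="matched no"):
        intramolecular_pair_pdf(fel, lambda a, b: False, 0.1)


# ---------------------------------------------------------------------------
# FSDP
# ---------------------------------------------------------------------------


def test_fsdp_constructed_gaussian():
    Q = default_q_grid(dq=0.02)
    S = 1.0 + 0.5 * np.exp(-0.5 * ((Q - 1.4) / 0.15) ** 2)
    pos, height, width = fsdp_metrics(ScatteringPattern(Q, S))
    assert pos == pytest.approx(1.4, abs=1e-3)
    assert height == pytest.approx(0.5, abs=1e-3)
    assert width == pytest.approx(0.15 * 2.3548, rel=0.05)


def test_fsdp_flat_pattern_raises():
    Q = default_q_grid(dq=0.05)
    with pytest.raises(PeakNotFoundError):
        fsdp_metrics(ScatteringPattern(Q, np.ones_like(Q)))


def test_fsdp_heights_track_inserted_peaks():
    Q = default_q_grid(dq=0.02)
    heights = []
    for h in (0.1, 0.25, 0.4, 0.8):
        S = 1.0 + h * np.exp(-0.5 * ((Q - 1.3) / 0.2) ** 2)
        heights.append(fsdp_metrics(ScatteringPattern(Q, S))[1])
    assert np.all(np.diff(heights) > 0)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def test_sq_ascii_roundtrip(tmp_path):
    Q = default_q_grid(dq=0.1)
    S = 1.0 + 0.1 * np.sin(Q)
    sig = np.full_like(Q, 0.005)
    pat = ScatteringPattern(Q, S, sigma=sig)
    path = tmp_path / "sq.txt"
    write_sq(pat, path, header="test pattern")
    back = read_sq(path)
    assert np.allclose(back.Q, Q)
    assert np.allclose(back.S, S)
    assert np.allclose(back.sigma, sig)


def test_pattern_invariants_enforced():
    with pytest.raises(ValueError):
        ScatteringPattern(np.array([0.0, 1.0]), np.array([1.0, 1.0]))  # Q[0]=0
    with pytest.raises(ValueError):
        ScatteringPattern(np.array([1.0, 0.5]), np.array([1.0, 1.0]))  # descending
    with pytest.raises(ValueError):
        ScatteringPattern(np.array([0.5, 1.0]), np.array([np.nan, 1.0]))
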