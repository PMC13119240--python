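"""Monte Carlo engine, constraints, R-factors and empirical-potential updates."""

import numpy as np
import pytest

from epsrkit.boxes import Configuration
from epsrkit.molecules import AtomSpec, FFEntry, ForceField, MolecularTemplate
from epsrkit.refine import (
    ConstraintSet,
    EmpiricalPotentialState,
    MCEngine,
    fit_scale,
    mc_step,
    metropolis_accept,
    r_factor,
    random_configuration,
    refine_to_data,
    update_empirical_potential,
    xray_pair_weights,
)
from epsrkit.scattering import ScatteringPattern, default_q_grid

from conftest import make_point_config


# ---------------------------------------------------------------------------
# Metropolis rule
# ---------------------------------------------------------------------------


def test_downhill_moves_always_accepted():
    rng = np.random.default_rng(0)
    assert all(metropolis_accept(-1.0, 2.5, rng) for _ in range(1000))
    assert all(metropolis_accept(0.0, 2.5, rng) for _ in range(10))


def test_acceptance_frequency_at_kt_is_inverse_e():
    """P(accept | dU = kT) = e^-1, checked against 10,000 Bernoulli draws."""
    rng = np.random.default_rng(123)
    n = 10_000
    kT = 2.494
    acc = sum(metropolis_accept(kT, kT, rng) for _ in range(n)) / n
    p = np.exp(-1.0)
    assert abs(acc - p) < 3 * np.sqrt(p * (1 - p) / n)


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------


def _nh_and_o_templates():
    donor = MolecularTemplate(
        "donor", "", [
            AtomSpec("N1", "N", "N_NHR", (0.0, 0.0, 0.0)),
            AtomSpec("H1N", "H", "H_NHR", (-1.01, 0.0, 0.0)),
        ], [("N1", "H1N")], [],
    )
    acceptor = MolecularTemplate(
        "acceptor", "", [
            AtomSpec("O1", "O", "O_R2CO", (0.0, 0.0, 0.0)),
            AtomSpec("C1", "C", "C_R2CO", (1.22, 0.0, 0.0)),
        ], [("O1", "C1")], [],
    )
    return donor, acceptor


def test_move_violating_nh_o_floor_is_rejected(ff):
    """An N···O approach to 2.5 Å under a 2.9 Å floor must be rejected."""
    donor, acceptor = _nh_and_o_templates()
    cfg = Configuration(
        20.0, [donor, acceptor],
        [donor.positions(), acceptor.positions() + np.array([8.0, 0, 0])],
        temperature_K=300.0,
    )
    eng = MCEngine(cfg, ff, constraints=ConstraintSet.nh_o_default(2.9), seed=1)
    bad = acceptor.positions() + np.array([2.5, 0.0, 0.0])  # O1 at 2.5 Å from N1
    assert not eng.constraint_ok(1, bad)
    ok = acceptor.positions() + np.array([3.5, 0.0, 0.0])  # O1 at 3.5 Å
    assert eng.constraint_ok(1, ok)


def test_hard_minimum_never_violated_during_run(lj_ff, lj_template):
    cs = ConstraintSet(hard_core_factor=0.6)
    cfg = random_configuration([lj_template] * 40, 16.0, 300.0, lj_ff,
                               constraints=cs, seed=2)
    eng = MCEngine(cfg, lj_ff, constraints=cs, seed=3)
    eng.run(30)
    pos = eng.config.flat_positions()
    d = pos[:, None, :] - pos[None, :, :]
    d -= 16.0 * np.round(d / 16.0)
    r = np.linalg.norm(d, axis=-1)
    np.fill_diagonal(r, 99.0)
    assert r.min() >= 0.6 * 3.55  # sigma_C default


def test_unknown_move_kind_rejected(lj_ff, lj_template):
    cfg = random_configuration([lj_template] * 5, 12.0, 300.0, lj_ff, seed=4)
    eng = MCEngine(cfg, lj_ff, seed=5)
    with pytest.raises(ValueError, match="move kind"):
        eng.step("teleport")
    with pytest.raises(ValueError, match="move kind"):
        mc_step(cfg, lj_ff, None, None, "teleport", seed=6)


def test_identical_seeds_give_bit_identical_trajectories(lj_ff, lj_template):
    runs = []
    for _ in range(2):
        cfg = random_configuration([lj_template] * 20, 14.0, 300.0, lj_ff, seed=7)
        eng = MCEngine(cfg, lj_ff, seed=8)
        eng.run(15)
        runs.append(eng.config.flat_positions().copy())
    assert np.array_equal(runs[0], runs[1])


# ---------------------------------------------------------------------------
# R-factor and scale
# ---------------------------------------------------------------------------


def test_r_factor_closed_forms():
    Q = default_q_grid(dq=0.1)
    S = 1.0 + 0.2 * np.sin(Q)
    assert r_factor(ScatteringPattern(Q, S), ScatteringPattern(Q, S)) == 0.0
    assert r_factor(ScatteringPattern(Q, S + 0.1), ScatteringPattern(Q, S)) == \
        pytest.approx(0.01, rel=1e-12)


def test_r_factor_matches_direct_summation_oracle():
    rng = np.random.default_rng(11)
    Q = default_q_grid(dq=0.1)
    a = 1.0 + 0.3 * rng.normal(size=len(Q))
    b = 1.0 + 0.3 * rng.normal(size=len(Q))
    manual = sum((x - y) ** 2 for x, y in zip(a, b)) / len(Q)
    assert r_factor(ScatteringPattern(Q, a), ScatteringPattern(Q, b)) == \
        pytest.approx(manual, rel=1e-12)


def test_r_factor_grid_mismatch_rejected():
    Q1 = default_q_grid(dq=0.1)
    Q2 = default_q_grid(dq=0.2)
    with pytest.raises(ValueError, match="different Q grids"):
        r_factor(ScatteringPattern(Q1, np.ones_like(Q1)),
                 ScatteringPattern(Q2, np.ones_like(Q2)))


def test_fit_scale_closed_forms_and_noise():
    rng = np.random.default_rng(12)
    Q = default_q_grid(dq=0.05)
    S = 1.0 + 0.4 * np.exp(-0.5 * ((Q - 1.5) / 0.3) ** 2) + 0.1 * np.sin(Q)
    model = ScatteringPattern(Q, S)
    assert fit_scale(model, model) == pytest.approx(1.0)
    target = ScatteringPattern(Q, 1 + 0.8 * (S - 1))
    assert fit_scale(model, target) == pytest.approx(1.25, rel=1e-12)
    noisy = ScatteringPattern(Q, 1 + 0.8 * (S - 1) + rng.normal(0, 0.005, len(Q)))
    assert fit_scale(model, noisy) == pytest.approx(1.25, rel=0.02)
    with pytest.raises(ValueError, match="degenerate"):
        fit_scale(model, ScatteringPattern(Q, np.ones_like(Q)))


# ---------------------------------------------------------------------------
# empirical potential updates
# ---------------------------------------------------------------------------


def _ep_and_patterns():
    Q = default_q_grid(dq=0.05)
    S = 1.0 + 0.3 * np.exp(-0.5 * ((Q - 1.5) / 0.3) ** 2)
    ep = EmpiricalPotentialState.zeros(pairs=[("C", "C")], r_max=8.0)
    return ep, ScatteringPattern(Q, S), Q


def test_zero_residual_leaves_ep_unchanged():
    ep, pat, _ = _ep_and_patterns()
    new = update_empirical_potential(ep, pat, pat, {("C", "C"): 1.0},
                                     rho=0.02, temperature_K=300.0)
    assert np.allclose(new.tables[("C", "C")], 0.0, atol=1e-15)
    assert new.iteration == 1


def test_ep_amplitude_never_exceeds_cap():
    ep, pat, Q = _ep_and_patterns()
    ep.amplitude_cap = 2.0
    target = ScatteringPattern(Q, np.ones_like(Q))
    rng = np.random.default_rng(13)
    for _ in range(40):
        wiggle = ScatteringPattern(Q, pat.S + rng.normal(0, 0.1, len(Q)))
        ep = update_empirical_potential(ep, wiggle, target, {("C", "C"): 1.0},
                                        rho=0.02, temperature_K=300.0)
        assert ep.max_amplitude() <= 2.0 + 1e-12


def test_ep_update_grid_mismatch_rejected():
    ep, pat, _ = _ep_and_patterns()
    Q2 = default_q_grid(dq=0.1)
    with pytest.raises(ValueError, match="different Q grids"):
        update_empirical_potential(
            ep, pat, ScatteringPattern(Q2, np.ones_like(Q2)),
            {("C", "C"): 1.0}, rho=0.02, temperature_K=300.0,
        )


def test_ep_update_pushes_against_excess_structure():
    """Model with more structure than target at r0 gains a repulsive bump
    near r0 (the fixed-point feedback has the right sign)."""
    ep = EmpiricalPotentialState.zeros(pairs=[("C", "C")], r_max=9.0)
    Q = np.arange(0.3, 25.0, 0.02)
    rho = 0.02
    r0, w = 4.0, 0.4
    # S built from a g-excess at r0 via the same FZ transform
    r = np.arange(0.01, 9.0, 0.01)
    h = 0.3 * np.exp(-0.5 * ((r - r0) / w) ** 2)
    Qr = np.outer(Q, r)
    S_model = 1 + 4 * np.pi * rho * np.trapezoid(r**2 * h * np.sin(Qr) / Qr, r, axis=-1)
    pat_m = ScatteringPattern(Q, S_model)
    pat_t = ScatteringPattern(Q, np.ones_like(Q))
    new = update_empirical_potential(ep, pat_m, pat_t, {("C", "C"): 1.0},
                                     rho=rho, temperature_K=300.0)
    u = new.tables[("C", "C")]
    assert u[np.argmin(np.abs(new.r - r0))] > 0  # repulsive where g too high
    assert np.abs(u[new.r < 2.0]).max() < u.max() * 0.5  # localized


def test_xray_pair_weights_normalized(nif):
    cfg = Configuration(30.0, [nif], [nif.positions() + 15])
    w = xray_pair_weights(cfg)
    assert max(w.values()) == pytest.approx(1.0)
    assert all(v > 0 for v in w.values())
    assert set(k for pair in w for k in pair) == {"H", "C", "N", "O"}


# ---------------------------------------------------------------------------
# refinement plumbing
# ---------------------------------------------------------------------------


def test_refine_zero_iterations_returns_start(lj_ff, lj_template):
    cfg = random_configuration([lj_template] * 20, 14.0, 300.0, lj_ff, seed=20)
    Q = default_q_grid(dq=0.2)
    target = ScatteringPattern(Q, np.ones_like(Q))
    res = refine_to_data(cfg, lj_ff, target, n_iterations=0)
    assert np.array_equal(res.config.flat_positions(), cfg.flat_positions())
    assert len(res.r_history) == 1
    assert res.r_history[0] >= 0


def test_scan_fraction_zero_matches_pure_pipeline(ff):
    """A 0.0 mixture fraction runs the identical pipeline to the pure
    single-conformer model: same seed, same R-factor."""
    from epsrkit.boxes import box_edge_for_density
    from epsrkit.refine import ScanProtocol, scan_conformer_fraction
    from epsrkit.synthetic_data import SyntheticSpec, make_pseudo_experiment

    from conftest import cl_chain_template

    lj_ff = ForceField(entries={"LJS": FFEntry(0.0, 3.4, 0.6)},
                       element_defaults=ff.element_defaults)
    ext = cl_chain_template("extended")
    fol = cl_chain_template("folded")
    n_mol, rho, T = 8, 0.012, 400.0
    edge = box_edge_for_density([(ext, n_mol)], rho)
    cfg0 = random_configuration([ext] * n_mol, edge, T, lj_ff, seed=5)
    spec = SyntheticSpec(components=[(ext, 1.0)], n_molecules=n_mol,
                         density=rho, temperature_K=T, seed=5,
                         noise_sigma=0.0, dq=0.2)
    target, _ = make_pseudo_experiment([cfg0], spec)
    proto = ScanProtocol(template_a=ext, template_b=fol, n_molecules=n_mol,
                         box_edge=edge, temperature_K=T, n_iterations=1,
                         sweeps_per_iter=4, ensemble_size=10,
                         ensemble_stride=1, equil_sweeps=10, seed=5,
                         n_replicas=1)
    df = scan_conformer_fraction([0.0], target, proto, lj_ff)
    pure = refine_to_data(
        random_configuration([ext] * n_mol, edge, T, lj_ff, seed=5),
        lj_ff, target, n_iterations=1, sweeps_per_iter=4, fit_snapshots=4,
        ensemble_size=10, ensemble_stride=1, seed=5, equil_sweeps=10,
    )
    assert df.r_factor.iloc[0] == pure.r_history[-1]


def test_scan_rejects_out_of_range_fractions(ff):
    from epsrkit.refine import ScanProtocol, scan_conformer_fraction
    from epsrkit.scattering import ScatteringPattern

    from conftest import cl_chain_template

    ext = cl_chain_template("extended")
    fol = cl_chain_template("folded")
    Q = default_q_grid(dq=0.5)
    target = ScatteringPattern(Q, np.ones_like(Q))
    proto = ScanProtocol(template_a=ext, template_b=fol, n_molecules=4,
                         box_edge=15.0)
    with pytest.raises(ValueError, match="outside"):
        scan_conformer_fraction([0.0, 1.2], target, proto, ff)


def test_nvt_energy_matches_independent_plain_mc_oracle(lj_ff, lj_template):
    """With no data term the engine is plain Metropolis NVT: its mean energy
    agrees with a small, independently coded Metropolis implementation."""
    L, N, T = 14.0, 30, 300.0
    kT = 0.008314462618 * T
    sigma, eps = 3.4, 1.0

    cfg = random_configuration([lj_template] * N, L, T, lj_ff, seed=21)
    eng = MCEngine(cfg, lj_ff, seed=22, auto_tune=False)
    eng.move_sizes.translate = 0.45
    eng.run(150)
    samples = []
    for _ in range(300):
        eng.run(1)
        samples.append(eng.model.total())
    mean_pkg = np.mean(samples)

    # independent oracle: textbook Metropolis on the same state point,
    # same truncated LJ (cutoff L/2)
    rng = np.random.default_rng(99)
    pos = cfg.flat_positions().copy()
    rc = L / 2.0

    def pair_e(r):
        x = (sigma / r) ** 6
        return np.where(r < rc, 4 * eps * (x * x - x), 0.0)

    def energy_of(i, p):
        d = np.delete(pos, i, axis=0) - p
        d -= L * np.round(d / L)
        r = np.linalg.norm(d, axis=-1)
        return pair_e(r).sum()

    def total():
        e = 0.0
        for i in range(N):
            e += energy_of(i, pos[i])
        return e / 2.0

    oracle = []
    for sweep in range(450):
        for _ in range(N):
            i = rng.integers(N)
            new = pos[i] + rng.uniform(-0.45, 0.45, 3)
            du = energy_of(i, new) - energy_of(i, pos[i])
            if du <= 0 or rng.random() < np.exp(-du / kT):
                pos[i] = new
        if sweep >= 150:
            oracle.append(total())
    mean_oracle = np.mean(oracle)
    spread = np.std(oracle) + np.std(samples)
    assert abs(mean_pkg - mean_oracle) < max(3.0 * spread / np.sqrt(20), 0.05 * abs(mean_oracle) + 1.0)
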