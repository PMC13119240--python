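"""Coordination numbers, hydrogen-bond censuses and density conversions."""

import numpy as np
import pytest

from epsrkit.boxes import Configuration
from epsrkit.molecules import AtomSpec, MolecularTemplate
from epsrkit.scattering import PairFunctionSet, compute_partial_gr
from epsrkit.structure_analysis import (
    HBondCriteria,
    default_acceptor_classes,
    density_convert,
    drug_polymer_preference,
    hbond_census,
    mass_density_to_number,
    parse_formula,
    running_coordination,
)

from conftest import make_point_config


# ---------------------------------------------------------------------------
# running coordination
# ---------------------------------------------------------------------------


def test_ideal_gas_coordination_closed_form():
    """g = 1 gives n(r) = (4/3) pi rho c_b r^3 exactly (quadrature error only)."""
    r = np.arange(0.01, 10, 0.01)
    rho, cb = 0.05, 0.3
    ps = PairFunctionSet(
        r=r, g={("A", "B"): np.ones_like(r)}, rho=rho,
        c={"A": 0.7, "B": cb}, element_of={"A": "C", "B": "O"},
    )
    n = running_coordination(ps, "A", "B")
    expect = 4.0 / 3.0 * np.pi * rho * cb * r**3
    assert np.abs(n.n - expect).max() < 1e-3 * expect.max()
    assert n.n[0] < 1e-4  # n(0) ~ 0
    assert np.all(np.diff(n.n) >= 0)  # non-decreasing


def test_isolated_pair_step_function():
    cfg = make_point_config([[0, 0, 0], [3.0, 0, 0]], 12.0)
    ps = compute_partial_gr(cfg, dr=0.05)
    n = running_coordination(ps, "C", "C")
    assert n.at(2.5) == pytest.approx(0.0, abs=1e-9)
    assert n.at(3.5) == pytest.approx(1.0, abs=1e-9)
    assert n.crossing(0.5) == pytest.approx(3.0, abs=0.06)


def test_coordination_matches_direct_count_oracle():
    rng = np.random.default_rng(17)
    L, N = 15.0, 120
    cfg = make_point_config(rng.uniform(0, L, (N, 3)), L)
    ps = compute_partial_gr(cfg, dr=0.05)
    n = running_coordination(ps, "C", "C")
    pos = cfg.flat_positions()
    for r_q in (3.0, 5.0, 7.0):
        count = 0
        for i in range(N):
            d = np.delete(pos, i, axis=0) - pos[i]
            d -= L * np.round(d / L)
            count += int((np.linalg.norm(d, axis=-1) <= r_q).sum())
        assert n.at(r_q) == pytest.approx(count / N, abs=0.02 * max(count / N, 1))


def test_missing_partial_rejected():
    r = np.arange(0.01, 5, 0.1)
    ps = PairFunctionSet(r=r, g={("A", "A"): np.ones_like(r)}, rho=0.05,
                         c={"A": 1.0}, element_of={"A": "C"})
    with pytest.raises(KeyError):
        running_coordination(ps, "A", "B")


# ---------------------------------------------------------------------------
# hydrogen-bond census
# ---------------------------------------------------------------------------


def _donor_template():
    return MolecularTemplate(
        "drug_like", "", [
            AtomSpec("N1", "N", "N_NHR", (0.0, 0.0, 0.0)),
            AtomSpec("H1N", "H", "H_NHR", (1.01, 0.0, 0.0)),
            AtomSpec("C1", "C", "default", (-1.4, 0.0, 0.0)),
        ], [("N1", "H1N"), ("N1", "C1")], [],
    )


def _acceptor_template(name="drug_like2", type_key="O_R2CO"):
    return MolecularTemplate(
        name, "", [
            AtomSpec("O1", "O", type_key, (0.0, 0.0, 0.0)),
            AtomSpec("C1", "C", "C_R2CO", (1.22, 0.0, 0.0)),
        ], [("O1", "C1")], [],
    )


def test_empty_box_has_zero_bonds():
    donor = _donor_template()
    cfg = Configuration(20.0, [donor], [donor.positions()])
    census = hbond_census(cfg)
    assert len(census) == 0
    assert census.attrs["n_donors"] == 1


def _donor_acceptor_config(d_no=3.0, L=20.0):
    donor = _donor_template()
    acceptor = _acceptor_template()
    # acceptor O along the N-H direction at d_no: near-linear N-H...O
    coords = [donor.positions(), acceptor.positions() + np.array([d_no, 0, 0])]
    return Configuration(L, [donor, acceptor], coords)


def test_census_finds_linear_bond_and_respects_criteria():
    cfg = _donor_acceptor_config(3.0)
    census = hbond_census(cfg, HBondCriteria(d_max=3.5, angle_min=120.0))
    assert len(census) == 1
    row = census.iloc[0]
    assert row.d_NO == pytest.approx(3.0)
    assert row.angle_NHO == pytest.approx(180.0)
    assert row.acceptor_class == "ester_carbonyl"
    # tighter distance criterion excludes it
    assert len(hbond_census(cfg, HBondCriteria(d_max=2.8))) == 0
    # impossible angle criterion excludes it
    assert len(hbond_census(cfg, HBondCriteria(angle_min=179.9999))) == 1


def test_census_invariant_under_rigid_translation():
    cfg = _donor_acceptor_config(3.2)
    c1 = hbond_census(cfg)
    shifted = Configuration(
        cfg.box_edge, cfg.templates,
        [c + np.array([7.3, -4.4, 11.0]) for c in cfg.coords],
    )
    c2 = hbond_census(shifted)
    assert len(c1) == len(c2) == 1
    assert c1.iloc[0].d_NO == pytest.approx(c2.iloc[0].d_NO)
    assert c1.iloc[0].angle_NHO == pytest.approx(c2.iloc[0].angle_NHO)


def test_zero_angle_criterion_equals_pure_distance_count():
    """With angle_min = 0 the census is exactly the number of N···O pairs
    within d_max (cross-check between the two operations)."""
    rng = np.random.default_rng(23)
    donor = _donor_template()
    acceptor = _acceptor_template()
    L = 18.0
    templates = [donor] * 4 + [acceptor] * 6
    coords = [t.positions() + rng.uniform(0, L, 3) for t in templates]
    cfg = Configuration(L, templates, coords)
    d_max = 6.0
    census = hbond_census(cfg, HBondCriteria(d_max=d_max, angle_min=0.0))
    # direct N...O pair count
    count = 0
    for i in range(4):
        n_xyz = cfg.coords[i][0]
        for j in range(4, 10):
            d = cfg.coords[j][0] - n_xyz
            d -= L * np.round(d / L)
            if np.linalg.norm(d) <= d_max:
                count += 1
    assert len(census) == count


# ---------------------------------------------------------------------------
# drug-polymer preference
# ---------------------------------------------------------------------------


def test_polymer_only_box_flags_ratio():
    donor = _donor_template()
    pvp_o = _acceptor_template(name="pvp_like", type_key="O_R2CO")
    cfg = Configuration(
        20.0, [donor, pvp_o],
        [donor.positions(), pvp_o.positions() + np.array([3.0, 0, 0])],
    )
    pref = drug_polymer_preference(cfg, r_cut=5.0)
    assert pref.n_at_cut["pvp_carbonyl"] > 0
    assert pref.n_at_cut["ester_carbonyl"] == 0
    assert pref.ratio == 0.0
    assert pref.flag == "polymer-only"


def test_preference_counts_match_direct_count():
    rng = np.random.default_rng(29)
    donor = _donor_template()
    drug_o = _acceptor_template(name="drug_o")
    pvp_o = _acceptor_template(name="pvp_like")
    L = 18.0
    templates = [donor] * 3 + [drug_o] * 5 + [pvp_o] * 5
    coords = [t.positions() + rng.uniform(0, L, 3) for t in templates]
    cfg = Configuration(L, templates, coords)
    r_cut = 6.0
    pref = drug_polymer_preference(cfg, r_cut=r_cut)
    for cls, sel in (("ester_carbonyl", range(3, 8)), ("pvp_carbonyl", range(8, 13))):
        count = 0
        for i in range(3):
            n_xyz = cfg.coords[i][0]
            for j in sel:
                d = cfg.coords[j][0] - n_xyz
                d -= L * np.round(d / L)
                if np.linalg.norm(d) <= r_cut:
                    count += 1
        assert pref.n_at_cut[cls] == pytest.approx(count / 3, abs=0.05)


def test_preference_total_additive_over_classes():
    rng = np.random.default_rng(31)
    donor = _donor_template()
    drug_o = _acceptor_template(name="drug_o")
    pvp_o = _acceptor_template(name="pvp_like")
    L = 18.0
    templates = [donor] * 3 + [drug_o] * 4 + [pvp_o] * 4
    coords = [t.positions() + rng.uniform(0, L, 3) for t in templates]
    cfg = Configuration(L, templates, coords)
    pref = drug_polymer_preference(cfg, r_cut=5.0)
    total = pref.total()
    assert np.allclose(total, sum(pref.curves.values()), atol=1e-12)


def test_missing_polymer_class_rejected():
    donor = _donor_template()
    drug_o = _acceptor_template(name="drug_o")
    cfg = Configuration(
        20.0, [donor, drug_o],
        [donor.positions(), drug_o.positions() + np.array([3, 0, 0])],
    )
    with pytest.raises(ValueError, match="absent"):
        drug_polymer_preference(cfg)


# ---------------------------------------------------------------------------
# density conversions
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "n_density,formula,expected",
    [
        (0.105, "C17H18N2O6", 1.40),  # nifedipine glass regime
        (0.110, "C17H18N2O6", 1.47),
        (0.093, "C18H19Cl2NO4", 1.35),  # felodipine
    ],
)
def test_density_conversion_printed_values(n_density, formula, expected):
    assert density_convert(n_density, formula) == pytest.approx(expected, abs=0.005)


def test_density_zero_and_roundtrip():
    assert density_convert(0.0, "C17H18N2O6") == 0.0
    x = 0.1077
    back = mass_density_to_number(density_convert(x, "C6H9NO"), "C6H9NO")
    assert back == pytest.approx(x, rel=1e-12)


def test_formula_parsing():
    assert parse_formula("C17H18N2O6") == {"C": 17, "H": 18, "N": 2, "O": 6}
    assert parse_formula("ClH") == {"Cl": 1, "H": 1}
    with pytest.raises(ValueError):
        parse_formula("C17X3")
    with pytest.raises(ValueError):
        parse_formula("17C")
    with pytest.raises(ValueError):
        density_convert(-0.1, "C")
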