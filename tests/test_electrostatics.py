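import numpy as np
import pytest

from structbatch.electrostatics import (ChargeAssignment, assign_charges,
                                        bjerrum_length_vacuum, debye_kappa2,
                                        equipotential_mask, grid_to_opendx,
                                        solve_lpbe, surface_potential)
from structbatch.fixtures import build_peptide
from structbatch.structure_io import Atom, Chain, Model, Residue, Structure


def _point_charges(specs):
    """Structure + ChargeAssignment from (coord, q, radius) triples."""
    atoms, charges, radii = [], [], []
    residues = []
    for i, (coord, q, r) in enumerate(specs):
        a = Atom(serial=i + 1, name="X", element="C", coord=coord,
                 is_hetero=True)
        atoms.append(a)
        charges.append(q)
        radii.append(r)
        residues.append(Residue(chain_id="A", number=i + 1, type="ION",
                                atoms=[a], structure_id="ions"))
    st = Structure(id="ions", models=[Model(chains=[
        Chain(id="A", residues=residues, structure_id="ions")])])
    return st, ChargeAssignment(atoms=atoms, charges=np.array(charges,
                                                              float),
                                radii=np.array(radii, float))


def test_physical_constants():
    assert bjerrum_length_vacuum() == pytest.approx(560.7, abs=1.0)
    # Debye length ~7.9 A at 0.15 M in water
    assert 1.0 / np.sqrt(debye_kappa2(0.15, 80.0)) == pytest.approx(7.9,
                                                                    abs=0.2)


def test_free_aspartate_net_charge_minus_one():
    st = build_peptide("D", [(-120.0, 130.0)], with_oxt=True)
    ca = assign_charges(st, charge_termini=True)
    assert ca.total_charge == pytest.approx(-1.0, abs=1e-9)


def test_polyalanine_neutral_without_termini():
    st = build_peptide("AAAA", [(-57.0, -47.0)] * 4)
    ca = assign_charges(st, charge_termini=False)
    assert ca.total_charge == pytest.approx(0.0, abs=1e-12)


def test_three_lys_one_glu_neutral_termini():
    st = build_peptide("KAKEKA", [(-120.0, 130.0)] * 6)
    ca = assign_charges(st, charge_termini=False)
    assert ca.total_charge == pytest.approx(2.0, abs=1e-9)


def test_ligand_atoms_warn_and_default_to_zero():
    st, _ = _point_charges([((0.0, 0.0, 0.0), 0.0, 1.7)])
    ca = assign_charges(st)
    assert ca.total_charge == 0.0
    assert any("no charge" in w for w in ca.warnings)


def test_zero_charges_zero_field():
    st, ca = _point_charges([((0.0, 0.0, 0.0), 0.0, 1.7)])
    grid = solve_lpbe(st, ca, n=17, box=20.0)
    assert np.all(grid.values == 0.0)


def test_debye_hueckel_oracle_within_5_percent():
    """Uniform dielectric, 0.15 M salt: the solver must match the screened
    Coulomb monopole to <= 5% over the 4-12 A shell."""
    st, ca = _point_charges([((0.0, 0.0, 0.0), 1.0, 1.7)])
    grid = solve_lpbe(st, ca, n=65, salt=0.15, eps_in=80.0, eps_out=80.0,
                      box=36.0, ion_exclusion=False)
    l_b = bjerrum_length_vacuum() / 80.0
    kap = np.sqrt(debye_kappa2(0.15, 80.0))
    rng = np.random.default_rng(0)
    for r in np.linspace(4.0, 12.0, 9):
        for _ in range(8):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            num = grid.interpolate(v * r)[0]
            ana = l_b * np.exp(-kap * r) / r
            assert abs(num - ana) / ana <= 0.05


def test_linearity_of_the_solver():
    spec1 = [((-3.0, 0.0, 0.0), 1.0, 1.7)]
    spec2 = [((3.0, 1.0, 0.0), -0.5, 1.7)]
    st1, ca1 = _point_charges(spec1)
    st2, ca2 = _point_charges(spec2)
    st12, ca12 = _point_charges(spec1 + spec2)
    kw = dict(n=33, box=30.0, ion_exclusion=False, eps_in=80.0, eps_out=80.0,
              center=(0.0, 0.0, 0.0))   # shared grid so fields superpose
    g1 = solve_lpbe(st1, ca1, **kw)
    g2 = solve_lpbe(st2, ca2, **kw)
    g12 = solve_lpbe(st12, ca12, **kw)
    # compare away from the grid boundary and the charges themselves
    pts = np.random.default_rng(1).uniform(-8, 8, size=(40, 3))
    v_sum = g1.interpolate(pts) + g2.interpolate(pts)
    v_tot = g12.interpolate(pts)
    scale = np.abs(v_tot).max()
    assert np.allclose(v_tot, v_sum, atol=2e-3 * scale + 1e-9)


def test_mirror_antisymmetry():
    st, ca = _point_charges([((-4.0, 0.0, 0.0), 1.0, 1.7),
                             ((4.0, 0.0, 0.0), -1.0, 1.7)])
    grid = solve_lpbe(st, ca, n=33, box=32.0, eps_in=80.0, eps_out=80.0,
                      ion_exclusion=False)
    pts = np.random.default_rng(2).uniform(-10, 10, size=(50, 3))
    mirrored = pts * np.array([-1.0, 1.0, 1.0])
    va = grid.interpolate(pts)
    vb = grid.interpolate(mirrored)
    assert np.allclose(va, -vb, atol=5e-3 * np.abs(va).max() + 1e-9)


def test_surface_all_white_on_zero_field():
    st = build_peptide("AAA", [(-57.0, -47.0)] * 3)
    ca = assign_charges(st, charge_termini=False)
    grid = solve_lpbe(st, ca, n=17)
    assert np.all(grid.values == 0.0)
    pts = surface_potential(grid, st, ca)
    assert pts and all(p.klass == "white" for p in pts)


def test_buried_positive_charge_never_red():
    st, ca = _point_charges([((0.0, 0.0, 0.0), 1.0, 2.0)])
    grid = solve_lpbe(st, ca, n=33, box=24.0)
    pts = surface_potential(grid, st, ca)
    assert pts and all(p.klass in ("blue", "white") for p in pts)


def test_cationic_patch_blue_asymmetry():
    """Strand with three Lys on one face: the Lys-side hemisphere must show
    a larger above-threshold (blue) surface fraction than the far side."""
    st = build_peptide("KAKAK", [(-120.0, 130.0)] * 5)
    ca = assign_charges(st, charge_termini=False)
    assert ca.total_charge == pytest.approx(3.0)
    grid = solve_lpbe(st, ca, n=49)
    pts = surface_potential(grid, st, ca)
    coords = np.array([a.coord for a in st.atoms()])
    centre = coords.mean(axis=0)
    nz = np.array([r.atom("NZ").coord for r in st.residues()
                   if r.type == "LYS"])
    side = nz.mean(axis=0) - centre
    side /= np.linalg.norm(side)

    def blue_fraction(points):
        if not points:
            return 0.0
        return sum(p.klass == "blue" for p in points) / len(points)

    near = [p for p in pts if np.dot(p.coord - centre, side) > 0]
    far = [p for p in pts if np.dot(p.coord - centre, side) < 0]
    assert blue_fraction(near) > blue_fraction(far)


def test_equipotential_masks():
    st, ca = _point_charges([((0.0, 0.0, 0.0), 1.0, 1.7)])
    grid = solve_lpbe(st, ca, n=33, box=24.0)
    pos, neg = equipotential_mask(grid, 50.0)
    assert not neg.any()
    # the +50 mV mask is a blob containing the node nearest the charge
    centre_idx = tuple(np.round((np.zeros(3) - grid.origin)
                                / grid.spacing).astype(int))
    assert pos[centre_idx]
    pos_hi, _ = equipotential_mask(grid, 120.0)
    assert pos_hi.sum() <= pos.sum()
    with pytest.raises(ValueError):
        equipotential_mask(grid, -10.0)
    zero_grid = solve_lpbe(*_point_charges([((0.0, 0.0, 0.0), 0.0, 1.7)]),
                           n=17, box=20.0)
    p0, n0 = equipotential_mask(zero_grid, 50.0)
    assert not p0.any() and not n0.any()


def test_grid_refinement_consistency():
    st, ca = _point_charges([((0.0, 0.0, 0.0), 1.0, 1.9),
                             ((4.0, 0.0, 0.0), -1.0, 1.9),
                             ((0.0, 4.0, 0.0), 1.0, 1.9)])
    g65 = solve_lpbe(st, ca, n=65, box=40.0)
    g97 = solve_lpbe(st, ca, n=97, box=40.0)
    # sample one solvent-side shell per atom, clear of the staircased
    # dielectric interface where pointwise convergence is not expected
    rng = np.random.default_rng(3)
    dirs = rng.normal(size=(30, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    pts = np.concatenate([c + 4.5 * dirs for c in ca.coords])
    keep = [i for i, p in enumerate(pts)
            if np.linalg.norm(p - ca.coords, axis=1).min() >= 4.4]
    pts = pts[keep]
    v65 = g65.interpolate(pts)
    v97 = g97.interpolate(pts)
    denom = np.abs(v97).max()
    assert np.all(np.abs(v65 - v97) / denom < 0.10)


def test_grid_contracts():
    st, ca = _point_charges([((0.0, 0.0, 0.0), 1.0, 1.7)])
    with pytest.raises(ValueError, match="odd"):
        solve_lpbe(st, ca, n=64)
    with pytest.raises(ValueError, match="exceeds"):
        solve_lpbe(st, ca, box=4.0)
    dx = grid_to_opendx(solve_lpbe(st, ca, n=17, box=20.0))
    assert "gridpositions counts 17 17 17" in dx
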