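import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from contactfes.errors import (
    DegenerateFitError,
    FormatError,
    ResidueLookupError,
    SelectionError,
)
from contactfes.structio import (
    Atom,
    Structure,
    Trajectory,
    min_residue_distance,
    read_structure,
    read_trajectory,
    rmsd_series,
    select_atoms,
    superpose,
    write_structure,
    write_trajectory,
)
from contactfes.synthetic import make_crystal_fixture, make_toy_chain

PDB_3ATOMS = """\
ATOM      1  CA  ALA A   1      11.104  13.207   2.100  1.00 10.00           C
ATOM      2  CB  ALA A   1      12.560  13.207   2.100  1.00 12.50           C
ATOM      3  CA  GLY A   2      14.800  10.000   0.000  1.00  0.00           C
END
"""


def test_read_preserves_file_order_and_fields(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(PDB_3ATOMS)
    s = read_structure(p)
    assert [a.name for a in s.atoms] == ["CA", "CB", "CA"]
    assert s.atoms[0].residue_number == 1 and s.atoms[2].residue_number == 2
    assert np.allclose(s.atoms[0].position, [11.104, 13.207, 2.100])
    assert s.atoms[1].b_factor == 12.5
    assert s.cell is None


def test_read_empty_file_is_a_format_error(tmp_path):
    p = tmp_path / "empty.pdb"
    p.write_text("")
    with pytest.raises(FormatError):
        read_structure(p)


def test_read_bad_atom_line_names_line_number(tmp_path):
    p = tmp_path / "bad.pdb"
    p.write_text("ATOM      1  CA  ALA A   1      xxx.xxx  13.2    2.1\n")
    with pytest.raises(FormatError, match="line 1"):
        read_structure(p)


def test_model_index_out_of_range(tmp_path):
    p = tmp_path / "one.pdb"
    p.write_text(PDB_3ATOMS)
    with pytest.raises(IndexError):
        read_structure(p, model_index=3)


def test_cryst1_and_smtry_parsed_and_cross_checked_with_gemmi(tmp_path):
    gemmi = pytest.importorskip("gemmi")
    st, _ = make_crystal_fixture(asu_size=5, spacegroup="P212121", seed=0)
    p = tmp_path / "fix.pdb"
    write_structure(st, p)
    s2 = read_structure(p)
    assert s2.cell is not None and len(s2.symmetry_ops) == 4
    for o1, o2 in zip(st.symmetry_ops, s2.symmetry_ops):
        assert np.allclose(o1.rot, o2.rot, atol=1e-6)
        assert np.allclose(o1.trans, o2.trans, atol=1e-5)
    g = gemmi.read_structure(str(p))
    gatoms = [a for m in g for ch in m for r in ch for a in r]
    assert len(gatoms) == len(s2.atoms)
    for ga, a in zip(gatoms, s2.atoms):
        assert ga.name == a.name
        assert abs(ga.pos.x - a.position[0]) < 1e-6
    assert abs(g.cell.a - s2.cell[0]) < 1e-3


def test_roundtrip_is_byte_stable_for_atom_records(tmp_path):
    chain = make_toy_chain(8, seed=1)
    p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
    write_structure(chain, p1)
    write_structure(read_structure(p1), p2)
    atoms1 = [l for l in p1.read_text().splitlines() if l.startswith("ATOM")]
    atoms2 = [l for l in p2.read_text().splitlines() if l.startswith("ATOM")]
    assert atoms1 == atoms2
    s2 = read_structure(p2)
    assert np.abs(s2.coords - chain.coords).max() < 1e-3


def test_sixteen_chain_supercell_roundtrips_chain_ids(tmp_path):
    from contactfes.crystal import build_supercell
    st, _ = make_crystal_fixture(asu_size=5, spacegroup="P212121", seed=0)
    sc = build_supercell(st, st.symmetry_ops, 2, 2, 1)
    p = tmp_path / "supercell.pdb"
    write_structure(sc, p)
    back = read_structure(p)
    assert len({a.chain_id for a in back.atoms}) == 16


def test_write_rejects_unrepresentable_coordinates(tmp_path):
    a = Atom(1, "CA", "ALA", 1, "A", np.array([12000.0, 0.0, 0.0]))
    with pytest.raises(ValueError, match="10000"):
        write_structure(Structure([a]), tmp_path / "x.pdb")


def test_trajectory_roundtrip_multi_model(tmp_path):
    chain = make_toy_chain(6, seed=2)
    frames = [chain.coords + k * 0.5 for k in range(3)]
    traj = Trajectory(chain, frames, np.array([0.0, 10.0, 20.0]))
    p = tmp_path / "traj.pdb"
    write_trajectory(traj, p)
    back = read_trajectory(p, dt=10.0)
    assert len(back) == 3
    for f1, f2 in zip(traj.frames, back.frames):
        assert np.abs(f1 - f2).max() < 1e-3


class TestSelection:
    def test_ca_count_matches_residues(self):
        chain = make_toy_chain(10, seed=0)
        assert len(select_atoms(chain, "name CA")) == 10

    def test_cv_eligible_selector(self):
        chain = make_toy_chain(10, seed=0)
        idx = select_atoms(chain, "name CA CB O")
        assert {chain.atoms[i].name for i in idx} == {"CA", "CB", "O"}
        assert len(idx) == len(chain)  # the coarse chain has only these atoms

    def test_empty_match_is_not_an_error(self, toy_chain):
        assert len(select_atoms(toy_chain, "name ZZ")) == 0

    def test_residue_ranges_and_combinators(self, toy_chain):
        idx = select_atoms(toy_chain, "name CA and resid 2-4 6")
        nums = sorted(toy_chain.atoms[i].residue_number for i in idx)
        assert nums == [2, 3, 4, 6]
        idx2 = select_atoms(toy_chain, "calpha and not resid 1-9")
        assert [toy_chain.atoms[i].residue_number for i in idx2] == [10]

    def test_backbone_keyword(self, toy_chain):
        idx = select_atoms(toy_chain, "backbone")
        assert {toy_chain.atoms[i].name for i in idx} == {"CA", "O"}

    @pytest.mark.parametrize("bad", ["", "name", "resid x", "frobnicate CA"])
    def test_malformed_selector_raises(self, toy_chain, bad):
        with pytest.raises(SelectionError):
            select_atoms(toy_chain, bad)


def _oracle_rmsd(mobile, reference):
    """Independent superposition oracle: direct minimization over rotation
    vectors from several starts (no Kabsch)."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def cost(rv):
        r = Rotation.from_rotvec(rv).as_matrix()
        return np.mean(np.sum((mob @ r.T - ref) ** 2, axis=1))

    best = np.inf
    for start in ([0, 0, 0], [1, 1, 1], [-2, 1, 0], [0.5, -1.5, 2.5],
                  [3, 0, 0], [0, 3, 0], [0, 0, 3]):
        res = minimize(cost, np.array(start, float), method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-16,
                                "maxiter": 20000})
        best = min(best, res.fun)
    return np.sqrt(best)


class TestSuperpose:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(5, 3))
        rot, trans, rmsd = superpose(pts, pts)
        assert rmsd < 1e-12
        assert np.allclose(rot, np.eye(3), atol=1e-9)

    def test_rigid_rotation_recovers_zero_rmsd(self):
        pts = np.random.default_rng(1).normal(size=(6, 3))
        rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        _, _, rmsd = superpose(pts @ rz.T + [1.0, -2.0, 3.0], pts)
        assert rmsd < 1e-9

    def test_proper_rotation_determinant(self):
        rng = np.random.default_rng(2)
        mob = rng.normal(size=(4, 3))
        ref = rng.normal(size=(4, 3))
        rot, _, _ = superpose(mob, ref)
        assert np.isclose(np.linalg.det(rot), 1.0, atol=1e-9)

    def test_matches_independent_minimization_oracle(self):
        ref = np.array([[0.0, 0, 0], [3, 0, 0], [0, 4, 0], [1, 1, 3]])
        mob = ref.copy()
        mob[3] += [0.7, -0.4, 0.9]
        rot = Rotation.from_euler("xyz", [20, -40, 65], degrees=True).as_matrix()
        mob = mob @ rot.T + [5.0, 6.0, -7.0]
        _, _, rmsd = superpose(mob, ref)
        assert abs(rmsd - _oracle_rmsd(mob, ref)) < 1e-6

    def test_rmsd_invariant_under_rigid_transform_of_mobile(self, rng):
        ref = rng.normal(size=(7, 3))
        mob = ref + 0.3 * rng.normal(size=(7, 3))
        _, _, r1 = superpose(mob, ref)
        extra = Rotation.from_rotvec([0.3, -1.0, 2.2]).as_matrix()
        _, _, r2 = superpose(mob @ extra.T + [10, 20, 30], ref)
        assert abs(r1 - r2) < 1e-6

    def test_degenerate_inputs(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateFitError):
            superpose(line, line)
        with pytest.raises(DegenerateFitError):
            superpose(line[:2], line[:2])


class TestRmsdSeries:
    def test_copies_of_reference_give_zeros(self, toy_chain):
        traj = Trajectory(toy_chain, [toy_chain.coords.copy() for _ in range(3)])
        out = rmsd_series(traj, toy_chain, range(len(toy_chain)))
        assert np.all(out < 1e-12)

    def test_excluding_displaced_tail_lowers_rmsd(self, toy_chain):
        coords = toy_chain.coords.copy()
        tail = [i for i, a in enumerate(toy_chain.atoms) if a.residue_number > 8]
        core = [i for i in range(len(toy_chain)) if i not in tail]
        coords[tail] += 5.0
        traj = Trajectory(toy_chain, [coords])
        full = rmsd_series(traj, toy_chain, core, range(len(toy_chain)))
        no_tail = rmsd_series(traj, toy_chain, core, core)
        assert no_tail[0] < full[0]

    def test_composition_matches_per_frame_superpose(self, toy_chain, rng):
        frames = [toy_chain.coords + 0.5 * rng.normal(size=toy_chain.coords.shape)
                  for _ in range(2)]
        traj = Trajectory(toy_chain, frames)
        fit = np.arange(len(toy_chain))
        series = rmsd_series(traj, toy_chain, fit)
        for k, f in enumerate(frames):
            _, _, r = superpose(f, toy_chain.coords, fit)
            assert abs(series[k] - r) < 1e-12


class TestMinResidueDistance:
    def test_single_atom_residues(self):
        atoms = [Atom(1, "CB", "ALA", 1, "A", np.zeros(3)),
                 Atom(2, "CB", "ALA", 2, "A", np.array([5.0, 0, 0]))]
        s = Structure(atoms)
        assert min_residue_distance(s, ("A", 1), ("A", 2)) == pytest.approx(5.0)

    def test_matches_brute_force_and_is_symmetric(self, toy_chain):
        d_ab = min_residue_distance(toy_chain, ("A", 2), ("A", 7))
        ia = toy_chain.residue_atom_indices("A", 2)
        ib = toy_chain.residue_atom_indices("A", 7)
        brute = min(np.linalg.norm(toy_chain.coords[i] - toy_chain.coords[j])
                    for i in ia for j in ib)
        assert d_ab == pytest.approx(brute, abs=1e-12)
        assert d_ab == pytest.approx(
            min_residue_distance(toy_chain, ("A", 7), ("A", 2)))

    def test_self_distance_zero_and_missing_residue(self, toy_chain):
        assert min_residue_distance(toy_chain, ("A", 3), ("A", 3)) == 0.0
        with pytest.raises(ResidueLookupError):
            min_residue_distance(toy_chain, ("A", 3), ("B", 99))
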