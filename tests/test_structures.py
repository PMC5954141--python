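"""Structure I/O, SASA, contacts, dihedrals, rotamer comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chemibody.structures import (
    Atom,
    Residue,
    Structure,
    compare_rotamer,
    compute_sasa,
    contact_map,
    dihedral_angle,
    read_structure,
    virtual_cbeta,
    write_pdb,
)

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
END
"""


def _atom(name, element, pos):
    return Atom(name=name, element=element, pos=np.asarray(pos, dtype=float))


def _single_atom_structure(element="C", pos=(0.0, 0.0, 0.0), name="C1"):
    return Structure(
        chains={"A": [Residue(name="UNK", seqid=1, atoms=[_atom(name, element, pos)])]}
    )


class TestIO:
    def test_minimal_pdb(self, tmp_path):
        p = tmp_path / "min.pdb"
        p.write_text(MINIMAL_PDB)
        s = read_structure(p)
        assert list(s.chains) == ["A"]
        assert len(s.chains["A"]) == 1
        assert len(s.chains["A"][0].atoms) == 3
        np.testing.assert_allclose(s.chains["A"][0].atom("CA").pos, [1.458, 0, 0])

    def test_round_trip_coordinates(self, toy_complex, tmp_path):
        s, _ = toy_complex
        p = tmp_path / "again.pdb"
        write_pdb(s, p)
        s2 = read_structure(p)
        for (c1, r1, a1), (c2, r2, a2) in zip(s.all_atoms(), s2.all_atoms()):
            assert (c1, r1.key, a1.name) == (c2, r2.key, a2.name)
            np.testing.assert_allclose(a1.pos, a2.pos, atol=1e-3)

    def test_mmcif_reading(self, toy_complex, tmp_path):
        import gemmi

        s, _ = toy_complex
        pdb = tmp_path / "c.pdb"
        write_pdb(s, pdb)
        st = gemmi.read_structure(str(pdb))
        st.setup_entities()
        cif = tmp_path / "c.cif"
        st.make_mmcif_document().write_file(str(cif))
        s2 = read_structure(cif)
        assert sum(len(rs) for rs in s2.chains.values()) == sum(
            len(rs) for rs in s.chains.values()
        )

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "nope.pdb")

    def test_unreadable_file(self, tmp_path):
        p = tmp_path / "bad.cif"
        p.write_text("this is not a structure file")
        with pytest.raises(ValueError):
            read_structure(p, fmt="mmcif")

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="unknown element"):
            _atom("X1", "Xx", (0, 0, 0))

    def test_altloc_highest_occupancy(self, tmp_path):
        pdb = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.30  0.00           C\n"
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.70  0.00           C\n"
            "END\n"
        )
        p = tmp_path / "alt.pdb"
        p.write_text(pdb)
        s = read_structure(p)
        res = s.chains["A"][0]
        assert len(res.atoms) == 1
        np.testing.assert_allclose(res.atom("CA").pos, [5.0, 0, 0])

    def test_duplicate_residue_ids_rejected(self):
        r1 = Residue(name="ALA", seqid=1, atoms=[_atom("CA", "C", (0, 0, 0))])
        r2 = Residue(name="GLY", seqid=1, atoms=[_atom("CA", "C", (5, 0, 0))])
        with pytest.raises(ValueError, match="duplicate"):
            Structure(chains={"A": [r1, r2]})


def _mc_sasa_oracle(centers, radii, probe, atom_idx, n=200_000, seed=7):
    """Monte-Carlo surface integration: fraction of random points on the
    expanded sphere of atom_idx not inside any other expanded sphere."""
    rng = np.random.default_rng(seed)
    r = radii[atom_idx] + probe
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts = centers[atom_idx] + r * pts
    free = np.ones(n, dtype=bool)
    for j, (c, rj) in enumerate(zip(centers, radii)):
        if j == atom_idx:
            continue
        free &= np.linalg.norm(pts - c, axis=1) >= rj + probe
    return 4.0 * np.pi * r * r * free.mean()


class TestSASA:
    def test_isolated_carbon_closed_form(self):
        s = _single_atom_structure("C")
        res = compute_sasa(s, probe=1.4, points=960)
        expected = 4.0 * np.pi * (1.7 + 1.4) ** 2  # ≈ 120.76 Å²
        assert res.atom_area("A", 1, "C1") == pytest.approx(expected, rel=1e-6)

    def test_distant_atoms_unoccluded(self):
        far = 2 * (1.7 + 1.4) + 1.0
        s = Structure(
            chains={
                "A": [
                    Residue(name="UNK", seqid=1, atoms=[_atom("C1", "C", (0, 0, 0))]),
                    Residue(name="UNK", seqid=2, atoms=[_atom("C1", "C", (far, 0, 0))]),
                ]
            }
        )
        res = compute_sasa(s)
        expected = 4.0 * np.pi * 3.1**2
        assert res.atom_area("A", 1, "C1") == pytest.approx(expected, rel=1e-6)
        assert res.atom_area("A", 2, "C1") == pytest.approx(expected, rel=1e-6)

    def test_overlapping_pair_matches_monte_carlo(self):
        centers = np.array([[0.0, 0.0, 0.0], [2.5, 0.0, 0.0]])
        radii = np.array([1.7, 1.55])
        s = Structure(
            chains={
                "A": [
                    Residue(name="UNK", seqid=1, atoms=[_atom("C1", "C", centers[0])]),
                    Residue(name="UNK", seqid=2, atoms=[_atom("N1", "N", centers[1])]),
                ]
            }
        )
        res = compute_sasa(s, points=960)
        for i, (resnum, nm) in enumerate([(1, "C1"), (2, "N1")]):
            oracle = _mc_sasa_oracle(centers, radii, 1.4, i)
            assert res.atom_area("A", resnum, nm) == pytest.approx(oracle, rel=0.01)

    def test_residue_area_is_atom_sum(self, toy_complex):
        s, _ = toy_complex
        res = compute_sasa(s)
        by_res = res.per_atom.groupby(["chain", "resnum", "icode"])["area"].sum()
        for row in res.per_residue.itertuples():
            assert by_res[(row.chain, row.resnum, row.icode)] == pytest.approx(
                row.area, abs=1e-9
            )

    def test_occluder_never_increases_area(self):
        base = Structure(
            chains={
                "A": [
                    Residue(name="UNK", seqid=1, atoms=[_atom("C1", "C", (0, 0, 0))]),
                    Residue(name="UNK", seqid=2, atoms=[_atom("C1", "C", (3.0, 0, 0))]),
                ]
            }
        )
        more = Structure(
            chains={
                "A": [
                    Residue(name="UNK", seqid=1, atoms=[_atom("C1", "C", (0, 0, 0))]),
                    Residue(name="UNK", seqid=2, atoms=[_atom("C1", "C", (3.0, 0, 0))]),
                    Residue(name="UNK", seqid=3, atoms=[_atom("C1", "C", (1.5, 2.5, 0))]),
                ]
            }
        )
        a0 = compute_sasa(base)
        a1 = compute_sasa(more)
        for resnum in (1, 2):
            assert a1.atom_area("A", resnum, "C1") <= a0.atom_area("A", resnum, "C1") + 1e-9


class TestContacts:
    def _structure_from_points(self, points_by_res):
        chains = {}
        for (cid, seqid), pts in points_by_res.items():
            atoms = [_atom(f"C{i + 1}", "C", p) for i, p in enumerate(pts)]
            chains.setdefault(cid, []).append(Residue(name="UNK", seqid=seqid, atoms=atoms))
        return Structure(chains=chains)

    def test_far_apart_no_contacts(self):
        s = self._structure_from_points({("A", 1): [(0, 0, 0)], ("B", 1): [(20, 0, 0)]})
        tab = contact_map(s, s.select(chain_ids={"A"}), s.select(chain_ids={"B"}))
        assert tab.contacts("A", 1) == 0

    def test_planted_pairs_counted(self):
        a_pts = [(0, 0, 0), (2.0, 0, 0)]
        b_pts = [(0, 3.5, 0), (2.0, 3.5, 0), (50, 0, 0)]
        s = self._structure_from_points({("A", 1): a_pts, ("B", 1): b_pts})
        tab = contact_map(s, s.select(chain_ids={"A"}), s.select(chain_ids={"B"}), cutoff=4.5)
        # exhaustive: pairs within 4.5 = (a1,b1),(a1,b2),(a2,b1),(a2,b2)
        assert tab.contacts("A", 1) == 4
        assert tab.table["min_distance"].iloc[0] == pytest.approx(3.5)

    def test_brute_force_equivalence_random(self, rng):
        pts_a = rng.uniform(0, 25, size=(250, 3))
        pts_b = rng.uniform(0, 25, size=(250, 3))
        points = {("A", i + 1): [p] for i, p in enumerate(pts_a)}
        points.update({("B", i + 1): [p] for i, p in enumerate(pts_b)})
        s = self._structure_from_points(points)
        tab = contact_map(s, s.select(chain_ids={"A"}), s.select(chain_ids={"B"}), cutoff=4.5)
        d = np.linalg.norm(pts_a[:, None, :] - pts_b[None, :, :], axis=2)
        brute = (d <= 4.5).sum(axis=1)
        got = tab.table.sort_values("resnum")["n_contacts"].to_numpy()
        np.testing.assert_array_equal(got, brute)

    def test_swap_preserves_total(self, rng):
        pts_a = rng.uniform(0, 12, size=(40, 3))
        pts_b = rng.uniform(0, 12, size=(40, 3))
        points = {("A", i + 1): [p] for i, p in enumerate(pts_a)}
        points.update({("B", i + 1): [p] for i, p in enumerate(pts_b)})
        s = self._structure_from_points(points)
        ab = contact_map(s, s.select(chain_ids={"A"}), s.select(chain_ids={"B"}))
        ba = contact_map(s, s.select(chain_ids={"B"}), s.select(chain_ids={"A"}))
        assert ab.table["n_contacts"].sum() == ba.table["n_contacts"].sum()

    def test_empty_selection_rejected(self):
        s = self._structure_from_points({("A", 1): [(0, 0, 0)], ("B", 1): [(9, 0, 0)]})
        with pytest.raises(ValueError):
            contact_map(s, [], s.select(chain_ids={"B"}))


def _dihedral_oracle(p1, p2, p3, p4):
    """Independent torsion formula via plane normals and a sign from the
    scalar triple product."""
    p1, p2, p3, p4 = map(np.asarray, (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = n1 @ n2 / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    if np.cross(n2, n1) @ b2 < 0:
        ang = -ang
    return ang


class TestDihedral:
    @pytest.mark.parametrize(
        "pts,expected",
        [
            ([(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)], 0.0),  # cis
            ([(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)], 180.0),  # trans
            ([(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 0, 1)], -90.0),
        ],
    )
    def test_convention(self, pts, expected):
        assert dihedral_angle(*pts) == pytest.approx(expected, abs=1e-9)

    @given(
        st.lists(
            st.tuples(*[st.floats(-10, 10) for _ in range(3)]), min_size=4, max_size=4
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_reversal_mirror_and_oracle(self, pts):
        """IUPAC torsions are invariant under point-order reversal and
        negate under mirror reflection."""
        p1, p2, p3, p4 = (np.array(p) for p in pts)
        try:
            fwd = dihedral_angle(p1, p2, p3, p4)
        except ValueError:
            return  # degenerate geometry is rejected, nothing to compare
        rev = dihedral_angle(p4, p3, p2, p1)
        assert abs(((fwd - rev + 180.0) % 360.0) - 180.0) == pytest.approx(0.0, abs=1e-6)
        flip = np.diag([1.0, 1.0, -1.0])
        mirrored = dihedral_angle(flip @ p1, flip @ p2, flip @ p3, flip @ p4)
        assert abs(((fwd + mirrored + 180.0) % 360.0) - 180.0) == pytest.approx(
            0.0, abs=1e-6
        )
        oracle = _dihedral_oracle(p1, p2, p3, p4)
        assert abs(((fwd - oracle + 180.0) % 360.0) - 180.0) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            dihedral_angle((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


def _cys_residue(chi1_extra=0.0):
    n = np.array([-1.458, 0.0, 0.0])
    ca = np.zeros(3)
    c = np.array([0.551, 1.420, 0.0])
    o = np.array([1.651, 1.950, 0.0])
    cb = virtual_cbeta(n, ca, c)
    # SG placed 1.81 Å from CB, rotated about the CA-CB axis
    axis = cb / np.linalg.norm(cb)
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    perp /= np.linalg.norm(perp)
    ang = np.radians(chi1_extra)
    rot = (
        np.cos(ang) * perp + np.sin(ang) * np.cross(axis, perp)
    )
    sg = cb + 1.81 * (0.5 * axis + 0.866 * rot) / np.linalg.norm(0.5 * axis + 0.866 * rot)
    atoms = [
        _atom("N", "N", n),
        _atom("CA", "C", ca),
        _atom("C", "C", c),
        _atom("O", "O", o),
        _atom("CB", "C", cb),
        _atom("SG", "S", sg),
    ]
    return Residue(name="CYS", seqid=30, atoms=atoms)


class TestRotamer:
    def test_self_comparison(self):
        r = _cys_residue()
        d = compare_rotamer(r, r)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in d.deltas.values())
        assert d.same_rotamer

    def test_chi1_rotation_detected(self):
        a = _cys_residue(0.0)
        b = _cys_residue(120.0)
        d = compare_rotamer(a, b)
        assert d.deltas["chi1"] == pytest.approx(120.0, abs=1.0)
        assert not d.same_rotamer
        assert d.deltas["ca_cb"] == pytest.approx(0.0, abs=1e-6)

    def test_glycine_surrogate_cbeta(self):
        gly_atoms = [
            _atom("N", "N", (-1.458, 0, 0)),
            _atom("CA", "C", (0, 0, 0)),
            _atom("C", "C", (0.551, 1.420, 0)),
        ]
        g = Residue(name="GLY", seqid=67, atoms=gly_atoms)
        d = compare_rotamer(g, g)
        assert d.same_rotamer

    def test_missing_atoms_reported(self):
        bad = Residue(name="ALA", seqid=1, atoms=[_atom("CA", "C", (0, 0, 0))])
        with pytest.raises(ValueError, match="missing backbone"):
            compare_rotamer(bad, bad)
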