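"""Structure metrics on synthetic fixtures: a hand-built model with a
tetrahedral Zn site (3 His + water), an octahedral Ca site with a bidentate
aspartate, one disulfide, and a small structure-factor mmCIF.

All fixtures are synthetic constructions written at test time; no deposited
data is required.
"""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ssxmerge.simulate import make_ideal_site
from ssxmerge.structure import (
    POLYHEDRA,
    _best_fit_to_template,
    atom_census,
    classify_geometry,
    count_deposited_reflections,
    find_coordination,
    find_disulfides,
    read_structure,
)
from ssxmerge.symmetry import UnitCell, generate_complete_set, space_group


def _pdb_line(serial, name, resname, chain, resseq, xyz, element,
              occ=1.0, altloc=" ", record="ATOM"):
    name_f = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    x, y, z = xyz
    return (
        f"{record:<6s}{serial:5d} {name_f}{altloc}{resname:>3s} {chain}"
        f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f} 20.00"
        f"          {element:>2s}"
    )


@pytest.fixture(scope="module")
def model_path(tmp_path_factory):
    """Synthetic test model emulating an intramembrane Zn enzyme's sites."""
    lines = []
    n = 0

    def add(name, resname, chain, resseq, xyz, element, record="ATOM", **kw):
        nonlocal n
        n += 1
        lines.append(_pdb_line(n, name, resname, chain, resseq, xyz,
                               element, record=record, **kw))

    # Zn site at origin: tetrahedral, 3 His NE2 + 1 water O at 2.1 A
    zn_site = make_ideal_site("tetrahedral", 2.1)
    his_seqs = (81, 217, 221)
    for seq, xyz in zip(his_seqs, zn_site.ligands[:3]):
        add("NE2", "HIS", "A", seq, xyz, "N")
        # backbone atoms far away from both metals
        add("CA", "HIS", "A", seq, np.asarray(xyz) * 4 + 40.0, "C")
    add("ZN", "ZN", "A", 301, (0.0, 0.0, 0.0), "ZN", record="HETATM")
    add("O", "HOH", "A", 401, zn_site.ligands[3], "O", record="HETATM")

    # Ca site at (20, 0, 0): octahedral, 6 O at 2.4 A, Asp19 bidentate
    ca_center = np.array([20.0, 0.0, 0.0])
    ca_site = make_ideal_site("octahedral", 2.4, center=ca_center)
    o_atoms = [
        ("OD1", "ASP", 19), ("OD2", "ASP", 19), ("O", "TRP", 20),
        ("O", "GLU", 22), ("OD1", "ASN", 24), ("OE1", "GLU", 33),
    ]
    for (name, resname, seq), xyz in zip(o_atoms, ca_site.ligands):
        add(name, resname, "A", seq, xyz, "O")
    add("CA", "CA", "A", 302, ca_center, "CA", record="HETATM")

    # disulfide between Cys21 and Cys196 (SG-SG 2.05 A), far from metals
    add("SG", "CYS", "A", 21, (40.0, 0.0, 0.0), "S")
    add("SG", "CYS", "A", 196, (42.05, 0.0, 0.0), "S")
    # free cysteine, not bonded
    add("SG", "CYS", "A", 250, (60.0, 0.0, 0.0), "S")
    add("O", "HOH", "A", 402, (70.0, 0.0, 0.0), "O", record="HETATM")
    # one mono-olein-like ligand fragment (3 atoms, "other" bucket)
    for i, name in enumerate(("C1", "C2", "O1")):
        add(name, "OLC", "A", 501, (80.0 + i, 0.0, 0.0),
            "O" if name == "O1" else "C", record="HETATM")

    p = tmp_path_factory.mktemp("model") / "synthetic_sites.pdb"
    p.write_text("\n".join(lines) + "\nEND\n")
    return p


@pytest.fixture(scope="module")
def model(model_path):
    return read_structure(model_path)


class TestReadStructure:
    def test_three_atom_fixture_exact_coordinates(self, tmp_path):
        lines = [
            _pdb_line(1, "N", "GLY", "A", 1, (1.0, 2.0, 3.0), "N"),
            _pdb_line(2, "CA", "GLY", "A", 1, (2.5, 3.5, 4.5), "C"),
            _pdb_line(3, "C", "GLY", "A", 1, (-1.0, 0.0, 9.25), "C"),
        ]
        p = tmp_path / "tiny.pdb"
        p.write_text("\n".join(lines) + "\nEND\n")
        st = read_structure(p)
        assert len(st) == 3
        np.testing.assert_allclose(
            st.atoms[["x", "y", "z"]].to_numpy()[0], [1.0, 2.0, 3.0]
        )

    def test_altloc_resolved_by_highest_occupancy(self, tmp_path):
        lines = [
            _pdb_line(1, "CB", "SER", "A", 5, (0, 0, 0), "C", occ=0.4, altloc="A"),
            _pdb_line(2, "CB", "SER", "A", 5, (5, 5, 5), "C", occ=0.6, altloc="B"),
        ]
        p = tmp_path / "alt.pdb"
        p.write_text("\n".join(lines) + "\nEND\n")
        st = read_structure(p)
        assert len(st) == 1
        assert st.atoms.iloc[0]["x"] == pytest.approx(5.0)

    def test_mmcif_round_trip_via_gemmi(self, model_path, tmp_path):
        import gemmi
        st = gemmi.read_structure(str(model_path))
        st.setup_entities()
        cif_path = tmp_path / "model.cif"
        st.make_mmcif_document().write_file(str(cif_path))
        a = read_structure(model_path)
        b = read_structure(cif_path)
        assert len(a) == len(b)
        np.testing.assert_allclose(
            np.sort(a.atoms["x"].to_numpy()), np.sort(b.atoms["x"].to_numpy()),
            atol=1e-3,
        )


class TestCoordination:
    def test_zn_sphere_three_his_nitrogens_plus_water(self, model):
        site = find_coordination(model, "ZN", cutoffs={"ZN": 2.6})
        assert site.n_ligands == 4
        elements = sorted(l.element for l in site.ligands)
        assert elements == ["N", "N", "N", "O"]
        his = {l.res_seq for l in site.ligands if l.res_name == "HIS"}
        assert his == {81, 217, 221}
        assert {l.res_name for l in site.ligands if l.element == "O"} == {"HOH"}

    def test_ca_sphere_six_oxygens_with_bidentate_asp(self, model):
        site = find_coordination(model, "CA", cutoffs={"CA": 3.0})
        assert site.n_ligands == 6
        assert all(l.element == "O" for l in site.ligands)
        assert site.multidentate_residues() == [("ASP", 19, 2)]

    def test_ligands_sorted_and_cutoff_monotone(self, model):
        small = find_coordination(model, "CA", cutoffs={"CA": 2.5})
        large = find_coordination(model, "CA", cutoffs={"CA": 3.5})
        dists = [l.distance for l in large.ligands]
        assert dists == sorted(dists)
        small_set = {(l.res_seq, l.name) for l in small.ligands}
        large_set = {(l.res_seq, l.name) for l in large.ligands}
        assert small_set <= large_set

    def test_missing_center_errors(self, model):
        with pytest.raises(ValueError, match="no MG centre"):
            find_coordination(model, "MG")


class TestClassifyGeometry:
    def test_ideal_shapes_classified_exactly(self):
        for label in POLYHEDRA:
            site = make_ideal_site(label, 2.4)
            got, rmsd = classify_geometry(site.ligands, center=site.center)
            assert got == label
            assert rmsd == pytest.approx(0.0, abs=1e-6)

    def test_synthetic_octahedral_ca_site(self, model):
        site = find_coordination(model, "CA", cutoffs={"CA": 3.0})
        label, rmsd = classify_geometry(site)
        assert label == "octahedral"
        assert rmsd < 1e-6

    def test_incomplete_pentagonal_bipyramid_beats_octahedron(self):
        site = make_ideal_site("pentagonal_bipyramid", 2.4, drop_vertices=1)
        label, rmsd = classify_geometry(site.ligands, center=site.center)
        assert label == "incomplete pentagonal_bipyramid"
        unit = (site.ligands - site.center) / 2.4
        oct_rmsd = _best_fit_to_template(unit, POLYHEDRA["octahedral"])
        assert rmsd < oct_rmsd - 5.0

    def test_jittered_tetrahedron_still_recognised(self):
        for seed in range(5):
            site = make_ideal_site("tetrahedral", 2.4, jitter_sd=0.05, seed=seed)
            label, rmsd = classify_geometry(site.ligands, center=site.center)
            assert label == "tetrahedral"
            assert rmsd < 5.0

    def test_rotation_invariance(self):
        site = make_ideal_site("octahedral", 2.4, jitter_sd=0.05, seed=1)
        _, r0 = classify_geometry(site.ligands, center=site.center)
        rng = np.random.default_rng(0)
        for _ in range(25):
            R = Rotation.random(rng=rng).as_matrix()
            _, r1 = classify_geometry(site.ligands @ R.T, center=site.center)
            assert abs(r1 - r0) < 1e-6

    def test_too_few_ligands_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            classify_geometry(np.eye(3)[:2] * 2.4, center=np.zeros(3))


class TestDisulfides:
    def test_single_pair_detected_once(self, model):
        pairs = find_disulfides(model)
        assert len(pairs) == 1
        (c1, r1), (c2, r2), dist = pairs[0]
        assert {r1, r2} == {21, 196}
        assert dist == pytest.approx(2.05, abs=1e-3)

    def test_distant_cysteines_excluded(self, model):
        seqs = {r for pair in find_disulfides(model) for _, r in pair[:2]}
        assert 250 not in seqs

    def test_cutoff_is_respected(self, model):
        assert find_disulfides(model, s_s_cutoff=1.5) == []


class TestCensus:
    def test_categories_and_conservation(self, model):
        census = atom_census(model)
        # 3x(NE2+CA) + 6 O ligands + 3 SG = 15 protein atoms
        assert census.protein == 15
        assert census.water == 2
        assert census.metals == {"ZN": 1, "CA": 1}
        assert census.other == {"OLC": 3}
        assert census.total == len(model)

    def test_as_dict_sums(self, model):
        d = atom_census(model).as_dict()
        assert d["total"] == d["protein"] + d["water"] + sum(
            d["metals"].values()) + sum(d["other"].values())


# ---------------------------------------------------------------------------
# Structure factors
# ---------------------------------------------------------------------------

def _sf_cif(cell, sg_name, rows):
    head = f"""data_synthetic_sf
_cell.length_a {cell.a}
_cell.length_b {cell.b}
_cell.length_c {cell.c}
_cell.angle_alpha {cell.alpha}
_cell.angle_beta {cell.beta}
_cell.angle_gamma {cell.gamma}
_symmetry.space_group_name_H-M '{sg_name}'
loop_
_refln.index_h
_refln.index_k
_refln.index_l
_refln.status
_refln.F_meas_au
"""
    return head + "\n".join(rows) + "\n"


class TestDepositedReflections:
    def test_counts_written_reflections(self, tmp_path):
        cell = UnitCell(30, 34, 44)
        rows = [f"{h} {k} {l} o 100.0" for h, k, l in
                [(2, 0, 2), (1, 1, 3), (0, 2, 4), (3, 1, 1)]]
        p = tmp_path / "sf.cif"
        p.write_text(_sf_cif(cell, "C 2 2 21", rows))
        out = count_deposited_reflections(p)
        assert out["n_reflections"] == 4

    def test_complete_set_fixture_has_unit_completeness(self, tmp_path, c2221):
        cell = UnitCell(30, 34, 44)
        full = generate_complete_set(cell, c2221, 4.0)
        rows = [f"{h} {k} {l} o 50.0" for h, k, l in full]
        p = tmp_path / "sf_full.cif"
        p.write_text(_sf_cif(cell, "C 2 2 21", rows))
        out = count_deposited_reflections(p)
        assert out["n_reflections"] == len(full)
        assert out["completeness"] == pytest.approx(1.0)

    def test_status_filter_excludes_free_set(self, tmp_path):
        cell = UnitCell(30, 34, 44)
        rows = ["2 0 2 o 10.0", "1 1 3 f 10.0", "0 2 4 o 10.0"]
        p = tmp_path / "sf.cif"
        p.write_text(_sf_cif(cell, "C 2 2 21", rows))
        assert count_deposited_reflections(p)["n_reflections"] == 2
        assert count_deposited_reflections(
            p, status_filter={"o", "f"})["n_reflections"] == 3

    def test_missing_data_columns_error(self, tmp_path):
        text = """data_x
loop_
_refln.index_h
_refln.index_k
_refln.index_l
1 2 3
"""
        p = tmp_path / "bad.cif"
        p.write_text(text)
        with pytest.raises(ValueError, match="column"):
            count_deposited_reflections(p)
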