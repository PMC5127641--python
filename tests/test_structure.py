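"""Superposition, SASA/BSA, cross-link mapping and docking funnels."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from specprofiler import structure, synth
from specprofiler.structure import (CrossLinkRecord, buried_surface_area,
                                    crosslink_support_summary, funnel_stats,
                                    kabsch_superpose, map_crosslinks,
                                    sasa_from_coords)

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
END
"""


# ---------------------------------------------------------------------------
# parsing


class TestParseStructure:
    def test_minimal_pdb(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(MINIMAL_PDB)
        model = structure.parse_structure(path)
        assert list(model.chains) == ["A"]
        residues = model.residues("A")
        assert len(residues) == 1
        np.testing.assert_allclose(residues[0].ca, [1.458, 0.0, 0.0])

    def test_round_trip_preserves_coordinates(self, tmp_path):
        ref, _, _ = synth.generate_helix_bundle(n_helices=2, residues_per_helix=8,
                                                seed=0)
        path = tmp_path / "bundle.pdb"
        structure.write_pdb(ref, path)
        back = structure.parse_structure(path)
        np.testing.assert_allclose(back.ca_coords("A"), ref.ca_coords("A"),
                                   atol=1e-3)  # PDB stores 3 decimals

    def test_generated_fixture_matches_its_ledger(self):
        ref, _, ledger = synth.generate_helix_bundle(n_helices=3,
                                                     residues_per_helix=10, seed=1)
        n = (ledger.params["n_helices"] * ledger.params["residues_per_helix"])
        residues = ref.residues("A")
        assert len(residues) == n
        assert all(len(r.atoms) == 2 for r in residues)


# ---------------------------------------------------------------------------
# superposition


class TestKabsch:
    def test_self_superposition_is_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 3))
        _, _, rmsd = kabsch_superpose(x, x)
        assert rmsd <= 1e-12

    def test_rigid_motion_is_recovered_exactly(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(12, 3))
        rot_true = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        y = x @ rot_true.T + np.array([5.0, -3.0, 2.0])
        rot, trans, rmsd = kabsch_superpose(x, y)
        assert rmsd <= 1e-8
        assert np.linalg.det(rot) == pytest.approx(1.0)
        np.testing.assert_allclose(rot, rot_true, atol=1e-8)

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_matches_independent_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(4, 3))
        y = x + rng.normal(scale=1.0, size=(4, 3))  # ~1 A planted displacement
        _, _, rmsd = kabsch_superpose(x, y)
        x0 = x - x.mean(axis=0)
        y0 = y - y.mean(axis=0)
        _, rssd = Rotation.align_vectors(y0, x0)
        assert rmsd == pytest.approx(rssd / np.sqrt(len(x)), rel=1e-6)

    def test_rmsd_invariant_under_rigid_motion_of_both_inputs(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(8, 3))
        y = x + rng.normal(scale=0.5, size=(8, 3))
        _, _, base = kabsch_superpose(x, y)
        rot = Rotation.random(random_state=7).as_matrix()
        t = np.array([1.0, 2.0, 3.0])
        _, _, moved = kabsch_superpose(x @ rot.T + t, y @ rot.T + t)
        assert moved == pytest.approx(base, abs=1e-9)
        _, _, one_side = kabsch_superpose(x @ rot.T + t, y)
        assert one_side == pytest.approx(base, abs=1e-9)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line)
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestAlignedPartnerRmsd:
    def make_complex(self, seed=0):
        target, _, _ = synth.generate_helix_bundle(n_helices=2,
                                                   residues_per_helix=12, seed=seed)
        inhibitor, _, _ = synth.generate_helix_bundle(n_helices=1,
                                                      residues_per_helix=10,
                                                      seed=seed + 1)
        shifted = structure.transform_model(inhibitor, np.eye(3),
                                            np.array([12.0, 0.0, 0.0]))
        return structure.StructureModel(chains={"T": target.chains["A"],
                                                "I": shifted.chains["A"]})

    def test_identical_complexes_give_zero(self):
        c = self.make_complex()
        rmsd = structure.aligned_partner_rmsd(c, c, ("T", "T"), ("I", "I"))
        assert rmsd <= 1e-12

    def test_rigidly_moved_copy_gives_zero(self):
        c1 = self.make_complex()
        rot = Rotation.random(random_state=3).as_matrix()
        c2 = structure.transform_model(c1, rot, np.array([4.0, -2.0, 9.0]))
        rmsd = structure.aligned_partner_rmsd(c1, c2, ("T", "T"), ("I", "I"))
        assert rmsd <= 1e-8

    def test_planted_partner_shift_is_measured(self):
        # same target placement, inhibitor translated by a known vector:
        # after target alignment (identity) the partner RMSD is that norm
        c1 = self.make_complex()
        shift = np.array([1.0, 2.0, 2.0])  # |shift| = 3
        c2 = structure.StructureModel(chains={
            "T": c1.chains["T"],
            "I": structure.transform_model(
                structure.StructureModel(chains={"I": c1.chains["I"]}),
                np.eye(3), shift).chains["I"]})
        rmsd = structure.aligned_partner_rmsd(c1, c2, ("T", "T"), ("I", "I"))
        assert rmsd == pytest.approx(3.0, abs=1e-9)

    def test_multi_copy_mean(self):
        c1 = self.make_complex()
        pairs = [(("T", "T"), ("I", "I")), (("T", "T"), ("I", "I"))]
        values, mean = structure.multi_copy_rmsd(c1, c1, pairs)
        assert values == pytest.approx([0.0, 0.0], abs=1e-10)
        assert mean == pytest.approx(0.0, abs=1e-10)


# ---------------------------------------------------------------------------
# surface areas


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        r, probe = 1.7, 1.4
        area = sasa_from_coords(np.zeros((1, 3)), np.array([r]), probe, 960)[0]
        assert area == pytest.approx(4 * np.pi * (r + probe) ** 2, rel=0.01)

    def test_two_overlapping_spheres_spherical_cap(self):
        # solvent radius R = 2 + 1.4 = 3.4; centers 4 A apart; each sphere
        # loses a cap of height h = R - d/2 = 1.4: area 2 pi R h = 29.9 A^2
        coords = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        radii = np.array([2.0, 2.0])
        areas = sasa_from_coords(coords, radii, probe=1.4, n_points=2000)
        big_r = 3.4
        cap = 2 * np.pi * big_r * 1.4
        expected = 4 * np.pi * big_r ** 2 - cap
        assert areas[0] == pytest.approx(expected, rel=0.02)
        assert areas[1] == pytest.approx(expected, rel=0.02)
        assert cap == pytest.approx(29.9, abs=0.05)

    def test_point_density_convergence(self):
        ref, _, _ = synth.generate_helix_bundle(n_helices=2, residues_per_helix=10,
                                                seed=2)
        coarse = structure.shrake_rupley_sasa(ref, n_points=960)
        fine = structure.shrake_rupley_sasa(ref, n_points=1920)
        assert abs(fine - coarse) / fine < 0.01


class TestBuriedSurfaceArea:
    def two_chain_model(self, separation):
        a, _, _ = synth.generate_helix_bundle(n_helices=1, residues_per_helix=8,
                                              seed=0)
        b = structure.transform_model(a, np.eye(3),
                                      np.array([separation, 0.0, 0.0]))
        return structure.StructureModel(chains={"A": a.chains["A"],
                                                "B": b.chains["A"]})

    def test_far_separated_chains_bury_nothing(self):
        model = self.two_chain_model(100.0)
        bsa = buried_surface_area(model, ["A"], ["B"], n_points=480)
        assert abs(bsa) < 1e-6

    def test_symmetric_under_side_swap_and_positive_on_contact(self):
        model = self.two_chain_model(7.0)
        ab = buried_surface_area(model, ["A"], ["B"], n_points=480)
        ba = buried_surface_area(model, ["B"], ["A"], n_points=480)
        assert ab == pytest.approx(ba, abs=1e-9)
        assert ab > 0

    def test_two_sphere_toy_matches_closed_form(self, tmp_path):
        # two carbon atoms 2 A apart; solvent radius 3.1, cap height 2.1
        pdb = ("ATOM      1  CA  ALA A   1       0.000   0.000   0.000"
               "  1.00  0.00           C\n"
               "ATOM      2  CA  ALA B   1       2.000   0.000   0.000"
               "  1.00  0.00           C\nEND\n")
        path = tmp_path / "two.pdb"
        path.write_text(pdb)
        model = structure.parse_structure(path)
        bsa = buried_surface_area(model, ["A"], ["B"], n_points=4000)
        big_r = 1.7 + 1.4
        expected = 2 * 2 * np.pi * big_r * (big_r - 1.0)
        assert bsa == pytest.approx(expected, rel=0.02)

    def test_interface_expansion_of_identical_complexes_is_zero(self):
        model = self.two_chain_model(7.0)
        delta = structure.interface_expansion(model, model,
                                              (["A"], ["B"]), (["A"], ["B"]),
                                              n_points=480)
        assert delta == pytest.approx(0.0, abs=1e-9)

    def test_empty_side_is_an_error(self):
        model = self.two_chain_model(7.0)
        with pytest.raises(ValueError):
            buried_surface_area(model, [], ["B"])


# ---------------------------------------------------------------------------
# cross-links


class TestCrossLinks:
    def test_limits_follow_most_permissive_reagent(self):
        dss = CrossLinkRecord("A", 1, "A", 2, frozenset({"DSS"}))
        dsg = CrossLinkRecord("A", 1, "A", 2, frozenset({"DSG"}))
        both = CrossLinkRecord("A", 1, "A", 2, frozenset({"DSG", "DSS"}))
        assert dss.distance_limit == 30.0
        assert dsg.distance_limit == 26.0
        assert both.distance_limit == 30.0

    def test_boundary_classification(self):
        ref, _, _ = synth.generate_helix_bundle(seed=0)
        lys = [r for r in ref.residues("A") if r.name == "LYS"]
        # plant two links with hand-set distances by fabricating coordinates
        a, b = lys[0], lys[1]
        b.atoms["CA"].xyz = a.ca + np.array([12.3, 0.0, 0.0])
        c = lys[2]
        c.atoms["CA"].xyz = a.ca + np.array([27.0, 0.0, 0.0])
        links = [CrossLinkRecord("A", a.number, "A", b.number, {"DSS"}),
                 CrossLinkRecord("A", a.number, "A", c.number, {"DSG"})]
        mapped = map_crosslinks(ref, links)
        assert mapped[0].ca_distance == pytest.approx(12.3)
        assert mapped[0].satisfied is True
        assert mapped[1].ca_distance == pytest.approx(27.0)
        assert mapped[1].satisfied is False  # 27.0 > DSG limit 26

    def test_classification_matches_distance_matrix_oracle(self):
        ref, _, _ = synth.generate_helix_bundle(n_helices=3, residues_per_helix=30,
                                                seed=4)
        links, ledger = synth.generate_crosslink_set(ref, n_true=12, n_false=6,
                                                     seed=5)
        mapped = map_crosslinks(ref, links)
        assert [m.satisfied for m in mapped] == ledger.manifest["is_true"]
        ca = {r.number: r.ca for r in ref.residues("A")}
        for link in mapped:
            dist = np.linalg.norm(ca[link.res_a] - ca[link.res_b])
            assert link.ca_distance == pytest.approx(dist)
            assert link.satisfied == (dist <= link.distance_limit)

    def test_unresolved_endpoint_is_unmappable(self):
        ref, _, _ = synth.generate_helix_bundle(seed=0)
        mapped = map_crosslinks(ref, [CrossLinkRecord("A", 9999, "A", 5, {"DSS"})])
        assert mapped[0].mappable is False
        assert mapped[0].satisfied is None

    def test_non_lysine_endpoint_warns_but_maps(self):
        ref, _, _ = synth.generate_helix_bundle(seed=0)
        ala = next(r for r in ref.residues("A") if r.name == "ALA")
        lys = next(r for r in ref.residues("A") if r.name == "LYS")
        with pytest.warns(UserWarning):
            mapped = map_crosslinks(ref, [CrossLinkRecord(
                "A", ala.number, "A", lys.number, {"BS3"})])
        assert mapped[0].mappable

    def test_support_summary_matches_brute_force(self):
        ref, _, _ = synth.generate_helix_bundle(n_helices=3, residues_per_helix=30,
                                                seed=6)
        links, _ = synth.generate_crosslink_set(ref, n_true=10, n_false=5, seed=7)
        mapped = map_crosslinks(ref, links)
        table = crosslink_support_summary(mapped)
        for level in (1, 2, 3):
            group = [l for l in mapped if l.support_level == level]
            assert table.loc[level, "total"] == len(group)
            assert table.loc[level, "satisfied"] == sum(l.satisfied for l in group)

    def test_all_satisfied_fractions_are_one(self):
        ref, _, _ = synth.generate_helix_bundle(n_helices=3, residues_per_helix=30,
                                                seed=8)
        links, _ = synth.generate_crosslink_set(ref, n_true=10, n_false=0, seed=9)
        table = crosslink_support_summary(map_crosslinks(ref, links))
        present = table.dropna(subset=["fraction"])
        assert (present["fraction"] == 1.0).all()

    def test_tsv_round_trip(self, tmp_path):
        ref, _, _ = synth.generate_helix_bundle(n_helices=3, residues_per_helix=30,
                                                seed=10)
        links, _ = synth.generate_crosslink_set(ref, n_true=4, n_false=2, seed=11)
        path = tmp_path / "links.tsv"
        structure.write_crosslink_tsv(links, path)
        back = structure.read_crosslink_tsv(path)
        assert [(l.res_a, l.res_b, l.reagents) for l in back] == \
               [(l.res_a, l.res_b, l.reagents) for l in links]


# ---------------------------------------------------------------------------
# docking funnels


class TestFunnelStats:
    def test_constant_scores(self):
        records = pd.DataFrame({"ddg": [-5.0] * 300, "rmsd": 0.0,
                                "run": ["local"] * 150 + ["global"] * 150})
        stats = funnel_stats(records)
        assert stats.local_minimum == -5.0
        assert stats.global_minimum == -5.0
        assert stats.relative_binding_energy == 0.0

    def test_mean_of_hundred_lowest(self):
        records = pd.DataFrame({
            "ddg": list(range(1, 151)) + [0.0],
            "rmsd": 0.0,
            "run": ["local"] * 150 + ["global"]})
        with pytest.warns(UserWarning):  # only one global record
            stats = funnel_stats(records)
        assert stats.local_minimum == pytest.approx(np.mean(range(1, 101)))
        assert stats.local_minimum == 50.5
        assert stats.n_global_used == 1

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_sort_and_average_oracle(self, seed):
        records, _ = synth.generate_funnel_table(seed=seed, n_local=500,
                                                 n_global=400)
        stats = funnel_stats(records, k=100)
        local = np.sort(records.loc[records.run == "local", "ddg"])[:100].mean()
        glob = np.sort(records.loc[records.run == "global", "ddg"])[:100].mean()
        assert stats.local_minimum == pytest.approx(local)
        assert stats.global_minimum == pytest.approx(glob)
        assert stats.relative_binding_energy == pytest.approx(local - glob)

    def test_k_equal_n_is_the_grand_mean(self):
        records, _ = synth.generate_funnel_table(seed=2, n_local=150, n_global=150)
        stats = funnel_stats(records, k=150)
        assert stats.local_minimum == pytest.approx(
            records.loc[records.run == "local", "ddg"].mean())

    def test_empty_class_is_an_error(self):
        records = pd.DataFrame({"ddg": [1.0], "rmsd": [0.0], "run": ["local"]})
        with pytest.raises(ValueError):
            funnel_stats(records)

    def test_dock_tsv_reader_validates_columns(self, tmp_path):
        records, _ = synth.generate_funnel_table(seed=3, n_local=5, n_global=5)
        path = tmp_path / "dock.tsv"
        records.to_csv(path, sep="\t", index=False)
        back = structure.read_dock_tsv(path)
        pd.testing.assert_frame_equal(back, records)
        bad = tmp_path / "bad.tsv"
        records.drop(columns=["run"]).to_csv(bad, sep="\t", index=False)
        with pytest.raises(ValueError):
            structure.read_dock_tsv(bad)
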