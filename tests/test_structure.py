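"""Structure reading, superposition, deviation, contacts, painting, overlap."""

import gemmi
import numpy as np
import pytest

from famcons.structure import (
    ContactCriteria,
    HelixAnnotation,
    StructureError,
    ca_deviation_profile,
    contact_count_grid,
    detect_polar_contacts,
    helix_network_report,
    map_scores_to_structure,
    mutation_overlap_report,
    read_structure,
    superpose,
)
from famcons.conservation import ConservationProfile
from famcons import synthetic as syn

from conftest import build_model, engineered_two_helix_model


def toy_helix(n=10, origin=(0, 0, 0)):
    return syn.generate_toy_structure(
        syn.ToyStructureSpec(helices=(syn.HelixPlacement(n, origin=origin),))
    )


class TestReadStructure:
    def test_toy_roundtrip_all_residues_have_ca(self, tmp_path):
        model = toy_helix(10)
        p = tmp_path / "toy.pdb"
        model.write_pdb(p)
        back = read_structure(p)
        assert len(back.ca_positions()) == 10
        assert back.missing_ca == []

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        model = build_model([("A", 1, "ALA", [("N", "N", (0, 0, 0)),
                                              ("C", "C", (2, 0, 0)),
                                              ("O", "O", (3, 0, 0))])])
        residue = model.get_residue("A", 1)
        for altloc, occ, x in (("A", 0.6, 1.0), ("B", 0.4, 9.0)):
            a = gemmi.Atom()
            a.name = "CA"
            a.element = gemmi.Element("C")
            a.pos = gemmi.Position(x, 0, 0)
            a.occ = occ
            a.altloc = altloc
            residue.add_atom(a)
        p = tmp_path / "alt.pdb"
        model.write_pdb(p)
        back = read_structure(p)
        residue = back.get_residue("A", 1)
        cas = [a for a in residue if a.name == "CA"]
        assert len(cas) == 1
        assert cas[0].pos.x == pytest.approx(1.0)
        assert cas[0].occ == pytest.approx(0.6)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(StructureError):
            read_structure(p)

    def test_missing_ca_flagged_not_dropped(self):
        model = build_model([
            ("A", 1, "GLY", [("N", "N", (0, 0, 0)), ("C", "C", (1.5, 0, 0))]),
            ("A", 2, "ALA", [("CA", "C", (4, 0, 0))]),
        ])
        assert ("A", 1) in model.missing_ca
        assert model.get_residue("A", 1) is not None


class TestSuperpose:
    def test_identical_structures_rmsd_zero(self):
        model = toy_helix()
        sup = superpose(model, model)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-6)

    def test_rigid_motion_recovered(self):
        model = toy_helix()
        moved, _ = syn.perturb_structure(
            model, rigid=(syn.random_rotation(11), np.array([5.0, -3.0, 2.0]))
        )
        sup = superpose(moved, model)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0)

    def test_rmsd_invariant_under_mobile_pretransform(self):
        wild = toy_helix()
        variant, _ = syn.perturb_structure(wild, {("A", 4): (1.0, 1.0, 0.0)})
        base = superpose(variant, wild).rmsd
        pre, _ = syn.perturb_structure(
            variant, rigid=(syn.random_rotation(5), np.array([-2.0, 7.0, 1.0]))
        )
        assert superpose(pre, wild).rmsd == pytest.approx(base, abs=1e-6)

    def test_fit_on_undisplaced_residues_gives_zero_rmsd(self):
        wild = toy_helix()
        variant, _ = syn.perturb_structure(wild, {("A", 5): (0, 0, 2.0)})
        fit = [("A", i) for i in range(1, 11) if i != 5]
        assert superpose(variant, wild, fit).rmsd == pytest.approx(0.0, abs=1e-6)

    def test_too_few_atoms_rejected(self):
        model = toy_helix()
        with pytest.raises(StructureError):
            superpose(model, model, [("A", 1), ("A", 2)])


class TestCaDeviation:
    def test_self_comparison_all_zero(self):
        model = toy_helix()
        prof = ca_deviation_profile(model, model)
        assert prof.table["deviation"].max() == pytest.approx(0.0, abs=1e-9)

    def test_injected_displacement_recovered(self):
        wild = toy_helix()
        variant, mags = syn.perturb_structure(wild, {("A", 5): (0, 0, 2.0)})
        fit = [("A", i) for i in range(1, 11) if i != 5]
        prof = ca_deviation_profile(variant, wild, fit_selection=fit)
        assert prof.deviation_at("A", 5) == pytest.approx(mags[("A", 5)], abs=1e-3)
        others = prof.table[prof.table["residue"] != 5]["deviation"]
        assert others.max() < 1e-6

    def test_rigid_only_perturbation_gives_zero_profile(self):
        wild = toy_helix()
        variant, _ = syn.perturb_structure(
            wild, rigid=(syn.random_rotation(2), np.array([1.0, 2.0, 3.0]))
        )
        prof = ca_deviation_profile(variant, wild)
        assert prof.table["deviation"].max() < 1e-6

    def test_report_selection_restricts_rows(self):
        wild = toy_helix()
        prof = ca_deviation_profile(wild, wild, report_selection=[("A", 3), ("A", 7)])
        assert sorted(prof.table["residue"]) == [3, 7]


class TestPolarContacts:
    def ser_og_fixture(self, distance):
        """Ser hydroxyl donor pointing at a backbone carbonyl O."""
        return build_model([
            ("A", 1, "SER", [("CB", "C", (0, 0, -1.5)), ("OG", "O", (0, 0, 0))]),
            ("A", 10, "ALA", [("CA", "C", (0, 1.5, distance)),
                              ("O", "O", (0, 0, distance))]),
        ])

    def test_hydrogen_bond_at_2p9(self):
        net = detect_polar_contacts(self.ser_og_fixture(2.9), [("A", 1)], [("A", 10)])
        assert net.atom_count == 1
        edge = net.edges.iloc[0]
        assert edge["type"] == "hydrogen-bond"
        assert edge["distance"] == pytest.approx(2.9)

    def test_no_edge_at_6_angstroms(self):
        net = detect_polar_contacts(self.ser_og_fixture(6.0), [("A", 1)], [("A", 10)])
        assert net.atom_count == 0

    def test_angle_criterion_rejects_backward_geometry(self):
        # acceptor placed behind the donor's antecedent: angle ~0 degrees
        model = build_model([
            ("A", 1, "SER", [("CB", "C", (0, 0, 1.5)), ("OG", "O", (0, 0, 0))]),
            ("A", 10, "ALA", [("O", "O", (0, 0, 2.9))]),
        ])
        net = detect_polar_contacts(model, [("A", 1)], [("A", 10)])
        assert net.atom_count == 0

    def arg_asp_fixture(self):
        return build_model([
            ("A", 1, "ARG", [("CZ", "C", (0.5, 0, -1.3)),
                             ("NH1", "N", (0, 0, 0)), ("NH2", "N", (1.0, 0, 0))]),
            ("A", 5, "ASP", [("CG", "C", (0.5, 0, 4.5)),
                             ("OD1", "O", (0, 0, 3.2)), ("OD2", "O", (1.0, 0, 3.2))]),
        ])

    def test_salt_bridge_deduplicated_to_one_edge(self):
        net = detect_polar_contacts(self.arg_asp_fixture(), [("A", 1)], [("A", 5)])
        assert net.residue_pair_count == 1 and net.atom_count == 1
        assert net.edges.iloc[0]["type"] == "ionic"
        assert net.edges.iloc[0]["distance"] == pytest.approx(3.2)

    def test_all_pairs_mode_reports_every_qualifying_atom_pair(self):
        crit = ContactCriteria(dedupe="all_pairs")
        net = detect_polar_contacts(self.arg_asp_fixture(), [("A", 1)], [("A", 5)], crit)
        assert net.atom_count == 4  # NH1/NH2 x OD1/OD2 all within 4.0 A

    def test_symmetric_in_selections(self):
        model = self.ser_og_fixture(2.9)
        a, b = [("A", 1)], [("A", 10)]
        n1 = detect_polar_contacts(model, a, b)
        n2 = detect_polar_contacts(model, b, a)
        assert n1.atom_count == n2.atom_count == 1
        assert n1.edges.iloc[0]["distance"] == pytest.approx(n2.edges.iloc[0]["distance"])

    def test_invariant_under_global_rigid_motion(self):
        model, ranges, _ = engineered_two_helix_model()
        moved, _ = syn.perturb_structure(
            model, rigid=(syn.random_rotation(9), np.array([3.0, -1.0, 8.0]))
        )
        sel_a = [("A", i) for i in range(ranges[0][0], ranges[0][1] + 1)]
        sel_b = [("A", i) for i in range(ranges[1][0], ranges[1][1] + 1)]
        n1 = detect_polar_contacts(model, sel_a, sel_b)
        n2 = detect_polar_contacts(moved, sel_a, sel_b)
        assert n1.atom_count == n2.atom_count
        assert np.allclose(
            np.sort(n1.edges["distance"]), np.sort(n2.edges["distance"]), atol=1e-9
        )


class TestHelixNetwork:
    def test_distant_helices_have_no_contacts(self):
        model = syn.generate_toy_structure(
            syn.ToyStructureSpec(
                helices=(syn.HelixPlacement(10), syn.HelixPlacement(10, origin=(25, 0, 0)))
            )
        )
        report = helix_network_report(
            model, [HelixAnnotation("h1", "A", 1, 10), HelixAnnotation("h2", "A", 11, 20)]
        )
        assert report.residue_pair_total == 0

    def test_engineered_bridges_counted_exactly(self):
        model, ranges, expected_pairs = engineered_two_helix_model()
        report = helix_network_report(
            model,
            [HelixAnnotation("h1", "A", *ranges[0]), HelixAnnotation("h2", "A", *ranges[1])],
        )
        assert report.residue_pair_total == len(expected_pairs)
        found = {
            tuple(sorted((r.res_a, r.res_b))) for r in report.network.edges.itertuples()
        }
        assert found == set(expected_pairs)

    def test_intra_helix_backbone_bonds_never_counted(self):
        # a single helix split into two annotations would be inter-helix;
        # here one helix annotated as itself vs a distant one: own i,i+4
        # backbone bonds must not appear anywhere in the report
        model, ranges, _ = engineered_two_helix_model()
        report = helix_network_report(
            model,
            [HelixAnnotation("h1", "A", *ranges[0]), HelixAnnotation("h2", "A", *ranges[1])],
        )
        for r in report.network.edges.itertuples():
            assert not (r.res_a <= 10 and r.res_b <= 10)
            assert not (r.res_a >= 11 and r.res_b >= 11)

    def test_overlapping_ranges_rejected(self):
        model, _, _ = engineered_two_helix_model()
        with pytest.raises(ValueError, match="overlap"):
            helix_network_report(
                model,
                [HelixAnnotation("h1", "A", 1, 12), HelixAnnotation("h2", "A", 10, 20)],
            )

    def test_counts_monotone_in_cutoffs(self):
        model, ranges, _ = engineered_two_helix_model()
        helices = [HelixAnnotation("h1", "A", *ranges[0]), HelixAnnotation("h2", "A", *ranges[1])]
        grid = contact_count_grid(
            model, helices, hbond_max_values=[2.5, 3.0, 3.5, 4.0], ionic_max_values=[4.0]
        )
        counts = list(grid.sort_values("hbond_max")["atom_pairs"])
        assert counts == sorted(counts)


class TestScoreMapping:
    def make_profile(self, sites, entropies):
        return ConservationProfile(
            site_numbers=list(sites),
            entropy=np.array(entropies, dtype=float),
            nongap_fraction=np.ones(len(sites)),
            consensus=["A"] * len(sites),
        )

    def test_scaled_scores_written_to_bfactors(self):
        model = toy_helix(6)
        profile = self.make_profile(range(1, 7), [0.0, 0.1, 0.2, 0.3, 0.5, 1.0])
        painted, missing = map_scores_to_structure(model, profile, "A", scale=100.0)
        assert missing == []
        residue = painted.get_residue("A", 5)
        assert all(a.b_iso == pytest.approx(50.0) for a in residue)

    def test_missing_sites_get_sentinel_and_are_listed(self):
        model = toy_helix(6)
        profile = self.make_profile([1, 2], [0.0, 0.4])
        painted, missing = map_scores_to_structure(model, profile, "A")
        assert missing == [3, 4, 5, 6]
        assert painted.get_residue("A", 4)[0].b_iso == pytest.approx(-1.0)

    def test_roundtrip_through_pdb(self, tmp_path):
        model = toy_helix(6)
        profile = self.make_profile(range(1, 7), [0.0, 0.1234, 0.2, 0.3, 0.5, 0.987])
        painted, _ = map_scores_to_structure(model, profile, "A")
        p = tmp_path / "painted.pdb"
        painted.write_pdb(p)
        back = read_structure(p)
        for site, s in zip(profile.site_numbers, profile.entropy):
            b = back.get_residue("A", site)[0].b_iso
            assert b == pytest.approx(100.0 * s, abs=0.005)

    def test_absent_chain_rejected(self):
        model = toy_helix(6)
        with pytest.raises(KeyError):
            map_scores_to_structure(model, self.make_profile([1], [0.0]), "Z")

    def test_original_model_untouched(self):
        model = toy_helix(6)
        map_scores_to_structure(model, self.make_profile([1], [0.9]), "A")
        assert model.get_residue("A", 1)[0].b_iso == 0.0


class TestMutationOverlap:
    def setup_inputs(self):
        model, ranges, _ = engineered_two_helix_model()
        net = detect_polar_contacts(
            model,
            [("A", i) for i in range(ranges[0][0], ranges[0][1] + 1)],
            [("A", i) for i in range(ranges[1][0], ranges[1][1] + 1)],
        )
        profile = ConservationProfile(
            site_numbers=list(range(1, 21)),
            entropy=np.array([0.04 if i in (2, 15) else 0.5 for i in range(1, 21)]),
            nongap_fraction=np.ones(20),
            consensus=["A"] * 20,
        )
        return net, profile

    def test_classification(self):
        net, profile = self.setup_inputs()
        report = mutation_overlap_report(net, profile, cmt_sites=[2, 12], s_max=0.1)
        table = report["table"].set_index("residue")
        assert table.loc[2, "class"] == "both"          # CMT site with S=0.04
        assert table.loc[12, "class"] == "cmt-only"
        assert table.loc[15, "class"] == "conserved-only"
        assert table.loc[5, "class"] == "neither"       # network-only residue

    def test_empty_cmt_list_classes_nothing_as_cmt(self):
        net, profile = self.setup_inputs()
        report = mutation_overlap_report(net, profile, cmt_sites=[], s_max=0.1)
        assert not report["table"]["cmt_site"].any()

    def test_focus_segment_contacts(self):
        net, profile = self.setup_inputs()
        report = mutation_overlap_report(
            net, profile, cmt_sites=[2], s_max=0.1, focus_residues=[12, 15, 18]
        )
        focus = report["focus_contacts"]
        assert sorted(focus["residue"]) == [2, 5, 8]
        assert focus.set_index("residue").loc[2, "class"] == "both"
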