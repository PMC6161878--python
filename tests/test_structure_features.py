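"""Structure parsing, surface area, dihedrals, neighborhoods, aggregation."""

import math

import numpy as np
import pytest

from snvloci import structure_features as sf
from snvloci.synthetic_fixtures import make_helix_structure
from conftest import ca_only_structure

PROBE = 1.4
R_C = 1.7  # carbon vdW


def single_atom_structure(xyz=(0.0, 0.0, 0.0)):
    return ca_only_structure([xyz], names=["GLY"])


class TestParseStructure:
    def test_minimal_structure(self, helix, helix_pdb):
        assert len(helix.chains) == 1
        assert len(helix.chains[0].residues) == 20
        assert all(len(r.atoms) == 4 for r in helix.chains[0].residues)

    def test_altloc_keeps_highest_occupancy(self):
        pdb = "\n".join([
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60 10.00           C",
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.40 10.00           C",
            "END",
        ])
        st = sf.parse_structure(pdb)
        atoms = st.chains[0].residues[0].atoms
        assert len(atoms) == 1
        assert atoms[0].occupancy == pytest.approx(0.60, abs=1e-6)
        assert atoms[0].xyz[0] == 0.0

    def test_waters_dropped_het_collected(self):
        pdb = make_helix_structure(5, seed=0, het_atoms=[("ZN", "ZN", (3.0, 0.0, 0.0))])
        pdb = pdb.replace(
            "END",
            "HETATM  998  O   HOH X 950      40.000  40.000  40.000  1.00 20.00           O\nEND",
        )
        st = sf.parse_structure(pdb)
        assert [g.name for g in st.het_groups] == ["ZN"]

    def test_no_atoms_raises(self):
        with pytest.raises(ValueError):
            sf.parse_structure("HEADER  NOTHING\n")

    def test_roundtrip_fixture_unchanged(self, helix_pdb, helix):
        reparsed = sf.parse_structure(helix_pdb, "helix")
        for r1, r2 in zip(helix.chains[0].residues, reparsed.chains[0].residues):
            assert r1.name == r2.name and r1.number == r2.number
            for a1, a2 in zip(r1.atoms, r2.atoms):
                assert np.allclose(a1.xyz, a2.xyz)
                assert a1.b_factor == pytest.approx(a2.b_factor, abs=1e-2)


class TestComputeAsa:
    def test_isolated_atom_matches_sphere_area(self):
        st = single_atom_structure()
        asa = sum(sf.compute_asa(st, probe_radius=PROBE, n_points=960).values())
        analytic = 4 * math.pi * (R_C + PROBE) ** 2
        assert asa == pytest.approx(analytic, rel=0.02)

    @pytest.mark.parametrize("d", [2.0, 3.5, 5.0])
    def test_two_spheres_match_cap_formula(self, d):
        st = ca_only_structure([(0, 0, 0), (d, 0, 0)], names=["GLY", "GLY"])
        total = sum(sf.compute_asa(st, probe_radius=PROBE, n_points=960).values())
        R = R_C + PROBE
        h = max(0.0, R - d / 2)  # buried cap height per sphere
        analytic = 2 * (4 * math.pi * R**2 - 2 * math.pi * R * h)
        assert total == pytest.approx(analytic, rel=0.02)

    def test_nonnegative_on_fixture(self, helix):
        assert all(v >= 0 for v in sf.compute_asa(helix).values())

    def test_quadrature_convergence(self, helix):
        coarse = sf.compute_asa(helix, n_points=960)
        fine = sf.compute_asa(helix, n_points=3840)
        total_c = sum(coarse.values())
        total_f = sum(fine.values())
        assert abs(total_c - total_f) / total_f < 0.01

    def test_unknown_element_warns(self):
        st = single_atom_structure()
        st.chains[0].residues[0].atoms[0].element = "Q"
        with pytest.warns(UserWarning, match="vdW"):
            sf.compute_asa(st)


class TestRelativeSa:
    def test_zero_and_reference_maximum(self):
        assert sf.relative_sa(0.0, "ALA") == 0.0
        assert sf.relative_sa(129.0, "ALA") == pytest.approx(1.0)

    def test_unknown_residue_missing(self):
        assert np.isnan(sf.relative_sa(50.0, "XYZ"))

    def test_exposed_gly_tripeptide_center_near_one(self):
        """Central Gly of an isolated Gly-Gly-Gly approaches full exposure.

        The fixture carries backbone atoms only, so some reference
        side-chain surface is absent; the band is widened accordingly.
        """
        st = sf.parse_structure(make_helix_structure(3, sequence="GGG", seed=0))
        asa = sf.compute_asa(st)
        mid = st.chains[0].residues[1]
        rsa = sf.relative_sa(asa[mid.id], mid.name)
        assert 0.75 <= rsa <= 1.2


class TestDihedrals:
    def test_chain_termini_missing(self, helix):
        first = helix.chains[0].residues[0]
        last = helix.chains[0].residues[-1]
        assert sf.backbone_dihedrals(helix, first)[0] is None
        assert sf.backbone_dihedrals(helix, last)[1] is None

    def test_helix_interior_hits_targets(self, helix):
        for res in helix.chains[0].residues[1:-1]:
            phi, psi = sf.backbone_dihedrals(helix, res)
            assert phi == pytest.approx(-57.0, abs=2.0)
            assert psi == pytest.approx(-47.0, abs=2.0)

    def test_collinear_backbone_missing(self):
        residues = []
        for i, x in enumerate([0.0, 1.5, 3.0]):
            residues.append(sf.Residue(
                name="GLY", number=i + 1, chain_id="A",
                atoms=[sf.Atom("N", "N", np.array([x, 0.0, 0.0])),
                       sf.Atom("CA", "C", np.array([x + 0.5, 0.0, 0.0])),
                       sf.Atom("C", "C", np.array([x + 1.0, 0.0, 0.0]))],
            ))
        st = sf.Structure(id="line", chains=[sf.Chain(name="A", residues=residues)])
        phi, psi = sf.backbone_dihedrals(st, residues[1])
        assert phi is None and psi is None


class TestCoreRegion:
    @pytest.mark.parametrize("phi,psi,expected", [
        (-57.0, -47.0, True),   # alpha box
        (-120.0, 130.0, True),  # beta box
        (60.0, 60.0, False),
    ])
    def test_default_boxes(self, phi, psi, expected):
        assert sf.in_core_region(phi, psi) is expected

    def test_missing_angle_propagates(self):
        assert sf.in_core_region(None, -47.0) is None


class TestNormalizeBfactors:
    def _with_bs(self, bs):
        st = ca_only_structure([(3 * i, 0, 0) for i in range(len(bs))])
        for r, b in zip(st.chains[0].residues, bs):
            r.atoms[0].b_factor = b
        return st

    def test_uniform_and_single(self):
        assert set(sf.normalize_bfactors(self._with_bs([7.0] * 4)).values()) == {0.0}
        assert list(sf.normalize_bfactors(self._with_bs([5.0])).values()) == [0.0]

    def test_population_zscores(self):
        z = sf.normalize_bfactors(self._with_bs([10.0, 20.0, 30.0]))
        assert sorted(z.values()) == pytest.approx([-1.2247, 0.0, 1.2247], abs=1e-4)


class TestFindNeighbors:
    def test_boundary_inclusive(self):
        st = ca_only_structure([(0, 0, 0), (4.2, 0, 0), (0, 8.99, 0),
                                (0, 0, 9.0), (9.01, 0, 0)])
        nbh = sf.find_neighbors(st, st.chains[0].residues[0], radius=9.0)
        assert len(nbh.members) == 3

    def test_single_residue_empty(self):
        st = single_atom_structure()
        nbh = sf.find_neighbors(st, st.chains[0].residues[0], radius=9.0)
        assert nbh.members == []

    def test_missing_ca_gives_none(self, helix):
        res = sf.Residue(name="ALA", number=99, chain_id="A",
                         atoms=[sf.Atom("CB", "C", np.zeros(3))])
        assert sf.find_neighbors(helix, res) is None

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(2, 40))
            coords = rng.uniform(0, 25, size=(n, 3))
            st = ca_only_structure(coords)
            center_idx = int(rng.integers(0, n))
            center = st.chains[0].residues[center_idx]
            radius = float(rng.uniform(5, 15))
            nbh = sf.find_neighbors(st, center, radius=radius)
            dists = np.linalg.norm(coords - coords[center_idx], axis=1)
            expected = {i + 1 for i in range(n)
                        if i != center_idx and dists[i] <= radius}
            assert {m.number for m in nbh.members} == expected

    def test_symmetry_and_radius_monotonicity(self, helix):
        residues = helix.chains[0].residues
        for radius in (5.0, 9.0, 15.0):
            sets = {r.id: {m.id for m in sf.find_neighbors(helix, r, radius).members}
                    for r in residues}
            for a in residues:
                for b_id in sets[a.id]:
                    assert a.id in sets[b_id]
        counts = [
            len(sf.find_neighbors(helix, residues[10], r).members)
            for r in np.linspace(5, 15, 6)
        ]
        assert counts == sorted(counts)


class TestBindingSiteTypes:
    def test_apo_structure_empty(self, helix):
        res = helix.chains[0].residues[5]
        assert sf.binding_site_types(helix, [res]) == set()

    def test_metal_contact(self):
        pdb = make_helix_structure(5, seed=0, het_atoms=[("ZN", "ZN", (3.0, 0.0, 0.0))])
        st = sf.parse_structure(pdb)
        res = st.chains[0].residues[0]  # N atom at origin
        assert sf.binding_site_types(st, [res]) == {"metal"}

    def test_ligand_and_protein_chain(self):
        pdb = make_helix_structure(
            5, seed=0, chain_ids=("A", "B"), chain_offset=6.0,
            het_atoms=[("C", "LIG", (0.0, 4.0, 0.0))],
        )
        st = sf.parse_structure(pdb)
        res = st.chains[0].residues[0]
        types = sf.binding_site_types(st, [res])
        assert types == {"ligand", "protein"}

    def test_count_bounded_by_taxonomy(self):
        pdb = make_helix_structure(
            5, seed=0, chain_ids=("A", "B"), chain_offset=4.0,
            het_atoms=[("ZN", "ZN", (2.0, 0.0, 0.0)), ("C", "LIG", (0.0, 2.0, 0.0))],
        )
        st = sf.parse_structure(pdb)
        types = sf.binding_site_types(st, st.chains[0].residues)
        assert types <= {"metal", "ligand", "nucleic", "protein"}


class TestPerStructureAndAggregate:
    def test_center_kd_lookup_and_neighbor_mean(self, helix):
        asa = sf.compute_asa(helix)
        res = helix.chains[0].residues[10]
        fs = sf.per_structure_features(helix, res, asa=asa)
        from snvloci.tables import KYTE_DOOLITTLE
        assert fs.kd == KYTE_DOOLITTLE[res.one_letter]
        nbh = sf.find_neighbors(helix, res)
        assert fs.n_num == len(nbh.members)
        expected_kd = np.mean([KYTE_DOOLITTLE[m.one_letter] for m in nbh.members])
        assert fs.n_kd == pytest.approx(expected_kd)

    def test_empty_neighborhood_missing_means(self):
        st = single_atom_structure()
        fs = sf.per_structure_features(st, st.chains[0].residues[0])
        assert fs.n_num == 0
        assert np.isnan(fs.n_rsa) and np.isnan(fs.n_kd) and np.isnan(fs.n_sc)

    def test_singleton_aggregation_identity(self, helix):
        fs = sf.per_structure_features(helix, helix.chains[0].residues[10],
                                       asa=sf.compute_asa(helix))
        agg = sf.aggregate_structures([fs])
        assert agg.KDmean == fs.kd
        assert agg.RSAmax == fs.rsa
        assert agg.Bstddev == 0.0
        assert agg.nNum == fs.n_num

    def test_rsamax_and_kd_pooling(self):
        a = sf.StructureFeatureSet(kd=4.5, rsa=0.2)
        b = sf.StructureFeatureSet(kd=-4.5, rsa=0.6)
        agg = sf.aggregate_structures([a, b])
        assert agg.RSAmax == 0.6
        assert agg.KDmean == 0.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        sets = [
            sf.StructureFeatureSet(
                kd=rng.normal(), rsa=rng.random(), b_norm=rng.normal(),
                in_core=bool(rng.integers(2)), n_num=int(rng.integers(0, 9)),
                n_rsa=rng.random(), n_b=rng.normal(), n_kd=rng.normal(),
                binding_types={"metal"} if rng.random() < 0.5 else set(),
            )
            for _ in range(5)
        ]
        fwd = sf.aggregate_structures(sets).as_dict()
        rev = sf.aggregate_structures(sets[::-1]).as_dict()
        for key in fwd:
            assert fwd[key] == pytest.approx(rev[key], nan_ok=True)

    def test_mapreg_majority_with_tie_to_core(self):
        core = sf.StructureFeatureSet(in_core=True)
        loop = sf.StructureFeatureSet(in_core=False)
        assert sf.aggregate_structures([core, core, loop]).Mapreg == 1.0
        assert sf.aggregate_structures([loop, loop, core]).Mapreg == 0.0
        assert sf.aggregate_structures([core, loop]).Mapreg == 1.0  # tie -> core

    def test_empty_input_all_missing(self):
        agg = sf.aggregate_structures([])
        assert all(np.isnan(v) for v in agg.as_dict().values())
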