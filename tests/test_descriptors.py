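"""Atom typing, bond distances, pair frequencies, shells, ring counts."""

import numpy as np
import pytest
from rdkit import Chem

from brd4qsar.curation import MoleculeRecord, embed3d
from brd4qsar.descriptors import (
    MODEL_A_DESCRIPTORS,
    DescriptorError,
    bond_distances,
    com_shell_count,
    generate_pool,
    model_a_descriptors,
    pairfreq,
    parse_descriptor_name,
    perceive_types,
    saturated_carbo_rings,
)

from conftest import REFERENCE_MOLECULES, pairfreq_oracle, record_from_smiles


class TestPerceiveTypes:
    def test_toluene(self, make_record):
        t = perceive_types(make_record("Cc1ccccc1"))
        assert len(t["sp3C"]) == 1  # the methyl
        assert len(t["aroC"]) == 6
        assert len(t["ringC"]) == 6
        assert len(t["lipo"]) == 7  # every carbon
        assert not t["N"] and not t["acc"] and not t["don"]

    def test_dimethyl_sulfone(self, make_record):
        t = perceive_types(make_record("CS(C)(=O)=O"))
        assert len(t["sulfonS"]) == 1
        assert len(t["acc"]) == 2  # both sulfonyl oxygens
        assert len(t["sp3O"]) == 0  # double-bonded oxygens are not sp3

    def test_methane(self, make_record):
        t = perceive_types(make_record("C"))
        assert t["lipo"] == frozenset({0})
        for name in ("sp3C", "ringC", "aroC", "N", "acc", "don", "sulfonS"):
            assert not t[name], name

    def test_pyridine_vs_pyrrole_nitrogen(self, make_record):
        pyridine = perceive_types(make_record("c1ccncc1"))
        assert len(pyridine["aroN"]) == 1 and len(pyridine["acc"]) == 1
        pyrrole = perceive_types(make_record("c1cc[nH]c1"))
        assert len(pyrrole["aroN"]) == 1
        assert not pyrrole["acc"]  # aromatic N-H is no acceptor
        assert len(pyrrole["don"]) == 1

    def test_amide_nitrogen_planar_not_acceptor(self, make_record):
        t = perceive_types(make_record("CC(=O)NC"))
        (n_idx,) = t["N"]
        assert n_idx in t["plaN"]
        assert n_idx not in t["acc"]
        assert n_idx in t["don"]

    def test_aromatic_nitrogen_implies_planar(self, reference_records):
        for rec in reference_records:
            t = perceive_types(rec)
            assert t["aroN"] <= t["plaN"]
            assert t["aroN"] <= t["N"]

    def test_unknown_type_rejected(self, make_record):
        t = perceive_types(make_record("CCO"))
        with pytest.raises(DescriptorError, match="unknown atom type"):
            t["sp2C"]


class TestBondDistances:
    def test_butane_chain(self, make_record):
        d = bond_distances(make_record("CCCC"))
        assert d[0, 3] == 3

    def test_benzene_para(self, make_record):
        d = bond_distances(make_record("c1ccccc1"))
        assert d.max() == 3  # para pairs meet around the ring

    def test_disconnected_fragments_infinite(self, make_record):
        d = bond_distances(make_record("CC.OO"))
        assert np.isinf(d[0, 2])

    def test_metric_properties(self, reference_records):
        for rec in reference_records:
            d = bond_distances(rec)
            assert np.allclose(d, d.T)
            assert (np.diag(d) == 0).all()
            n = d.shape[0]
            for i in range(0, n, 5):  # triangle inequality, sampled rows
                via = (d[i][:, None] + d).min(axis=0)  # min_m d[i,m] + d[m,j]
                mask = np.isfinite(d[i])
                assert (d[i][mask] <= via[mask] + 1e-9).all()
            # bonded pairs are exactly at distance 1
            mol = Chem.RemoveHs(rec.mol)
            for bond in mol.GetBonds():
                assert d[bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()] == 1


class TestPairfreq:
    def test_toluene_sp3C_to_ringC(self, make_record):
        rec = make_record("Cc1ccccc1")
        t, d = perceive_types(rec), bond_distances(rec)
        # ortho carbons sit at 2 bonds from the methyl; ipso at 1 is excluded
        assert pairfreq(t, d, "sp3C", "ringC", 2) == 2

    def test_methylcyclohexane_all_excluded(self, make_record):
        rec = make_record("CC1CCCCC1")
        t, d = perceive_types(rec), bond_distances(rec)
        # every ring carbon has an sp3 neighbour at 1 bond -> none at exactly 2
        assert pairfreq(t, d, "sp3C", "ringC", 2) == 0

    def test_amine_to_pyridine_nitrogen(self, make_record):
        rec = make_record("NCCc1ccccn1")
        t, d = perceive_types(rec), bond_distances(rec)
        assert pairfreq(t, d, "plaN", "N", 4) == 1

    def test_no_source_atoms_gives_zero(self, make_record):
        rec = make_record("CCCC")
        t, d = perceive_types(rec), bond_distances(rec)
        assert pairfreq(t, d, "sulfonS", "aroC", 8) == 0

    @pytest.mark.parametrize("source,target", [
        ("sp3C", "ringC"), ("lipo", "acc"), ("plaN", "N"),
        ("sp3O", "aroN"), ("sulfonS", "aroC"), ("don", "acc"),
    ])
    def test_matches_bruteforce_oracle(self, source, target, fixture_molecules):
        """Every typed pair count equals the independent BFS oracle."""
        for rec in fixture_molecules:
            t, d = perceive_types(rec), bond_distances(rec)
            mol = Chem.RemoveHs(rec.mol)
            for k in range(1, 9):
                expected = pairfreq_oracle(mol, set(t[source]), set(t[target]), k)
                assert pairfreq(t, d, source, target, k) == expected, (
                    rec.id, source, target, k,
                )

    def test_reindexing_invariance(self, reference_records):
        """Counts do not depend on the atom numbering of the input."""
        rng = np.random.default_rng(7)
        for rec in reference_records[:4]:
            mol = Chem.RemoveHs(rec.mol)
            perm = list(rng.permutation(mol.GetNumAtoms()))
            shuffled = Chem.RenumberAtoms(mol, [int(i) for i in perm])
            rec2 = MoleculeRecord(id=rec.id, smiles_input="", mol=shuffled)
            t1, d1 = perceive_types(rec), bond_distances(rec)
            t2, d2 = perceive_types(rec2), bond_distances(rec2)
            for source, target, k in [("sp3C", "ringC", 2), ("lipo", "acc", 3),
                                      ("plaN", "N", 4)]:
                assert pairfreq(t1, d1, source, target, k) == \
                    pairfreq(t2, d2, source, target, k)

    def test_distance_partition_of_targets(self, reference_records):
        """Summing over all k partitions the reachable target atoms."""
        for rec in reference_records:
            t, d = perceive_types(rec), bond_distances(rec)
            source, target = "lipo", "acc"
            src, tgt = t[source], t[target]
            diameter = int(np.nanmax(np.where(np.isfinite(d), d, np.nan)))
            total = sum(
                pairfreq(t, d, source, target, k) for k in range(1, diameter + 1)
            )
            unreachable = sum(
                1
                for a in tgt
                if not any(np.isfinite(d[a, s]) and s != a for s in src)
            )
            assert total + unreachable == len(tgt)


@pytest.fixture(scope="module")
def fixture_molecules():
    """50 molecules: the 10 reference inhibitors + 40 generated ones."""
    from brd4qsar.synthetic import SyntheticSpec, generate

    records = [
        record_from_smiles(smiles, mol_id)
        for mol_id, (smiles, _, _) in REFERENCE_MOLECULES.items()
    ]
    extra, _ = generate(SyntheticSpec(n_molecules=40, seed=123))
    return records + extra


class TestSaturatedCarboRings:
    @pytest.mark.parametrize(
        "smiles, expected",
        [
            ("C1CCCCC1", 1),  # cyclohexane
            ("C1CCC2CCCCC2C1", 2),  # decalin
            ("C1=CCCCC1", 0),  # cyclohexene: ring double bond
            ("C1CCNCC1", 0),  # piperidine: ring nitrogen
            ("c1ccccc1", 0),  # benzene
            ("C1CC1c1ccccc1", 1),  # phenylcyclopropane
        ],
    )
    def test_ring_census(self, smiles, expected, make_record):
        assert saturated_carbo_rings(make_record(smiles)) == expected

    def test_reference_molecule_cyclopropyl(self):
        smiles = REFERENCE_MOLECULES["570"][0]
        assert saturated_carbo_rings(record_from_smiles(smiles)) == 1


class TestComShellCount:
    def test_methane_carbon_at_center(self, make_record):
        rec = embed3d(make_record("C"), seed=1)
        assert com_shell_count(rec, "C", 4.0) == 1

    def test_lone_noble_atom_has_no_carbon(self, make_record):
        rec = embed3d(make_record("[He]"), seed=1)
        assert com_shell_count(rec, "C", 10.0) == 0

    def test_decane_matches_direct_distance_count(self, make_record):
        rec = embed3d(make_record("CCCCCCCCCC"), seed=5)
        mol = rec.mol3d
        coords = np.asarray(mol.GetConformer().GetPositions())
        masses = np.array([a.GetMass() for a in mol.GetAtoms()])
        com = (coords * masses[:, None]).sum(axis=0) / masses.sum()
        expected = sum(
            1
            for a in mol.GetAtoms()
            if a.GetSymbol() == "C"
            and np.linalg.norm(coords[a.GetIdx()] - com) <= 4.0
        )
        assert com_shell_count(rec, "C", 4.0) == expected

    def test_monotone_in_radius(self, make_record):
        rec = embed3d(make_record("CCCCCCCCCC"), seed=5)
        counts = [com_shell_count(rec, "C", r) for r in (1.0, 2.0, 4.0, 8.0)]
        assert counts == sorted(counts)

    def test_requires_coordinates(self, make_record):
        with pytest.raises(DescriptorError, match="3D"):
            com_shell_count(make_record("CC"), "C", 4.0)


class TestModelADescriptors:
    def test_cyclohexane(self, make_record):
        rec = embed3d(make_record("C1CCCCC1"), seed=2)
        values = model_a_descriptors(rec)
        assert values["Saturated_Carbo_Rings"] == 1
        assert values["fplaNN4B"] == 0
        assert values["fsulfonSaroC8B"] == 0

    def test_benzene_has_no_saturated_ring(self, make_record):
        rec = embed3d(make_record("c1ccccc1"), seed=2)
        assert model_a_descriptors(rec)["Saturated_Carbo_Rings"] == 0

    def test_missing_coordinates_names_culprit(self, make_record):
        with pytest.raises(DescriptorError, match="com"):
            model_a_descriptors(make_record("C1CCCCC1"))

    def test_counts_are_nonnegative_integers(self, reference_records):
        for rec in reference_records[:3]:
            rec = embed3d(rec, seed=11)
            for name, value in model_a_descriptors(rec).items():
                assert value >= 0
                assert value == int(value), name


class TestGeneratePool:
    def test_matrix_shape_and_names(self, make_record):
        records = [make_record(s, str(i)) for i, s in
                   enumerate(["Cc1ccccc1", "CC1CCCCC1", "CCc1ccccc1"])]
        matrix = generate_pool(records, sources=("sp3C",), targets=("ringC",),
                               k_range=(1, 2, 3))
        assert matrix.data.shape == (3, 3)
        assert matrix.names == ["fsp3CringC1B", "fsp3CringC2B", "fsp3CringC3B"]

    def test_empty_request_gives_zero_columns(self, make_record):
        matrix = generate_pool([make_record("CC")], k_range=())
        assert matrix.data.shape == (1, 0)

    def test_consistent_with_model_a(self, reference_records):
        """Pool restricted to the published definitions matches the
        dedicated model-descriptor path (topological columns)."""
        topo = {k: v for k, v in MODEL_A_DESCRIPTORS.items()
                if v[0] != "com_shell"}
        matrix = generate_pool(reference_records, sources=(), targets=(),
                               k_range=(), extra=topo)
        for rec in reference_records:
            rec3d = embed3d(rec, seed=3)
            expected = model_a_descriptors(rec3d)
            for name in topo:
                assert matrix.data.loc[rec.id, name] == expected[name]

    def test_all_counts_integer_nonnegative(self, fixture_molecules):
        matrix = generate_pool(fixture_molecules, sources=("sp3C", "lipo"),
                               targets=("ringC", "acc"), k_range=(1, 2, 3, 4))
        values = matrix.data.to_numpy()
        assert (values >= 0).all()
        assert np.array_equal(values, np.round(values))


class TestParseDescriptorName:
    @pytest.mark.parametrize("name", list(MODEL_A_DESCRIPTORS))
    def test_published_names_roundtrip(self, name):
        assert parse_descriptor_name(name) == MODEL_A_DESCRIPTORS[name]

    def test_garbage_rejected(self):
        with pytest.raises(DescriptorError):
            parse_descriptor_name("fnotatypeX9B")
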