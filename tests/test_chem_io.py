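"""Curation pipeline: reading, standardization, InChI dedup, scaffold
clustering and representative selection."""

import pytest
from rdkit import Chem

from qeppi.chem_io import (
    CompoundRecord,
    CompoundSet,
    ScaffoldCluster,
    cluster_by_scaffold,
    curate,
    dedupe_by_inchi,
    murcko_scaffold,
    read_compounds,
    select_representatives,
    standardize,
    standardize_set,
)


def _records(*smiles, activities=None):
    acts = activities or [None] * len(smiles)
    return CompoundSet(
        records=[
            CompoundRecord(id=f"m{i}", smiles=s, activity=a)
            for i, (s, a) in enumerate(zip(smiles, acts))
        ]
    )


class TestReadCompounds:
    def test_smiles_table_single_record(self, tmp_path):
        p = tmp_path / "one.smi"
        p.write_text("c1ccccc1 benzene\n")
        cset = read_compounds(p)
        assert len(cset) == 1
        assert cset.records[0].id == "benzene"

    def test_invalid_smiles_skipped_not_fatal(self, tmp_path):
        p = tmp_path / "three.smi"
        p.write_text("c1ccccc1 a\nnot_a_smiles((( b\nCCO c\n")
        cset = read_compounds(p)
        assert len(cset) == 2
        assert [r.id for r in cset] == ["a", "c"]

    def test_csv_with_smiles_column(self, tmp_path):
        p = tmp_path / "five.csv"
        rows = ["SMILES,name", "CCO,e1", "CCC,e2", "CCN,e3", "CCCl,e4", "CCBr,e5"]
        p.write_text("\n".join(rows) + "\n")
        cset = read_compounds(p, smiles_column="SMILES")
        assert len(cset) == 5

    def test_csv_activity_column(self, tmp_path):
        p = tmp_path / "act.csv"
        p.write_text("smiles,id,activity\nCCO,a,6.2\nCCC,b,\n")
        cset = read_compounds(p)
        assert cset.records[0].activity == pytest.approx(6.2)
        assert cset.records[1].activity is None

    def test_sdf_roundtrip(self, tmp_path):
        p = tmp_path / "mols.sdf"
        writer = Chem.SDWriter(str(p))
        for smi, name in [("CCO", "ethanol"), ("c1ccccc1", "benzene")]:
            mol = Chem.MolFromSmiles(smi)
            mol.SetProp("_Name", name)
            writer.write(mol)
        writer.close()
        cset = read_compounds(p)
        assert [r.id for r in cset] == ["ethanol", "benzene"]

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_compounds(tmp_path / "absent.smi")

    def test_no_parseable_records_raises(self, tmp_path):
        p = tmp_path / "bad.smi"
        p.write_text("not_a_smiles((( x\n")
        with pytest.raises(ValueError, match="no parseable"):
            read_compounds(p)


class TestStandardize:
    @pytest.mark.parametrize(
        "smiles, expected_fragment",
        [
            ("CCO.Cl", "CCO"),  # solvent/counter-ion stripped
            ("[Na+].CC(=O)[O-]", "CC(=O)[O-]"),  # acetate kept over sodium
            ("Cl.NCCc1ccccc1", "NCCc1ccccc1"),
        ],
    )
    def test_largest_fragment_kept(self, smiles, expected_fragment):
        rec = standardize(CompoundRecord(id="x", smiles=smiles))
        assert rec.smiles == Chem.MolToSmiles(Chem.MolFromSmiles(expected_fragment))

    def test_single_fragment_canonicalized_unchanged(self):
        rec = standardize(CompoundRecord(id="x", smiles="c1ccccc1"))
        assert rec.smiles == Chem.MolToSmiles(Chem.MolFromSmiles("c1ccccc1"))
        assert rec.inchi.startswith("InChI=1S/")

    def test_idempotent(self, fixture_set):
        for rec in fixture_set.records[:20]:
            once = standardize(rec)
            twice = standardize(once)
            assert (twice.smiles, twice.inchi) == (once.smiles, once.inchi)

    def test_unparseable_raises(self):
        with pytest.raises(ValueError):
            standardize(CompoundRecord(id="x", smiles="xyz((("))


class TestDedupe:
    def test_same_molecule_different_spelling_collapses(self):
        # independent oracle: RDKit InChI equality of the two spellings
        assert Chem.MolToInchi(Chem.MolFromSmiles("CCO")) == Chem.MolToInchi(
            Chem.MolFromSmiles("OCC")
        )
        cset = standardize_set(_records("CCO", "OCC"))
        assert len(dedupe_by_inchi(cset)) == 1

    def test_disjoint_structures_unchanged(self):
        cset = standardize_set(_records("CCO", "CCC", "c1ccccc1"))
        assert len(dedupe_by_inchi(cset)) == 3

    def test_first_occurrence_kept_order_preserved(self):
        cset = standardize_set(_records("CCO", "CCC", "OCC"))
        out = dedupe_by_inchi(cset)
        assert [r.id for r in out] == ["m0", "m1"]

    def test_idempotent(self, fixture_set):
        once = dedupe_by_inchi(standardize_set(fixture_set))
        twice = dedupe_by_inchi(once)
        assert [r.id for r in twice] == [r.id for r in once]

    def test_unstandardized_record_rejected(self):
        with pytest.raises(ValueError, match="standardize"):
            dedupe_by_inchi(_records("CCO"))


class TestScaffoldClustering:
    def test_shared_framework_groups_together(self):
        cset = standardize_set(_records("Cc1ccccc1", "CCc1ccccc1"))
        clusters = cluster_by_scaffold(cset)
        assert len(clusters) == 1
        assert clusters[0].scaffold == murcko_scaffold("c1ccccc1")

    def test_aromatic_vs_saturated_ring_distinct(self):
        cset = standardize_set(_records("c1ccccc1", "C1CCCCC1"))
        assert len(cluster_by_scaffold(cset)) == 2

    def test_distinct_frameworks_give_n_clusters(self):
        cset = standardize_set(_records("c1ccccc1", "c1ccncc1", "C1CCCCC1"))
        assert len(cluster_by_scaffold(cset)) == 3

    def test_acyclic_molecules_share_one_cluster(self):
        cset = standardize_set(_records("CCO", "CCCC", "c1ccccc1"))
        clusters = cluster_by_scaffold(cset)
        by_scaffold = {c.scaffold: c for c in clusters}
        assert len(by_scaffold[""].members) == 2

    def test_partition_property(self, fixture_set):
        cset = dedupe_by_inchi(standardize_set(fixture_set))
        clusters = cluster_by_scaffold(cset)
        member_ids = sorted(r.id for c in clusters for r in c.members)
        assert member_ids == sorted(r.id for r in cset)


class TestSelectRepresentatives:
    def test_highest_activity_wins(self):
        cluster = ScaffoldCluster(
            scaffold="c1ccccc1",
            members=[
                CompoundRecord(id="low", smiles="Cc1ccccc1", activity=6.2),
                CompoundRecord(id="high", smiles="CCc1ccccc1", activity=7.5),
            ],
        )
        out = select_representatives([cluster])
        assert out.records[0].id == "high"

    def test_all_missing_activity_lexicographic_id(self):
        cluster = ScaffoldCluster(
            scaffold="",
            members=[
                CompoundRecord(id="zeta", smiles="CCO"),
                CompoundRecord(id="alpha", smiles="CCC"),
            ],
        )
        assert select_representatives([cluster]).records[0].id == "alpha"

    def test_missing_activity_loses_to_any_value(self):
        cluster = ScaffoldCluster(
            scaffold="",
            members=[
                CompoundRecord(id="a", smiles="CCO"),
                CompoundRecord(id="b", smiles="CCC", activity=-3.0),
            ],
        )
        assert select_representatives([cluster]).records[0].id == "b"

    def test_one_representative_per_cluster(self, fixture_set):
        cset = dedupe_by_inchi(standardize_set(fixture_set))
        clusters = cluster_by_scaffold(cset)
        assert len(select_representatives(clusters)) == len(clusters)


def test_curate_end_to_end(fixture_set):
    reps, clusters = curate(fixture_set)
    assert len(reps) == len(clusters)
    # the duplicate-spelling pair and salt forms must have collapsed
    assert len(reps) < len(fixture_set)
    assert all(r.inchi for r in reps)
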