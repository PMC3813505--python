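"""Library IO: SDF/SMILES/table parsing, tag coercion, round trips."""

import math

import pytest
from rdkit import Chem

from chemprof.chemio import (
    DEFAULT_TAG_SCHEMA, Library, LibraryError, MoleculeRecord, TagSpec,
    extract_descriptors, load_tag_schema, read_library, write_library,
)

GOOD_MOLBLOCK = """benzaldehyde
     RDKit          2D

  8  8  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0
    1.2990    0.7500    0.0000 C   0  0
    2.5981    0.0000    0.0000 C   0  0
    2.5981   -1.5000    0.0000 C   0  0
    1.2990   -2.2500    0.0000 C   0  0
    0.0000   -1.5000    0.0000 C   0  0
   -1.2990    0.7500    0.0000 C   0  0
   -2.5981    0.0000    0.0000 O   0  0
  1  2  2  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  1  1  0
  1  7  1  0
  7  8  2  0
M  END
"""


def sdf_record(molblock=GOOD_MOLBLOCK, tags=None):
    parts = [molblock.rstrip("\n")]
    for tag, value in (tags or {}).items():
        parts += [f">  <{tag}>", str(value), ""]
    parts.append("$$$$")
    return "\n".join(parts) + "\n"


def test_sdf_reading_preserves_tags_and_order(tmp_path):
    text = (
        sdf_record(tags={"MW": "406.0", "QPlogPo/w": "3.99"})
        + sdf_record(tags={"MW": "118.0"})
    )
    path = tmp_path / "lib.sdf"
    path.write_text(text)
    lib = read_library(path)
    assert len(lib) == 2
    assert lib.records[0].raw_tags["MW"] == "406.0"
    assert lib.records[0].raw_tags["QPlogPo/w"] == "3.99"
    assert lib.records[0].record_id == "benzaldehyde"
    assert lib.records[1].record_id == "benzaldehyde_2"  # deterministic suffix


def test_corrupt_record_skipped_with_exact_counts(tmp_path):
    corrupt = GOOD_MOLBLOCK.replace("  8  8", "  9  XY")
    text = sdf_record() + sdf_record(corrupt) + sdf_record()
    path = tmp_path / "mixed.sdf"
    path.write_text(text)
    lib = read_library(path)
    assert len(lib) == 2
    assert lib.n_skipped == 1
    assert len(lib) + lib.n_skipped == 3


def test_zero_parseable_records_is_fatal(tmp_path):
    path = tmp_path / "empty.smi"
    path.write_text("")
    with pytest.raises(LibraryError, match="zero parseable"):
        read_library(path)


def test_missing_file_is_fatal_and_names_path(tmp_path):
    with pytest.raises(LibraryError, match="nope.sdf"):
        read_library(tmp_path / "nope.sdf")


def test_v3000_rejected(tmp_path):
    block = GOOD_MOLBLOCK.replace("V2000", "V3000")
    path = tmp_path / "v3.sdf"
    path.write_text(sdf_record(block))
    with pytest.raises(LibraryError, match="V3000"):
        read_library(path)


def test_smiles_reading_with_and_without_ids(tmp_path):
    path = tmp_path / "lib.smi"
    path.write_text("CCO\tethanol\nc1ccccc1\nnot_a_smiles\n")
    lib = read_library(path)
    assert lib.record_ids() == ["ethanol", "mol2"]
    assert lib.n_skipped == 1


def test_sdf_round_trip_structures_and_tags(tmp_path, boundary):
    lib, _ = boundary
    structural = Library(
        records=[r for r in lib.records if r.mol is not None][:5],
        name="five", tag_schema=lib.tag_schema,
    )
    for rec in structural.records:
        rec.raw_tags["note"] = "kept verbatim"
    out = tmp_path / "out.sdf"
    write_library(structural, out, format="sdf")
    back = read_library(out)
    assert back.record_ids() == structural.record_ids()
    for a, b in zip(structural.records, back.records):
        assert a.mol.GetNumAtoms() == b.mol.GetNumAtoms()
        assert Chem.MolToSmiles(Chem.RemoveHs(a.mol)) == Chem.MolToSmiles(
            Chem.RemoveHs(b.mol)
        )
        assert b.raw_tags["note"] == "kept verbatim"


def test_sdf_round_trip_keeps_3d_coordinates():
    from conftest import make_3d_record

    rec = make_3d_record("CCO", "ethanol3d")
    lib = Library(records=[rec], name="one")
    import tempfile, pathlib

    with tempfile.TemporaryDirectory() as d:
        out = pathlib.Path(d) / "e.sdf"
        write_library(lib, out, format="sdf")
        back = read_library(out)
    a = rec.mol.GetConformer()
    b = back.records[0].mol.GetConformer()
    for i in range(rec.mol.GetNumAtoms()):
        for u, v in zip(a.GetAtomPosition(i), b.GetAtomPosition(i)):
            assert abs(u - v) < 5e-5  # molblocks carry 4 decimal places


def test_table_round_trip(tmp_path, boundary):
    lib, truths = boundary
    vectors = Library(
        records=[r for r in lib.records if r.mol is None],
        name="vectors", tag_schema=lib.tag_schema,
    )
    out = tmp_path / "vectors.tsv"
    write_library(vectors, out, format="table")
    header = out.read_text().splitlines()[0].split("\t")
    assert header[0] == "record_id"
    back = read_library(out, format="table")
    assert back.record_ids() == vectors.record_ids()
    dv = extract_descriptors(back.records[0], DEFAULT_TAG_SCHEMA)
    truth = truths[0]
    for name, value in truth.descriptors.items():
        assert dv[name] == pytest.approx(value)


def test_empty_library_refused_for_writing(tmp_path):
    with pytest.raises(LibraryError):
        write_library(Library(records=[]), tmp_path / "x.sdf")


class TestTagExtraction:
    schema = {
        "MW": TagSpec("MW", "Da", "real"),
        "QPlogPo/w": TagSpec("logP", "log units", "real"),
        "HBD": TagSpec("HBD", "count", "count"),
    }

    def rec(self, tags):
        return MoleculeRecord(record_id="r", raw_tags=tags)

    def test_matching_tag_coerced(self):
        dv = extract_descriptors(self.rec({"QPlogPo/w": "3.99"}), self.schema)
        assert dv["logP"] == 3.99
        assert dv.provenance["logP"] == "imported"

    def test_unparseable_value_degrades_to_missing(self):
        dv = extract_descriptors(self.rec({"MW": "abc"}), self.schema)
        assert "MW" not in dv

    def test_fractional_count_accepted_as_real(self):
        # library-average rows legitimately carry HBD values like 1.67
        dv = extract_descriptors(self.rec({"HBD": "1.67"}), self.schema)
        assert dv["HBD"] == 1.67

    def test_unmatched_and_empty_tags_ignored(self):
        dv = extract_descriptors(
            self.rec({"unknown": "5", "MW": "  "}), self.schema
        )
        assert len(dv) == 0

    def test_scientific_notation_accepted(self):
        dv = extract_descriptors(self.rec({"MW": "4.06e2"}), self.schema)
        assert math.isclose(dv["MW"], 406.0)


def test_load_tag_schema_yaml(tmp_path):
    p = tmp_path / "schema.yaml"
    p.write_text(
        "MW_tag:\n  descriptor: MW\n  unit: Da\n  kind: real\n"
    )
    schema = load_tag_schema(p)
    assert schema["MW_tag"].descriptor == "MW"
    bad = tmp_path / "bad.yaml"
    bad.write_text("X:\n  descriptor: not_a_descriptor\n")
    with pytest.raises(KeyError):
        load_tag_schema(bad)
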