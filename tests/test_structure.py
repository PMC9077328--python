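"""Structure loading, profile-to-structure mapping, and .pml emission."""

import re

import gemmi
import pytest

from missensemap.errors import ConfigurationError
from missensemap.profile import aggregate_by_residue
from missensemap.structure import (
    StyleSpec,
    emit_viewer_script,
    load_structure,
    map_profile,
    overlay_pathogenic,
    parse_viewer_script,
    write_mapping_report,
)
from missensemap.synth import generate_toy_structure
from missensemap.variants import VariantRecord


def _profile(position_afs, length):
    records = [
        VariantRecord(
            protein_id="P", hgvs_p=f"p.Ala{p}Val", ref_aa="A", position=p,
            alt_aa="V", vep_annotation="missense_variant", allele_count=1,
            allele_number=100000, allele_frequency=af,
        )
        for p, af in position_afs
    ]
    return aggregate_by_residue(records, length)


@pytest.fixture
def toy_pdb(tmp_path):
    return generate_toy_structure(10, plddt_profile=[90.0] * 10,
                                  out=tmp_path / "toy.pdb")


class TestLoadStructure:
    def test_pdb_round_trip(self, tmp_path):
        path = generate_toy_structure(3, out=tmp_path / "t3.pdb")
        model = load_structure(path)
        assert model.chains == ["A"]
        assert sorted(k[1] for k in model.residues) == [1, 2, 3]
        assert all(r.has_ca for r in model.residues.values())

    def test_mmcif_gives_identical_residue_index(self, tmp_path):
        pdb = generate_toy_structure(5, plddt_profile=[90, 65, 90, 40, 80],
                                     out=tmp_path / "t5.pdb")
        cif = generate_toy_structure(5, plddt_profile=[90, 65, 90, 40, 80],
                                     out=tmp_path / "t5.cif")
        a, b = load_structure(pdb), load_structure(cif)
        assert set(a.residues) == set(b.residues)
        for key in a.residues:
            assert a.residues[key].has_ca == b.residues[key].has_ca
            assert a.residues[key].b_factor == pytest.approx(
                b.residues[key].b_factor, abs=0.01
            )

    def test_residue_without_ca_flagged(self, tmp_path):
        path = generate_toy_structure(3, out=tmp_path / "t.pdb")
        st = gemmi.read_structure(str(path))
        st[0]["A"][1][0].name = "CB"  # second residue loses its CA
        out = tmp_path / "noca.pdb"
        st.write_pdb(str(out))
        model = load_structure(out)
        assert model.residue("A", 1).has_ca
        assert not model.residue("A", 2).has_ca

    def test_unparseable_file_raises_format_error(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("this is not a structure\n")
        from missensemap.errors import DataError
        with pytest.raises(DataError):
            load_structure(bad)


class TestMapProfile:
    def test_plddt_above_threshold_mapped(self, tmp_path):
        path = generate_toy_structure(10, plddt_profile=[90.0] * 10,
                                      out=tmp_path / "m.pdb")
        profile = _profile([(10, 1e-4)], 20)
        ann = map_profile(profile, load_structure(path), "A", plddt_min=70.0)
        assert ann.mapped == [(10, 10, 2)]

    def test_plddt_at_or_below_threshold_unmapped(self, tmp_path):
        path = generate_toy_structure(10, plddt_profile=[90.0] * 9 + [65.0],
                                      out=tmp_path / "m.pdb")
        profile = _profile([(10, 1e-4)], 20)
        ann = map_profile(profile, load_structure(path), "A", plddt_min=70.0)
        assert ann.mapped == []
        assert ann.unmapped_positions == [(10, "plddt_below_threshold")]

    def test_masking_off_when_plddt_min_unset(self, tmp_path):
        path = generate_toy_structure(10, plddt_profile=[10.0] * 10,
                                      out=tmp_path / "m.pdb")
        profile = _profile([(4, 1e-4)], 20)
        ann = map_profile(profile, load_structure(path), "A")
        assert len(ann.mapped) == 1

    def test_negative_offset_targets_shifted_residue(self, toy_pdb):
        profile = _profile([(10, 1e-3)], 20)
        ann = map_profile(profile, load_structure(toy_pdb), "A", offset=-5)
        assert ann.mapped == [(10, 5, 3)]

    def test_absent_residue_reported(self, toy_pdb):
        profile = _profile([(15, 1e-3)], 20)
        ann = map_profile(profile, load_structure(toy_pdb), "A")
        assert ann.unmapped_positions == [(15, "absent_residue")]

    def test_unknown_chain_raises(self, toy_pdb):
        profile = _profile([(1, 1e-3)], 20)
        with pytest.raises(ConfigurationError, match="chain"):
            map_profile(profile, load_structure(toy_pdb), "Z")

    def test_every_position_in_exactly_one_of_mapped_or_unmapped(self, tmp_path):
        path = generate_toy_structure(30, plddt_profile=[90, 60] * 15,
                                      out=tmp_path / "m.pdb")
        profile = _profile([(p, 1e-4) for p in range(1, 41, 3)], 50)
        ann = map_profile(profile, load_structure(path), "A", plddt_min=70.0)
        mapped = {p for p, _, _ in ann.mapped}
        unmapped = {p for p, _ in ann.unmapped_positions}
        assert mapped | unmapped == set(profile.positions())
        assert mapped & unmapped == set()

    def test_insertion_codes_refuse_integer_offset_mapping(self, tmp_path):
        path = generate_toy_structure(3, out=tmp_path / "t.pdb")
        st = gemmi.read_structure(str(path))
        st[0]["A"][1].seqid = gemmi.SeqId(1, "A")  # residue 1A
        out = tmp_path / "icode.pdb"
        st.write_pdb(str(out))
        profile = _profile([(1, 1e-3)], 5)
        with pytest.raises(ConfigurationError, match="insertion"):
            map_profile(profile, load_structure(out), "A")


class TestPathogenicOverlay:
    def test_mapped_position_appears_in_overlay(self, toy_pdb):
        profile = _profile([(2, 1e-4)], 20)
        model = load_structure(toy_pdb)
        ann = map_profile(profile, model, "A")
        ann2 = overlay_pathogenic(ann, [(5, "CSS")], model, "A")
        assert ann2.pathogenic_mapped == [(5, 5, "CSS")]

    def test_absent_position_reported_not_fatal(self, toy_pdb):
        profile = _profile([(2, 1e-4)], 20)
        model = load_structure(toy_pdb)
        ann = map_profile(profile, model, "A")
        ann2 = overlay_pathogenic(ann, [(18, "DDD")], model, "A")
        assert ann2.pathogenic_mapped == []
        assert ann2.pathogenic_unmapped == [(18, "absent_residue")]

    def test_empty_list_leaves_annotation_unchanged(self, toy_pdb):
        profile = _profile([(2, 1e-4)], 20)
        model = load_structure(toy_pdb)
        ann = map_profile(profile, model, "A")
        ann2 = overlay_pathogenic(ann, [], model, "A")
        assert ann2.mapped == ann.mapped
        assert ann2.pathogenic_mapped == []


class TestScriptEmission:
    def test_one_selection_per_nonempty_bin(self, toy_pdb, tmp_path):
        profile = _profile([(1, 1e-7), (2, 0.9)], 10)  # bins 1 and 6 only
        ann = map_profile(profile, load_structure(toy_pdb), "A")
        out = emit_viewer_script(ann, StyleSpec(), toy_pdb, tmp_path / "v.pml")
        selections = parse_viewer_script(out)
        assert sorted(selections) == ["bin1_af_le_1e-05", "bin6_af_1e-01_to_1"]

    def test_empty_annotation_emits_base_commands_only(self, toy_pdb, tmp_path):
        profile = _profile([], 10)
        ann = map_profile(profile, load_structure(toy_pdb), "A")
        out = emit_viewer_script(ann, StyleSpec(), toy_pdb, tmp_path / "v.pml")
        text = out.read_text()
        assert "load" in text
        assert not any(l.startswith("select ") for l in text.splitlines())

    def test_parse_back_matches_brute_force_expected_selection(self, toy_pdb, tmp_path):
        # three positions, all falling in bin 4, offset +2
        profile = _profile([(1, 5e-3), (3, 2e-3), (6, 9e-3)], 10)
        ann = map_profile(profile, load_structure(toy_pdb), "A", offset=2)
        out = emit_viewer_script(ann, StyleSpec(), toy_pdb, tmp_path / "v.pml")
        selections = parse_viewer_script(out)
        expected = {p + 2 for p in (1, 3, 6)}  # independent offset arithmetic
        assert selections == {"bin4_af_1e-03_to_1e-02": expected}

    def test_byte_identical_across_runs(self, toy_pdb, tmp_path):
        profile = _profile([(p, 10 ** (-6 + p * 0.5)) for p in range(1, 9)], 10)
        ann = map_profile(profile, load_structure(toy_pdb), "A")
        a = emit_viewer_script(ann, StyleSpec(), toy_pdb, tmp_path / "a.pml")
        b = emit_viewer_script(ann, StyleSpec(), toy_pdb, tmp_path / "b.pml")
        assert a.read_bytes() == b.read_bytes()

    def test_sphere_radius_non_decreasing_in_emitted_script(self, toy_pdb, tmp_path):
        profile = _profile([(p, 10 ** (-7 + p)) for p in range(1, 8)], 10)
        ann = map_profile(profile, load_structure(toy_pdb), "A")
        out = emit_viewer_script(ann, StyleSpec(), toy_pdb, tmp_path / "v.pml")
        radii = [float(m) for m in re.findall(r"vdw=([0-9.]+)", out.read_text())]
        assert radii == sorted(radii)

    def test_pathogenic_selection_distinct_from_bins(self, toy_pdb, tmp_path):
        profile = _profile([(2, 1e-4)], 10)
        model = load_structure(toy_pdb)
        ann = overlay_pathogenic(
            map_profile(profile, model, "A"), [(7, "var")], model, "A"
        )
        out = emit_viewer_script(ann, StyleSpec(), toy_pdb, tmp_path / "v.pml")
        selections = parse_viewer_script(out)
        assert selections["pathogenic"] == {7}
        assert "color_pathogenic" in out.read_text()


class TestStyleSpec:
    def test_default_radii_non_decreasing(self):
        style = StyleSpec()
        assert list(style.radii) == sorted(style.radii)

    def test_decreasing_radii_rejected(self):
        with pytest.raises(ValueError):
            StyleSpec(radii=(2.8, 2.4, 2.0, 1.6, 1.2, 0.8))

    def test_wrong_cardinality_rejected(self):
        with pytest.raises(ValueError):
            StyleSpec(radii=(1.0, 2.0))


def test_mapping_report_lists_every_position(toy_pdb, tmp_path):
    profile = _profile([(2, 1e-4), (15, 1e-4)], 20)
    ann = map_profile(profile, load_structure(toy_pdb), "A")
    path = tmp_path / "report.tsv"
    write_mapping_report(ann, path)
    lines = path.read_text().splitlines()[1:]
    assert len(lines) == 2
    statuses = {l.split("\t")[0]: l.split("\t")[2] for l in lines}
    assert statuses == {"2": "mapped", "15": "unmapped"}
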