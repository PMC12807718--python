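"""Validation pipeline: schema, chemistry, cross-reference and dataset stages."""

import json

import pytest

from mitekit.model import Dataset, Entry
from mitekit.validation import (ERROR, WARNING, validate_chemistry,
                                validate_crossrefs, validate_dataset,
                                validate_entry, validate_schema)


def build(minimal_entry_kwargs, **overrides):
    raw = json.loads(json.dumps(minimal_entry_kwargs))
    raw.update(overrides)
    return raw


class TestSchemaStage:
    def test_complete_entry_passes(self, minimal_entry_kwargs):
        entry = Entry.model_validate(build(minimal_entry_kwargs))
        assert validate_schema(entry).is_valid

    def test_zero_reactions_reported_at_path(self, minimal_entry_kwargs):
        raw = build(minimal_entry_kwargs, reactions=[])
        broken = Entry.model_construct(**raw)  # bypass constructor invariants
        report = validate_schema(broken)
        assert any(r.level == ERROR and r.path == "reactions"
                   for r in report.stage_results)

    def test_missing_sequence_reference_is_error(self, minimal_entry_kwargs):
        raw = build(minimal_entry_kwargs)
        raw["enzyme"] = {"name": "NoSeq"}
        report = validate_schema(Entry.model_construct(**raw))
        assert any("sequence reference missing" in r.message
                   for r in report.errors())

    def test_unknown_tailoring_term_is_error(self, minimal_entry_kwargs):
        raw = build(minimal_entry_kwargs)
        raw["reactions"][0]["tailoring_terms"] = ["Transmogrification"]
        report = validate_schema(Entry.model_construct(**raw))
        assert any("Transmogrification" in r.message for r in report.errors())

    def test_all_violations_reported_no_short_circuit(self, minimal_entry_kwargs):
        raw = build(minimal_entry_kwargs, accession="MITE42", references=[])
        raw["enzyme"] = {"name": ""}
        report = validate_schema(Entry.model_construct(**raw))
        paths = {r.path for r in report.errors()}
        assert {"accession", "references", "enzyme.name"} <= paths


class TestChemistryStage:
    def test_fixture_halogenase_style_entry_passes(self, minimal_entry_kwargs):
        entry = Entry.model_validate(build(minimal_entry_kwargs))
        assert validate_chemistry(entry).is_valid

    def test_swapped_product_fails_naming_example_and_smiles(self, minimal_entry_kwargs):
        raw = build(minimal_entry_kwargs)
        raw["reactions"][0]["examples"][0]["products"] = ["c1ccncc1"]
        entry = Entry.model_validate(raw)
        report = validate_chemistry(entry)
        errors = report.errors()
        assert len(errors) == 1
        # failure message carries expected and generated canonical SMILES
        assert "c1ccncc1" in errors[0].message
        assert "CCc1ccc(OC)cc1" in errors[0].message
        assert "examples.0" in errors[0].path

    def test_wildcard_substrate_with_r_group_rule_passes(self, minimal_entry_kwargs):
        raw = build(minimal_entry_kwargs)
        raw["reactions"][0].update(
            smarts="[NX3;H2:1][CH:2]>>[N;H1:1](C)[CH:2]",
            examples=[{"substrate": "*CC(N)C(=O)O", "products": ["*CC(NC)C(=O)O"]}])
        entry = Entry.model_validate(raw)
        assert validate_chemistry(entry).is_valid

    def test_dialect_smarts_rejected_with_rule_path(self, minimal_entry_kwargs):
        entry = Entry.model_validate(build(minimal_entry_kwargs))
        bad_rule = entry.reactions[0].model_copy(
            update={"smarts": "[C:1]>>[C:1]O |x|"})
        entry = entry.model_copy(update={"reactions": [bad_rule]})
        report = validate_chemistry(entry)
        assert any(r.path == "reactions.0.smarts" for r in report.errors())


class TestCrossrefStage:
    def test_wellformed_identifiers_pass(self, minimal_entry_kwargs):
        raw = build(minimal_entry_kwargs)
        raw["enzyme"]["mibig_id"] = "BGC0000469"
        raw["reactions"][0]["ec_number"] = "1.14.19.-"
        report = validate_crossrefs(Entry.model_validate(raw))
        assert report.is_valid

    @pytest.mark.parametrize("bad_ec", ["1.14", "1.14.19", "a.b.c.d", "1..1.1"])
    def test_malformed_ec_number_is_error(self, minimal_entry_kwargs, bad_ec):
        raw = build(minimal_entry_kwargs)
        raw["reactions"][0]["ec_number"] = bad_ec
        report = validate_crossrefs(Entry.model_validate(raw))
        assert any("EC number" in r.message for r in report.errors())

    def test_neither_mibig_nor_rhea_warns_uncrossreferenced(self, minimal_entry_kwargs):
        entry = Entry.model_validate(build(minimal_entry_kwargs))
        report = validate_crossrefs(entry)
        assert any("uncrossreferenced" in r.message for r in report.warnings())

    def test_mibig_presence_suppresses_uncrossreferenced_warning(self, minimal_entry_kwargs):
        raw = build(minimal_entry_kwargs)
        raw["enzyme"]["mibig_id"] = "BGC0000469"
        report = validate_crossrefs(Entry.model_validate(raw))
        assert not any("uncrossreferenced" in r.message for r in report.warnings())


class TestDatasetStage:
    def test_generated_fixtures_validate_with_zero_errors(self, dataset):
        reports, summary = validate_dataset(dataset)
        assert summary[ERROR] == 0
        assert all(r.is_valid for r in reports)

    def test_bottromycin_fixture_validates_with_zero_errors(self, bot):
        reports, summary = validate_dataset(Dataset(bot.entries))
        assert summary[ERROR] == 0

    def test_duplicate_primary_sequence_reference_warns(self, minimal_entry_kwargs):
        a = build(minimal_entry_kwargs)
        b = build(minimal_entry_kwargs, accession="MITE9999002")
        reports, _ = validate_dataset(Dataset([Entry.model_validate(a),
                                               Entry.model_validate(b)]))
        dup = [r for rep in reports for r in rep.stage_results
               if "isoform" in r.message]
        assert len(dup) == 1

    def test_summary_counts_one_broken_entry(self, minimal_entry_kwargs, dataset):
        raw = build(minimal_entry_kwargs, accession="MITE9999099")
        raw["reactions"][0]["examples"][0]["products"] = ["c1ccncc1"]
        broken = Entry.model_validate(raw)
        ds = Dataset(list(dataset) + [broken])
        _, summary = validate_dataset(ds)
        assert summary[ERROR] == 1
        assert summary["pass"] + summary[WARNING] == len(dataset)

    def test_validation_is_deterministic_and_side_effect_free(self, dataset):
        first, s1 = validate_dataset(dataset)
        second, s2 = validate_dataset(dataset)
        assert s1 == s2
        assert [r.stage_results for r in first] == [r.stage_results for r in second]


def test_validate_entry_merges_all_three_stages(minimal_entry_kwargs, bot):
    report = validate_entry(bot.entries[0])
    stages = {r.stage for r in report.stage_results}
    assert {"chemistry", "crossref"} <= stages
    assert report.is_valid
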