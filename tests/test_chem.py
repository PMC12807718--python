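"""Chemistry engine: canonicalization, rule standardization and application."""

import random

import pytest
from rdkit import Chem

from mitekit.chem import (MatchPolicy, apply_rule, canonicalize,
                          match_products, standardize_rule, strip_stereo,
                          substructure_match)
from mitekit.errors import ChemistryError, RuleError

FIXTURE_MOLECULES = [
    "CC(N)C(=O)O",                        # alanine
    "NC(Cc1c[nH]c2ccccc12)C(=O)O",        # tryptophan
    "Oc1ccc(CCN)cc1",                     # tyramine
    "C[C@H](N)C(=O)O",                    # L-alanine (stereo)
    "*CC(N)C(=O)O",                       # R-group substrate
    "CC(=O)NC1CCCCC1",                    # amide
]

TRP_5_HALOGENATION = (
    "[NX3;H2:1][CH:2]([CH2:3][c:4]1[cH:5][nH:6][c:7]2[cH:8][cH:9][cH:10]"
    "[cH:11][c:12]12)[C:13](=[O:14])[OX2;H1:15]>>"
    "[NX3;H2:1][CH:2]([CH2:3][c:4]1[cH:5][nH:6][c:7]2[cH:8][cH:9][c:10](Cl)"
    "[cH:11][c:12]12)[C:13](=[O:14])[OX2;H1:15]"
)


def random_respelling(smiles: str, seed: int) -> str:
    """A different SMILES spelling of the same molecule (atom renumbering)."""
    mol = Chem.MolFromSmiles(smiles)
    order = list(range(mol.GetNumAtoms()))
    random.Random(seed).shuffle(order)
    return Chem.MolToSmiles(Chem.RenumberAtoms(mol, order), canonical=False)


class TestCanonicalize:
    def test_two_spellings_of_same_molecule_agree(self):
        assert canonicalize("OC(=O)C(N)C") == canonicalize("CC(N)C(O)=O")

    def test_wildcard_atoms_preserved(self):
        assert "*" in canonicalize("*CC(N)C(=O)O")

    def test_unparsable_raises(self):
        with pytest.raises(ChemistryError):
            canonicalize("C(")

    @pytest.mark.parametrize("smiles", FIXTURE_MOLECULES)
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fixed_point_over_random_atom_orderings(self, smiles, seed):
        respelled = random_respelling(smiles, seed)
        canonical = canonicalize(smiles)
        assert canonicalize(respelled) == canonical
        assert canonicalize(canonical) == canonical


class TestStandardizeRule:
    def test_plain_rule_accepted(self):
        std = standardize_rule("[C:1]>>[C:1]O")
        assert std.value.count(">>") == 1
        assert not std.had_dialect_extensions

    def test_dialect_extension_block_rejected(self):
        with pytest.raises(RuleError) as exc:
            standardize_rule("[C:1]>>[C:1]O |^1:0|")
        assert "dialect" in str(exc.value)

    def test_single_separator_normalized_to_two_sided(self):
        # reactants>agents>products with empty agents equals reactants>>products
        assert standardize_rule("CC>CC").value == standardize_rule("CC>>CC").value

    def test_explicit_empty_agent_field_normalized(self):
        assert standardize_rule("CC>>CO").value == "CC>>CO"

    @pytest.mark.parametrize("bad", ["CC", ">>CC", "CC>>", "C>C>C>C",
                                     "CC>O>CC"])
    def test_malformed_rules_rejected(self, bad):
        with pytest.raises(RuleError):
            standardize_rule(bad)


class TestApplyRule:
    @pytest.mark.parametrize("smiles", FIXTURE_MOLECULES)
    def test_identity_rule_is_identity_on_canonical_form(self, smiles):
        products = apply_rule("[C:1]>>[C:1]", smiles)
        assert products
        expected = canonicalize(smiles)
        for tup in products:
            assert list(tup) == [expected]

    def test_tryptophan_5_halogenation(self):
        products = apply_rule(TRP_5_HALOGENATION, "NC(Cc1c[nH]c2ccccc12)C(=O)O")
        assert sorted(products.tuples) == [
            (canonicalize("NC(Cc1c[nH]c2ccc(Cl)cc12)C(=O)O"),)]

    def test_non_substrate_gives_empty_product_set(self):
        assert len(apply_rule(TRP_5_HALOGENATION, "NCC(=O)O")) == 0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_output_invariant_to_substrate_spelling(self, seed):
        trp = "NC(Cc1c[nH]c2ccccc12)C(=O)O"
        a = apply_rule(TRP_5_HALOGENATION, trp)
        b = apply_rule(TRP_5_HALOGENATION, random_respelling(trp, seed))
        assert a.tuples == b.tuples

    def test_symmetry_distinct_matches_all_enumerated(self):
        # meta-cresol has two distinct ortho positions relative to the OH
        products = apply_rule("[c:1]([OX2;H1:2])[cH:3]>>[c:1]([OX2;H1:2])[c:3]Cl",
                              "Oc1cccc(C)c1")
        assert len(products) == 2


class TestMatchProducts:
    def test_canonical_equality(self):
        generated = apply_rule("[C:1]>>[C:1]", "CCO")
        assert match_products(generated, ["OCC"])[0]

    def test_wrong_product_fails_with_diagnostic(self):
        generated = apply_rule("[C:1]>>[C:1]", "CCO")
        ok, diag = match_products(generated, ["CCN"])
        assert not ok
        assert "CCN" in diag and "CCO" in diag

    def test_stereo_policy(self):
        generated = apply_rule("[C:1]>>[C:1]", "C[C@H](N)C(=O)O")
        strict = match_products(generated, ["CC(N)C(=O)O"])[0]
        agnostic = match_products(generated, ["CC(N)C(=O)O"],
                                  MatchPolicy(stereo_strict=False))[0]
        assert not strict and agnostic
        # independent check: stripping stereo makes the two spellings equal
        assert strip_stereo("C[C@H](N)C(=O)O") == canonicalize("CC(N)C(=O)O")

    def test_match_insensitive_to_product_order_and_spelling(self):
        generated = apply_rule(
            "[N;R:1][CH;R:2][C:3](=[O:4])[NH:5][CH2:6]>>"
            "([N;R:1][CH;R:2][C:3](=[O:4])[OH]).([NH2:5][CH2:6])",
            "O=C(NCC(=O)O)C1CCCN1C")
        expected = ["OC(=O)C1CCCN1C", "NCC(=O)O"]
        assert match_products(generated, expected)[0]
        assert match_products(generated, list(reversed(expected)))[0]

    def test_subset_policy_tolerates_unlisted_coproducts(self):
        generated = apply_rule(
            "[N;R:1][CH;R:2][C:3](=[O:4])[NH:5][CH2:6]>>"
            "([N;R:1][CH;R:2][C:3](=[O:4])[OH]).([NH2:5][CH2:6])",
            "O=C(NCC(=O)O)C1CCCN1C")
        partial = ["OC(=O)C1CCCN1C"]
        assert not match_products(generated, partial)[0]
        assert match_products(generated, partial, MatchPolicy(allow_subset=True))[0]


class TestSubstructureMatch:
    def test_peptide_bond_in_glycylglycine(self):
        assert substructure_match("NCC(=O)NCC(=O)O",
                                  "[CX3](=O)[NX3][CX4][CX3](=O)")

    def test_methane_has_no_peptide_bond(self):
        assert not substructure_match("C", "[CX3](=O)[NX3][CX4][CX3](=O)")

    @pytest.mark.parametrize("smiles", FIXTURE_MOLECULES)
    def test_universal_pattern_matches_everything(self, smiles):
        assert substructure_match(smiles, "[*]")

    def test_unparsable_pattern_raises(self):
        with pytest.raises(ChemistryError):
            substructure_match("CC", "[[")
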