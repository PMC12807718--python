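"""Molecule- and reaction-level chemistry.

All canonicalization, reaction-SMARTS standardization, rule application and
product matching used by the validator, the query engine and the biosynthesis
planner goes through this module. Reaction rules follow the generic Daylight
``reactants>>products`` grammar; proprietary dialect extensions (CXSMILES-style
``|...|`` blocks) are rejected rather than repaired.

Conventions
-----------
* Molecules are compared as canonical isomeric SMILES strings.
* Wildcard atoms (``*``) are zero-valence dummy atoms. They survive
  canonicalization and, during matching, satisfy only explicit wildcard query
  atoms — a ``*`` in an expected product never matches a concrete atom.
* Applying a rule enumerates *all* symmetry-distinct template matches and
  returns the deduplicated set of product tuples; product tuples that fail
  sanitization are dropped with a warning, not an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

from .errors import ChemistryError, RuleError

logger = logging.getLogger(__name__)

# RDKit is chatty on invalid input; we raise typed errors instead.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise ChemistryError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemistryError(f"unparsable SMILES: {smiles!r}")
    return mol


def canonicalize(smiles: str) -> str:
    """Return the canonical isomeric SMILES spelling of *smiles*.

    Stereochemistry is retained; wildcard atoms are preserved. The result is
    a fixed point: ``canonicalize(canonicalize(s)) == canonicalize(s)``.
    """
    return Chem.MolToSmiles(_mol_from_smiles(smiles))


def strip_stereo(smiles: str) -> str:
    """Canonical SMILES with all stereo descriptors removed."""
    return Chem.MolToSmiles(_mol_from_smiles(smiles), isomericSmiles=False)


@dataclass(frozen=True)
class StandardizedRule:
    """A generic reaction SMARTS accepted by the standard.

    ``value`` is the normalized two-sided form; ``had_dialect_extensions`` is
    always False for accepted rules (extension-bearing input is rejected, never
    silently repaired) and exists so reports can state the check ran.
    """

    value: str
    had_dialect_extensions: bool = False

    @property
    def smarts(self) -> str:
        return self.value

    def to_reaction(self) -> AllChem.ChemicalReaction:
        rxn = AllChem.ReactionFromSmarts(self.value)
        if rxn is None:  # pragma: no cover - standardization guarantees parse
            raise RuleError(f"rule no longer parses: {self.value!r}")
        return rxn


def standardize_rule(smarts: str) -> StandardizedRule:
    """Normalize a reaction SMARTS into the accepted generic form.

    Accepts ``reactants>>products`` and the three-part
    ``reactants>agents>products`` grammar with an *empty* agent field, which is
    equivalent; the two-part ``reactants>products`` spelling is normalized the
    same way. Rejection is explicit for: dialect extension blocks appended
    after a pipe character, missing separator, empty reactant side, and rules
    whose templates do not parse.
    """
    if not isinstance(smarts, str) or not smarts.strip():
        raise RuleError("empty reaction SMARTS")
    smarts = smarts.strip()
    if "|" in smarts:
        raise RuleError(
            "dialect extension rejected: CXSMILES-style '|...|' block in "
            f"{smarts!r}; only generic reaction SMARTS are accepted"
        )
    if ">" not in smarts:
        raise RuleError(f"malformed rule (no '>' separator): {smarts!r}")
    parts = smarts.split(">")
    if len(parts) == 2:
        reactants, agents, products = parts[0], "", parts[1]
    elif len(parts) == 3:
        reactants, agents, products = parts
    else:
        raise RuleError(f"malformed rule (too many '>' separators): {smarts!r}")
    if agents.strip():
        raise RuleError(
            f"agent templates are not part of the generic grammar: {smarts!r}"
        )
    if not reactants.strip():
        raise RuleError(f"empty reactant side: {smarts!r}")
    if not products.strip():
        raise RuleError(f"empty product side: {smarts!r}")
    two_sided = f"{reactants.strip()}>>{products.strip()}"
    rxn = AllChem.ReactionFromSmarts(two_sided)
    if rxn is None:
        raise RuleError(f"reaction SMARTS does not parse: {smarts!r}")
    if rxn.GetNumReactantTemplates() < 1 or rxn.GetNumProductTemplates() < 1:
        raise RuleError(
            f"rule must have at least one reactant and one product template: {smarts!r}"
        )
    return StandardizedRule(value=two_sided, had_dialect_extensions=False)


@dataclass(frozen=True)
class ProductSet:
    """Deduplicated product tuples from applying one rule to one substrate.

    Each tuple is sorted canonically; the set is empty iff the rule's reactant
    template did not match the substrate at all.
    """

    tuples: frozenset[tuple[str, ...]] = field(default_factory=frozenset)

    def __bool__(self) -> bool:
        return bool(self.tuples)

    def __len__(self) -> int:
        return len(self.tuples)

    def __iter__(self):
        return iter(sorted(self.tuples))

    def flat(self) -> list[str]:
        """All product SMILES across tuples, deduplicated, sorted."""
        return sorted({s for tup in self.tuples for s in tup})


def apply_rule(rule: StandardizedRule | str, substrate: str) -> ProductSet:
    """Apply a reaction rule to a substrate SMILES.

    Returns every distinct product tuple over all symmetry-distinct matches of
    the reactant template. A substrate the template does not recognize yields
    an empty :class:`ProductSet` — never an error. Tuples containing a product
    that fails sanitization are dropped with a logged warning.
    """
    if isinstance(rule, str):
        rule = standardize_rule(rule)
    mol = _mol_from_smiles(substrate)
    rxn = rule.to_reaction()
    if rxn.GetNumReactantTemplates() != 1:
        raise RuleError(
            "rule application supports single-reactant templates; got "
            f"{rxn.GetNumReactantTemplates()} in {rule.value!r}"
        )
    out: set[tuple[str, ...]] = set()
    for prod_tuple in rxn.RunReactants((mol,)):
        smis: list[str] = []
        ok = True
        for prod in prod_tuple:
            try:
                Chem.SanitizeMol(prod)
                smis.append(Chem.MolToSmiles(prod))
            except Exception as exc:  # kekulization/valence failures
                logger.warning(
                    "dropping product tuple: sanitization failed (%s) for rule %s "
                    "on substrate %s", exc, rule.value, substrate,
                )
                ok = False
                break
        if ok:
            out.add(tuple(sorted(smis)))
    return ProductSet(tuples=frozenset(out))


@dataclass(frozen=True)
class MatchPolicy:
    """Controls the equality relation used to verify example reactions.

    stereo_strict
        Compare canonical isomeric SMILES (default). If False, stereo
        descriptors are stripped on both sides before comparison.
    allow_subset
        If True, the expected products may be a sub-multiset of a generated
        tuple, tolerating unlisted co-products (e.g. water). Default off.
    """

    stereo_strict: bool = True
    allow_subset: bool = False


DEFAULT_POLICY = MatchPolicy()


def _counts(smiles_list, stereo_strict: bool) -> dict[str, int]:
    norm = canonicalize if stereo_strict else strip_stereo
    counts: dict[str, int] = {}
    for s in smiles_list:
        c = norm(s)
        counts[c] = counts.get(c, 0) + 1
    return counts


def match_products(
    generated: ProductSet,
    expected: list[str],
    policy: MatchPolicy = DEFAULT_POLICY,
) -> tuple[bool, str]:
    """Check whether some generated tuple equals the expected product multiset.

    Comparison is canonical-SMILES multiset equality under *policy*. Wildcard
    atoms compare literally: a ``*`` in an expected product matches only a
    ``*`` in a generated one. Returns ``(matched, diagnostic)`` where the
    diagnostic always carries both the expected and the generated canonical
    SMILES so curators can see what the rule actually produced.
    """
    if not expected:
        raise ChemistryError("expected product list must be non-empty")
    want = _counts(expected, policy.stereo_strict)
    norm = canonicalize if policy.stereo_strict else strip_stereo
    seen: list[str] = []
    for tup in generated:
        have: dict[str, int] = {}
        for s in tup:
            c = norm(s)
            have[c] = have.get(c, 0) + 1
        seen.append(".".join(sorted(have)))
        if have == want:
            return True, f"matched tuple {sorted(tup)}"
        if policy.allow_subset and all(
            have.get(k, 0) >= v for k, v in want.items()
        ):
            return True, f"expected products are a subset of tuple {sorted(tup)}"
    diag = (
        f"no generated product tuple matches; expected={sorted(want)} "
        f"generated={seen if seen else '[] (substrate not recognized)'}"
    )
    return False, diag


def substructure_match(smiles: str, pattern: str) -> bool:
    """Standard SMARTS substructure semantics."""
    mol = _mol_from_smiles(smiles)
    patt = Chem.MolFromSmarts(pattern)
    if patt is None:
        raise ChemistryError(f"unparsable SMARTS pattern: {pattern!r}")
    return mol.HasSubstructMatch(patt)


def parses(smiles: str) -> bool:
    """True iff *smiles* parses as a molecule."""
    return Chem.MolFromSmiles(smiles) is not None
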