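"""Searching and subsetting datasets.

A query is a finite expression tree of predicates combined with AND/OR/NOT.
Evaluation is pure: a predicate sees one entry (plus, for sequence
predicates, the bundled sequences) and returns whether it matched together
with provenance records saying *which* reaction/example produced the hit.

Predicate kinds
---------------
* field-equals / field-contains on dotted field paths,
* tailoring-term membership,
* has-crossref(kind) for mibig/rhea/ec/uniprot/genbank/wikidata,
* substructure(smarts, scope in {substrates, products, both}) over all
  example reactions of all rules,
* reaction-pattern(reaction SMARTS): the query's reactant pattern must hit an
  example substrate AND its product pattern must hit a product of the *same*
  example,
* sequence-similarity(sequence, min_identity) via local alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Any, Optional

import pandas as pd
from rdkit import Chem

from . import align, chem
from .errors import QueryError
from .model import Dataset, Entry


@dataclass(frozen=True)
class Provenance:
    predicate: str
    detail: str
    rule_index: Optional[int] = None
    example_index: Optional[int] = None


class Predicate:
    """Base class; subclasses implement :meth:`matches`."""

    def check(self) -> None:
        """Validate predicate arguments (e.g. SMARTS parse) before evaluation."""

    def matches(self, entry: Entry, sequences: dict[str, str]) -> tuple[bool, list[Provenance]]:
        raise NotImplementedError

    def __and__(self, other: "Predicate") -> "And":
        return And(self, other)

    def __or__(self, other: "Predicate") -> "Or":
        return Or(self, other)

    def __invert__(self) -> "Not":
        return Not(self)


@dataclass(frozen=True)
class MatchAll(Predicate):
    def matches(self, entry, sequences):
        return True, []


@dataclass(frozen=True)
class FieldEquals(Predicate):
    path: str
    value: Any

    def matches(self, entry, sequences):
        got = _resolve(entry.to_dict(), self.path)
        hit = any(v == self.value for v in got)
        prov = [Provenance("field-equals", f"{self.path} == {self.value!r}")] if hit else []
        return hit, prov


@dataclass(frozen=True)
class FieldContains(Predicate):
    path: str
    value: str

    def matches(self, entry, sequences):
        got = _resolve(entry.to_dict(), self.path)
        hit = any(isinstance(v, str) and self.value.lower() in v.lower() for v in got)
        prov = [Provenance("field-contains", f"{self.value!r} in {self.path}")] if hit else []
        return hit, prov


@dataclass(frozen=True)
class TailoringTerm(Predicate):
    term: str

    def matches(self, entry, sequences):
        prov = [
            Provenance("tailoring-term", self.term, rule_index=i)
            for i, rule in enumerate(entry.reactions)
            if self.term in rule.tailoring_terms
        ]
        return bool(prov), prov


_CROSSREF_KINDS = {"mibig", "rhea", "ec", "uniprot", "genbank", "wikidata"}


@dataclass(frozen=True)
class HasCrossref(Predicate):
    kind: str

    def check(self) -> None:
        if self.kind not in _CROSSREF_KINDS:
            raise QueryError(f"unknown crossref kind {self.kind!r}; expected one of {sorted(_CROSSREF_KINDS)}")

    def matches(self, entry, sequences):
        enzyme = entry.enzyme
        if self.kind == "mibig":
            hit = enzyme.mibig_id is not None
            detail = enzyme.mibig_id
        elif self.kind == "uniprot":
            hit = enzyme.uniprot_id is not None
            detail = enzyme.uniprot_id
        elif self.kind == "genbank":
            hit = enzyme.genbank_id is not None
            detail = enzyme.genbank_id
        elif self.kind == "wikidata":
            hit = enzyme.wikidata_id is not None
            detail = enzyme.wikidata_id
        elif self.kind == "rhea":
            hit = any(r.rhea_id is not None for r in entry.reactions)
            detail = next((r.rhea_id for r in entry.reactions if r.rhea_id), None)
        else:  # ec
            hit = any(r.ec_number is not None for r in entry.reactions)
            detail = next((r.ec_number for r in entry.reactions if r.ec_number), None)
        prov = [Provenance("has-crossref", f"{self.kind}={detail}")] if hit else []
        return hit, prov


@dataclass(frozen=True)
class Substructure(Predicate):
    smarts: str
    scope: str = "both"  # substrates | products | both

    def check(self) -> None:
        if self.scope not in {"substrates", "products", "both"}:
            raise QueryError(f"invalid substructure scope {self.scope!r}")
        if Chem.MolFromSmarts(self.smarts) is None:
            raise QueryError(f"unparsable SMARTS in substructure predicate: {self.smarts!r}")

    def matches(self, entry, sequences):
        prov = []
        for i, rule in enumerate(entry.reactions):
            for j, ex in enumerate(rule.examples):
                targets = []
                if self.scope in ("substrates", "both"):
                    targets.append(("substrate", ex.substrate))
                if self.scope in ("products", "both"):
                    targets.extend(("product", p) for p in ex.products)
                for role, smi in targets:
                    try:
                        if chem.substructure_match(smi, self.smarts):
                            prov.append(Provenance("substructure", f"{role} {smi}", i, j))
                            break
                    except chem.ChemistryError:
                        continue
        return bool(prov), prov


@dataclass(frozen=True)
class ReactionPattern(Predicate):
    reaction_smarts: str

    def _patterns(self):
        parts = self.reaction_smarts.split(">>")
        if len(parts) != 2:
            raise QueryError(
                f"reaction-pattern predicate needs 'reactants>>products': {self.reaction_smarts!r}")
        r = Chem.MolFromSmarts(parts[0])
        p = Chem.MolFromSmarts(parts[1])
        if r is None or p is None:
            raise QueryError(f"unparsable reaction SMARTS in predicate: {self.reaction_smarts!r}")
        return r, p

    def check(self) -> None:
        self._patterns()

    def matches(self, entry, sequences):
        rpat, ppat = self._patterns()
        prov = []
        for i, rule in enumerate(entry.reactions):
            for j, ex in enumerate(rule.examples):
                sub = Chem.MolFromSmiles(ex.substrate)
                if sub is None or not sub.HasSubstructMatch(rpat):
                    continue
                for p in ex.products:
                    pm = Chem.MolFromSmiles(p)
                    if pm is not None and pm.HasSubstructMatch(ppat):
                        prov.append(Provenance("reaction-pattern",
                                               f"{ex.substrate}>>{p}", i, j))
                        break
        return bool(prov), prov


@dataclass(frozen=True)
class SequenceSimilarity(Predicate):
    sequence: str
    min_identity: float

    def check(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise QueryError("min_identity must be in (0, 1]")
        if not self.sequence.strip():
            raise QueryError("empty query sequence")

    def matches(self, entry, sequences):
        subject = sequences.get(entry.accession)
        if subject is None:
            return False, []
        identity, score = align.local_identity(self.sequence, subject)
        if identity >= self.min_identity:
            return True, [Provenance("sequence-similarity",
                                     f"identity={identity:.4f} score={score:g}")]
        return False, []


@dataclass(frozen=True)
class And(Predicate):
    operands: tuple[Predicate, ...]

    def __init__(self, *operands: Predicate):
        object.__setattr__(self, "operands", tuple(operands))

    def check(self) -> None:
        for op in self.operands:
            op.check()

    def matches(self, entry, sequences):
        prov: list[Provenance] = []
        for op in self.operands:
            ok, p = op.matches(entry, sequences)
            if not ok:
                return False, []
            prov.extend(p)
        return True, prov


@dataclass(frozen=True)
class Or(Predicate):
    operands: tuple[Predicate, ...]

    def __init__(self, *operands: Predicate):
        object.__setattr__(self, "operands", tuple(operands))

    def check(self) -> None:
        for op in self.operands:
            op.check()

    def matches(self, entry, sequences):
        prov: list[Provenance] = []
        hit = False
        for op in self.operands:
            ok, p = op.matches(entry, sequences)
            hit = hit or ok
            prov.extend(p)
        return hit, prov


@dataclass(frozen=True)
class Not(Predicate):
    operand: Predicate

    def check(self) -> None:
        self.operand.check()

    def matches(self, entry, sequences):
        ok, _ = self.operand.matches(entry, sequences)
        return not ok, []


@dataclass
class EntryTable:
    """Tabular query result; rows sorted by accession, with match provenance."""

    rows: list[dict[str, Any]] = dc_field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def accessions(self) -> list[str]:
        return [r["accession"] for r in self.rows]

    def to_frame(self) -> pd.DataFrame:
        cols = ["accession", "enzyme_name", "tailoring_terms", "crossrefs",
                "identity", "score", "provenance"]
        df = pd.DataFrame(self.rows)
        for c in cols:
            if c not in df.columns:
                df[c] = None
        return df[cols]

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False)


def _resolve(d: Any, path: str) -> list[Any]:
    """All values at a dotted path; lists fan out."""
    parts = path.split(".")
    current = [d]
    for part in parts:
        nxt = []
        for node in current:
            if isinstance(node, list):
                node_items = node
            else:
                node_items = [node]
            for item in node_items:
                if isinstance(item, dict) and part in item:
                    nxt.append(item[part])
        current = nxt
    out = []
    for v in current:
        if isinstance(v, list):
            out.extend(v)
        else:
            out.append(v)
    return out


def _row(entry: Entry, prov: list[Provenance], **extra: Any) -> dict[str, Any]:
    terms = sorted({t for r in entry.reactions for t in r.tailoring_terms})
    crossrefs = []
    if entry.enzyme.mibig_id:
        crossrefs.append(f"mibig:{entry.enzyme.mibig_id}")
    if entry.enzyme.uniprot_id:
        crossrefs.append(f"uniprot:{entry.enzyme.uniprot_id}")
    if entry.enzyme.genbank_id:
        crossrefs.append(f"genbank:{entry.enzyme.genbank_id}")
    for r in entry.reactions:
        if r.rhea_id:
            crossrefs.append(f"rhea:{r.rhea_id}")
        if r.ec_number:
            crossrefs.append(f"ec:{r.ec_number}")
    row = {
        "accession": entry.accession,
        "enzyme_name": entry.enzyme.name,
        "tailoring_terms": ";".join(terms),
        "crossrefs": ";".join(crossrefs),
        "provenance": ";".join(
            f"{p.predicate}[{'' if p.rule_index is None else p.rule_index}]:{p.detail}"
            for p in prov),
    }
    row.update(extra)
    return row


def evaluate(dataset: Dataset, query: Predicate,
             sequences: Optional[dict[str, str]] = None) -> EntryTable:
    """Evaluate a query tree over a dataset.

    Malformed predicates (e.g. unparsable SMARTS) raise :class:`QueryError`
    before any entry is examined.
    """
    query.check()
    sequences = sequences or {}
    rows = []
    for entry in dataset:  # dataset iterates in accession order
        ok, prov = query.matches(entry, sequences)
        if ok:
            rows.append(_row(entry, prov))
    return EntryTable(rows)


def sequence_search(dataset: Dataset, query_sequence: str, min_identity: float,
                    sequences: dict[str, str]) -> EntryTable:
    """Local-alignment similarity search over the dataset's sequences.

    Entries without an available sequence are skipped (not errors). Rows carry
    the alignment identity and score of the best local alignment.
    """
    if not (0 < min_identity <= 1):
        raise QueryError("min_identity must be in (0, 1]")
    rows = []
    for entry in dataset:
        subject = sequences.get(entry.accession)
        if subject is None:
            continue
        identity, score = align.local_identity(query_sequence, subject)
        if identity >= min_identity:
            prov = [Provenance("sequence-similarity",
                               f"identity={identity:.4f} score={score:g}")]
            rows.append(_row(entry, prov, identity=round(identity, 6), score=score))
    return EntryTable(rows)
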