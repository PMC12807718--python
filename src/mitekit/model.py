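"""Typed representation of MITE entries and datasets.

A MITE entry describes exactly one tailoring enzyme encoded by one gene (one
entry per protein isoform), carrying a permanent ``MITE`` + 7-digit accession,
a resolvable sequence cross-reference (UniProt or GenBank), at least one
reaction described as a generic reaction SMARTS with at least one concrete
example reaction, and at least one DOI to primary literature.

Entries live on disk as one JSON record per file, named ``<accession>.json``.
Parsing is lossless: unknown fields are preserved verbatim in ``extras`` so a
record round-trips byte-identically through ``parse_entry``/``serialize_entry``
even when the upstream schema has grown fields this package does not know.
"""

from __future__ import annotations

import json
import re
import tarfile
import zipfile
from pathlib import Path
from typing import Any, Iterator, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

from . import chem
from .errors import DatasetError, ParseError, SchemaError

ACCESSION_PATTERN = re.compile(r"^MITE\d{7}$")
RESERVED_ACCESSION = "MITE0000000"
MIBIG_PATTERN = re.compile(r"^BGC\d{7}$")
WIKIDATA_PATTERN = re.compile(r"^Q\d+$")
DOI_PATTERN = re.compile(r"^10\.\d{4,9}/\S+$")
RHEA_PATTERN = re.compile(r"^\d+$")
# four dot-separated components; trailing ones may be '-' or n-prefixed
EC_PATTERN = re.compile(r"^\d+\.(n?\d+|-)\.(n?\d+|-)\.(n?\d+|-)$")
UNIPROT_PATTERN = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})$"
)
GENBANK_PATTERN = re.compile(r"^[A-Z]{1,6}_?\d{3,10}(?:\.\d+)?$", re.IGNORECASE)
ISO_DATE_PATTERN = re.compile(r"^\d{4}-\d{2}-\d{2}$")

DOI_RESOLVER_PREFIXES = ("https://doi.org/", "http://doi.org/", "doi:")

# fields that are bookkeeping, not data, under the data-point counting rule
METADATA_KEYS = frozenset({"changelog", "status"})


def normalize_doi(doi: str) -> str:
    """Strip resolver prefixes; DOIs are stored bare (``10.xxxx/...``)."""
    doi = doi.strip()
    for prefix in DOI_RESOLVER_PREFIXES:
        if doi.lower().startswith(prefix):
            doi = doi[len(prefix):]
    return doi


class _Model(BaseModel):
    model_config = ConfigDict(extra="allow", validate_assignment=True)

    @property
    def extras(self) -> dict[str, Any]:
        """Unknown fields preserved for round-tripping."""
        return dict(self.__pydantic_extra__ or {})


class AuxiliaryEnzyme(_Model):
    """A second enzyme required for the described enzyme's activity."""

    name: str = Field(min_length=1)
    description: Optional[str] = None
    uniprot_id: Optional[str] = None
    genbank_id: Optional[str] = None


class EnzymeInfo(_Model):
    name: str = Field(min_length=1)
    description: Optional[str] = None
    uniprot_id: Optional[str] = None
    genbank_id: Optional[str] = None
    mibig_id: Optional[str] = None
    wikidata_id: Optional[str] = None
    auxiliary_enzymes: list[AuxiliaryEnzyme] = Field(default_factory=list)

    @model_validator(mode="after")
    def _sequence_resolvable(self) -> "EnzymeInfo":
        if not self.uniprot_id and not self.genbank_id:
            raise ValueError(
                "sequence reference missing: at least one of uniprot_id/genbank_id required"
            )
        for aux in self.auxiliary_enzymes:
            if self.uniprot_id and aux.uniprot_id == self.uniprot_id:
                raise ValueError(
                    f"auxiliary enzyme {aux.name!r} shares the parent uniprot_id"
                )
            if self.genbank_id and aux.genbank_id == self.genbank_id:
                raise ValueError(
                    f"auxiliary enzyme {aux.name!r} shares the parent genbank_id"
                )
        return self


class ExampleReaction(_Model):
    """A concrete substrate -> product(s) pair used to verify a rule.

    Substrate and products must parse as SMILES; asterisk atoms (unknown
    cores / R-groups) are permitted. Optional per-example overrides of the
    product-matching policy let curators mark deliberately partial examples.
    """

    substrate: str
    products: list[str] = Field(min_length=1)
    is_balanced: bool = False
    description: Optional[str] = None
    stereo_strict: Optional[bool] = None
    allow_subset: Optional[bool] = None

    @field_validator("substrate")
    @classmethod
    def _substrate_parses(cls, v: str) -> str:
        if not chem.parses(v):
            raise ValueError(f"substrate is not valid SMILES: {v!r}")
        return v

    @field_validator("products")
    @classmethod
    def _products_parse(cls, v: list[str]) -> list[str]:
        for s in v:
            if not chem.parses(s):
                raise ValueError(f"product is not valid SMILES: {s!r}")
        return v

    @model_validator(mode="after")
    def _substrate_differs(self) -> "ExampleReaction":
        sub = chem.canonicalize(self.substrate)
        for p in self.products:
            if chem.canonicalize(p) == sub:
                raise ValueError(
                    "example reaction is a no-op: substrate equals a product "
                    f"after canonicalization ({sub})"
                )
        return self


class ReactionRule(_Model):
    """A generic reaction SMARTS with its validated examples and evidence."""

    smarts: str
    tailoring_terms: list[str] = Field(min_length=1)
    examples: list[ExampleReaction] = Field(min_length=1)
    rhea_id: Optional[str] = None
    ec_number: Optional[str] = None
    evidence_codes: list[str] = Field(min_length=1)
    references: list[str] = Field(default_factory=list)
    iterative: bool = False

    @field_validator("smarts")
    @classmethod
    def _separator(cls, v: str) -> str:
        if v.count(">>") != 1:
            raise ValueError(
                f"reaction SMARTS must contain exactly one '>>' separator: {v!r}"
            )
        if not v.split(">>")[0].strip():
            raise ValueError(f"reaction SMARTS has an empty reactant side: {v!r}")
        return v

    @field_validator("references")
    @classmethod
    def _norm_dois(cls, v: list[str]) -> list[str]:
        return [normalize_doi(d) for d in v]


class ChangelogRecord(_Model):
    version: str
    date: str
    note: str

    @field_validator("date")
    @classmethod
    def _iso(cls, v: str) -> str:
        if not ISO_DATE_PATTERN.match(v):
            raise ValueError(f"date must be ISO-8601 (YYYY-MM-DD): {v!r}")
        return v


class Entry(_Model):
    """One tailoring enzyme: identity, cross-references, reactions, provenance."""

    accession: str
    status: str = "active"
    enzyme: EnzymeInfo
    reactions: list[ReactionRule] = Field(min_length=1)
    references: list[str] = Field(min_length=1)
    changelog: list[ChangelogRecord] = Field(default_factory=list)

    @field_validator("accession")
    @classmethod
    def _accession(cls, v: str) -> str:
        if not ACCESSION_PATTERN.match(v):
            raise ValueError(f"accession pattern violation: {v!r} (expect MITE + 7 digits)")
        if v == RESERVED_ACCESSION:
            raise ValueError(f"accession {RESERVED_ACCESSION} is reserved")
        return v

    @field_validator("status")
    @classmethod
    def _status(cls, v: str) -> str:
        if v not in {"active", "retired"}:
            raise ValueError(f"status must be 'active' or 'retired': {v!r}")
        return v

    @field_validator("references")
    @classmethod
    def _dois(cls, v: list[str]) -> list[str]:
        return [normalize_doi(d) for d in v]

    @model_validator(mode="after")
    def _retired_note(self) -> "Entry":
        if self.status == "retired" and not any(c.note for c in self.changelog):
            raise ValueError("retired entries must carry a changelog note explaining retirement")
        return self

    def to_dict(self) -> dict[str, Any]:
        """Deterministic plain-dict form: declared fields in declaration order
        (Nones dropped), then unknown extras sorted by key."""
        return _model_to_dict(self)


def _model_to_dict(obj: Any) -> Any:
    if isinstance(obj, _Model):
        out: dict[str, Any] = {}
        for name in type(obj).model_fields:
            val = getattr(obj, name)
            if val is None:
                continue
            if name == "iterative" and val is False:
                continue  # planner bookkeeping; omitted at its default
            out[name] = _model_to_dict(val)
        for key in sorted(obj.extras):
            out[key] = obj.extras[key]
        return out
    if isinstance(obj, list):
        return [_model_to_dict(v) for v in obj]
    return obj


def _schema_error_from(exc: ValidationError, where: str) -> SchemaError:
    problems = []
    field = None
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        if field is None:
            field = loc
        problems.append(f"{loc}: {err['msg']}")
    return SchemaError(f"schema violation in {where}: " + "; ".join(problems), field=field)


def parse_entry(text: str, source: str = "<string>") -> Entry:
    """Parse one JSON entry record into a typed :class:`Entry`.

    Syntax errors raise :class:`ParseError` with line/column context; records
    missing mandatory fields or violating construction-time invariants raise
    :class:`SchemaError` naming the offending field. Unknown fields are kept.
    """
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(
            f"{source}: invalid JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}"
        ) from exc
    if not isinstance(raw, dict):
        raise ParseError(f"{source}: entry record must be a JSON object")
    try:
        return Entry.model_validate(raw)
    except ValidationError as exc:
        raise _schema_error_from(exc, source) from exc


def serialize_entry(entry: Entry) -> str:
    """Serialize an entry to its canonical JSON text (round-trip identity)."""
    return json.dumps(entry.to_dict(), indent=2, ensure_ascii=False) + "\n"


def count_data_points(entry: Entry) -> int:
    """Number of data points in an entry.

    A data point is a leaf key-value pair; every scalar leaf counts once and
    each element of a list of scalars counts once. Bookkeeping metadata —
    ``status`` and the whole ``changelog`` — is excluded from the count.
    """

    def walk(obj: Any) -> int:
        if isinstance(obj, dict):
            return sum(walk(v) for k, v in obj.items() if k not in METADATA_KEYS)
        if isinstance(obj, list):
            return sum(walk(v) for v in obj)
        return 1

    return walk(entry.to_dict())


class Dataset:
    """A collection of entries with unique accessions, iterated in sorted order."""

    def __init__(self, entries: list[Entry], version: str = "0",
                 source: Optional[str] = None):
        seen: dict[str, Entry] = {}
        for e in entries:
            if e.accession in seen:
                raise DatasetError(f"duplicate accession {e.accession}")
            seen[e.accession] = e
        self._entries = {k: seen[k] for k in sorted(seen)}
        self.version = version
        self.source = source

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[Entry]:
        return iter(self._entries.values())

    def __contains__(self, accession: str) -> bool:
        return accession in self._entries

    def get(self, accession: str) -> Entry:
        return self._entries[accession]

    @property
    def accessions(self) -> list[str]:
        return list(self._entries)

    def active(self) -> list[Entry]:
        return [e for e in self if e.status == "active"]


def _iter_records(location: Path):
    """Yield (name, text) for every entry record under a directory or archive."""
    if location.is_dir():
        for path in sorted(location.rglob("*.json")):
            yield str(path), path.read_text(encoding="utf-8")
    elif zipfile.is_zipfile(location):
        with zipfile.ZipFile(location) as zf:
            for name in sorted(zf.namelist()):
                if name.endswith(".json"):
                    yield f"{location}!{name}", zf.read(name).decode("utf-8")
    elif tarfile.is_tarfile(location):
        with tarfile.open(location) as tf:
            for member in sorted(tf.getmembers(), key=lambda m: m.name):
                if member.isfile() and member.name.endswith(".json"):
                    fh = tf.extractfile(member)
                    assert fh is not None
                    yield f"{location}!{member.name}", fh.read().decode("utf-8")
    else:
        raise DatasetError(f"not a directory or archive: {location}")


def load_dataset(location: str | Path, version: str = "unknown",
                 strict: bool = False) -> tuple[Dataset, list[str]]:
    """Load every entry record under a directory, zip or tar archive.

    Returns ``(dataset, failures)`` where *failures* collects per-file parse
    and schema problems instead of silently dropping files. With
    ``strict=True`` any failure raises. Duplicate accessions and an empty
    location are always hard errors.
    """
    location = Path(location)
    if not location.exists():
        raise DatasetError(f"location does not exist: {location}")
    entries: list[Entry] = []
    sources: dict[str, str] = {}
    failures: list[str] = []
    n_records = 0
    for name, text in _iter_records(location):
        n_records += 1
        try:
            entry = parse_entry(text, source=name)
        except (ParseError, SchemaError) as exc:
            if strict:
                raise
            failures.append(str(exc))
            continue
        if entry.accession in sources:
            raise DatasetError(
                f"duplicate accession {entry.accession} in {sources[entry.accession]} and {name}"
            )
        sources[entry.accession] = name
        entries.append(entry)
    if n_records == 0:
        raise DatasetError(f"no entry records found under {location}")
    return Dataset(entries, version=version, source=str(location)), failures


def write_dataset(dataset: Dataset, outdir: str | Path) -> list[Path]:
    """Write one ``<accession>.json`` file per entry; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for entry in dataset:
        path = outdir / f"{entry.accession}.json"
        path.write_text(serialize_entry(entry), encoding="utf-8")
        paths.append(path)
    return paths
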