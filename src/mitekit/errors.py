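"""Exception hierarchy for the toolkit."""


class MiteError(Exception):
    """Base class for all toolkit errors."""


class ChemistryError(MiteError):
    """A SMILES/SMARTS string failed to parse or sanitize."""


class RuleError(MiteError):
    """A reaction SMARTS is malformed or uses a rejected dialect."""


class SchemaError(MiteError):
    """An entry record violates the data model."""

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message)
        self.field = field


class ParseError(MiteError):
    """An entry file is not syntactically valid."""


class DatasetError(MiteError):
    """Dataset-level integrity violation (duplicate accessions, empty source)."""


class QueryError(MiteError):
    """A query expression is malformed (e.g. unparsable SMARTS predicate)."""


class CascadeError(MiteError):
    """A rule in a biosynthetic cascade failed to recognize its substrate."""

    def __init__(self, message: str, step_index: int | None = None,
                 intermediate: str | None = None, template: str | None = None):
        super().__init__(message)
        self.step_index = step_index
        self.intermediate = intermediate
        self.template = template


class FixtureSpecError(MiteError):
    """A synthetic-dataset specification is infeasible."""
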