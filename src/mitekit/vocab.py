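"""Controlled vocabularies (tailoring terms, evidence codes).

The vocabularies ship as editable plain-text configuration files under
``mitekit/data/``; one term per line, ``#`` comments ignored.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources


def _load(name: str) -> frozenset[str]:
    text = resources.files("mitekit.data").joinpath(name).read_text(encoding="utf-8")
    terms = set()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            terms.add(line)
    return frozenset(terms)


@lru_cache(maxsize=None)
def tailoring_terms() -> frozenset[str]:
    return _load("tailoring_terms.txt")


@lru_cache(maxsize=None)
def evidence_codes() -> frozenset[str]:
    return _load("evidence_codes.txt")
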