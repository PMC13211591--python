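"""Text normalization shared by header matching and identity matching.

Source exports are written for human readers: headers and values carry
accents, curly apostrophes, stray spaces and inconsistent case.  Matching
layers normalize; ingestion never does (values are preserved verbatim so the
audit trail can show exactly what the source contained).
"""

from __future__ import annotations

import re
import unicodedata

_WS = re.compile(r"\s+")
# curly apostrophes/quotes seen in real exports
_APOSTROPHES = str.maketrans({"’": "'", "‘": "'", "ʼ": "'"})


def strip_accents(text: str) -> str:
    """Remove combining diacritics (é -> e, ë -> e) via NFKD decomposition."""
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


def fold_header(header: str) -> str:
    """Canonical form of a column header for mapping lookup.

    Trim, collapse internal whitespace, case-fold, accent-fold, and unify
    apostrophe variants, so "Origine de l'ADN" and " origine de l’adn "
    resolve to the same mapping rule.
    """
    text = header.translate(_APOSTROPHES)
    text = strip_accents(text).casefold()
    return _WS.sub(" ", text).strip()


def normalize_name(raw: str) -> str:
    """Canonical form of a person-name component for identity matching.

    Case-fold, strip diacritics, turn hyphens and apostrophes into spaces
    (compound names such as "Marie-Anne" / "Marie Anne" must match), then
    collapse whitespace.
    """
    text = raw.translate(_APOSTROPHES)
    text = strip_accents(text).casefold()
    text = text.replace("-", " ").replace("'", " ")
    return _WS.sub(" ", text).strip()
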