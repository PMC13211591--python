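"""Reference terminologies (ORPHA, HPO, gene symbols) and code validity.

Terminologies are loaded from one XML file per reference system.  A code in
a terminology-bound field that is not present in the loaded set blocks the
whole patient's import at validation time.

Fixture terminologies shipped under ``redbridge/data/terminology`` are small
synthetic subsets (real code shapes, curated labels) sufficient for testing;
they are not full releases.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

SYSTEMS = ("ORPHA", "HPO", "GENE")

_ORPHA_RE = re.compile(r"^(?:ORPHA:)?(\d+)$", re.IGNORECASE)
_HPO_RE = re.compile(r"^HP:\d{7}$", re.IGNORECASE)


class TerminologyError(ValueError):
    """Malformed terminology file or integrity violation (duplicate code)."""


def normalize_code(code: str, system: str) -> str:
    """Canonical form of a code for a given system.

    ORPHA accepts bare digits or an ``ORPHA:`` prefix in any case and is
    normalized to the prefixed upper-case form; HPO is upper-cased
    (``hp:0000505`` -> ``HP:0000505``); gene symbols are upper-cased and
    trimmed.  Normalization is idempotent.  Codes that do not match the
    system's shape are returned trimmed/upper-cased so membership lookup
    simply fails for them.
    """
    code = code.strip()
    if system == "ORPHA":
        m = _ORPHA_RE.match(code)
        return f"ORPHA:{m.group(1)}" if m else code.upper()
    if system == "HPO":
        return code.upper()
    return code.upper()


@dataclass
class TerminologySet:
    """One reference system: code -> preferred label."""

    system: str
    entries: dict[str, str] = field(default_factory=dict)
    version: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return is_valid(code, self)


def load_terminology(path: str | Path, system: str) -> TerminologySet:
    """Parse one terminology XML file into a :class:`TerminologySet`.

    Expected layout::

        <terminology system="HPO" version="fixture-1">
          <term code="HP:0000505" label="Visual impairment"/>
          ...
        </terminology>

    Raises :class:`TerminologyError` on malformed XML (message names the
    line), a system mismatch, a code violating the system's pattern, or a
    duplicate code within the file.
    """
    if system not in SYSTEMS:
        raise TerminologyError(f"unknown terminology system {system!r}")
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:  # carries line number
        raise TerminologyError(f"malformed terminology XML {path}: {exc}") from exc

    root = tree.getroot()
    if root.tag != "terminology":
        raise TerminologyError(f"{path}: root element must be <terminology>")
    declared = root.get("system", system)
    if declared != system:
        raise TerminologyError(
            f"{path}: file declares system {declared!r}, expected {system!r}"
        )

    tset = TerminologySet(system=system, version=root.get("version", ""))
    for term in root.iter("term"):
        code = term.get("code")
        if code is None:
            raise TerminologyError(
                f"{path}: <term> without code attribute at line {term.sourceline}"
            )
        norm = normalize_code(code, system)
        _check_shape(norm, system, path, term.sourceline)
        if norm in tset.entries:
            raise TerminologyError(
                f"{path}: duplicate code {norm} at line {term.sourceline}"
            )
        tset.entries[norm] = term.get("label", "")
    return tset


def _check_shape(code: str, system: str, path, line) -> None:
    ok = True
    if system == "ORPHA":
        ok = code.startswith("ORPHA:") and code[6:].isdigit()
    elif system == "HPO":
        ok = bool(_HPO_RE.match(code))
    elif system == "GENE":
        ok = code == code.upper() and bool(code)
    if not ok:
        raise TerminologyError(
            f"{path}: code {code!r} does not match the {system} pattern (line {line})"
        )


def is_valid(code: str, tset: TerminologySet) -> bool:
    """True iff the normalized code is an entry of the set. Unknown -> False."""
    return normalize_code(code, tset.system) in tset.entries


def load_all(directory: str | Path) -> dict[str, TerminologySet]:
    """Load the conventional ``orpha.xml`` / ``hpo.xml`` / ``genes.xml`` trio."""
    directory = Path(directory)
    names = {"ORPHA": "orpha.xml", "HPO": "hpo.xml", "GENE": "genes.xml"}
    return {
        system: load_terminology(directory / fname, system)
        for system, fname in names.items()
    }
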