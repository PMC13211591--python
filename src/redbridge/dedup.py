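"""Duplicate-import prevention against existing target-registry profiles.

The target registry exposes only profile metadata (surname, given name,
birth date) before import.  Matching is deterministic: normalized surname
and given name must be equal and the birth date calendar-exact.  Name
normalization makes the check robust to case, diacritics and compound names
("Marie-Anne" vs "Marie Anne").  No phonetic or fuzzy matching: a false
negative (re-review) is preferable to silently merging two patients.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._text import normalize_name
from .records import Identity


@dataclass(frozen=True)
class RegistryProfile:
    profile_id: str
    surname: str
    given_name: str
    birth_date: str  # ISO string as served by the registry


def is_duplicate(identity: Identity, profiles: list[RegistryProfile]) -> str | None:
    """Return the matching profile_id, or None.

    A match requires equality of normalized surname AND normalized given
    name AND the exact birth date.  Identities missing any attribute never
    match (they are flagged upstream instead).
    """
    if not identity.is_complete():
        return None
    surname = normalize_name(identity.surname)
    given = normalize_name(identity.given_name)
    birth = identity.birth_date.isoformat()
    for profile in profiles:
        if (
            normalize_name(profile.surname) == surname
            and normalize_name(profile.given_name) == given
            and profile.birth_date == birth
        ):
            return profile.profile_id
    return None
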