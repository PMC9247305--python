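"""Standardized animal identifiers.

Every animal carries a 23-character ID built from four components:

* 3 letters for the breed (e.g. ``ALP`` Alpine, ``SAA`` Saanen),
* 3 letters for the country of registration (``CAN``, ``FRA``, ``ITA``,
  ``CHE``),
* 1 letter for the sex (``F`` or ``M``),
* a 16-character core holding the 2-letter birth-country code and the local
  numeric identifier, the whole core left-padded with ``'0'``.

An Alpine female with local ID 5248383, born in France and registered in
Switzerland, is therefore ``ALPCHEF0000000FR5248383``.  The core keeps the
birth country visible inside any national pedigree, which is what makes
cross-country record linkage possible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

CORE_LEN = 16
ID_LEN = 23

#: 2-letter birth-country codes for the 3-letter registration codes.
BIRTH_CODES = {"CAN": "CA", "FRA": "FR", "ITA": "IT", "CHE": "CH"}

_CORE_RE = re.compile(r"^0*([A-Z]{2})(\d+)$")


class IDFormatError(ValueError):
    """Raised when a raw identifier cannot be canonicalized."""


def birth_code(country: str) -> str:
    """2-letter birth-country code for a 3-letter country code."""
    return BIRTH_CODES.get(country, country[:2])


@dataclass(frozen=True)
class CanonicalID:
    """Parsed form of a 23-character standardized ID."""

    breed: str
    country: str
    sex: str
    core: str

    def __post_init__(self) -> None:
        if len(self.core) != CORE_LEN:
            raise IDFormatError(f"core must be {CORE_LEN} characters: {self.core!r}")
        if self.sex not in ("F", "M"):
            raise IDFormatError(f"sex must be F or M: {self.sex!r}")

    def __str__(self) -> str:
        return f"{self.breed}{self.country}{self.sex}{self.core}"

    @classmethod
    def from_string(cls, s: str) -> "CanonicalID":
        if len(s) != ID_LEN:
            raise IDFormatError(f"canonical ID must be {ID_LEN} characters: {s!r}")
        return cls(breed=s[:3], country=s[3:6], sex=s[6], core=s[7:])

    @property
    def birth_country(self) -> str | None:
        """2-letter birth-country code embedded in the core, if parseable."""
        m = _CORE_RE.match(self.core)
        return m.group(1) if m else None

    @property
    def digits(self) -> str:
        """Local numeric identifier with leading zeros stripped."""
        m = _CORE_RE.match(self.core)
        if m:
            return m.group(2).lstrip("0") or "0"
        return "".join(c for c in self.core if c.isdigit()).lstrip("0") or "0"


def standardize_id(
    raw_id: str,
    breed: str,
    registration_country: str,
    sex: str,
    birth_country: str,
) -> CanonicalID:
    """Build the canonical 23-character ID from a local identifier.

    ``raw_id`` is normally the bare numeric local ID; the birth-country code
    is prepended and the result is left-padded with zeros to 16 characters.
    A ``raw_id`` that is already a well-formed core (with the birth-country
    letters embedded) is accepted unchanged, so the function is idempotent.

    >>> str(standardize_id("5248383", "ALP", "CHE", "F", "FR"))
    'ALPCHEF0000000FR5248383'
    """
    raw_id = raw_id.strip()
    if not raw_id:
        raise IDFormatError("empty raw identifier")
    if not (len(breed) == 3 and breed.isalpha()):
        raise IDFormatError(f"invalid breed code: {breed!r}")
    if not (len(registration_country) == 3 and registration_country.isalpha()):
        raise IDFormatError(f"invalid country code: {registration_country!r}")
    if not (len(birth_country) == 2 and birth_country.isalpha()):
        raise IDFormatError(f"invalid birth-country code: {birth_country!r}")

    m = _CORE_RE.match(raw_id)
    if m and m.group(1) == birth_country.upper():
        body = m.group(1) + m.group(2)
    else:
        if not raw_id.isdigit():
            raise IDFormatError(f"local identifier must be numeric: {raw_id!r}")
        if len(raw_id) > CORE_LEN - 2:
            raise IDFormatError(
                f"local identifier longer than {CORE_LEN - 2} characters: {raw_id!r}"
            )
        body = birth_country.upper() + raw_id
    if len(body) > CORE_LEN:
        raise IDFormatError(f"core overflows {CORE_LEN} characters: {body!r}")
    core = body.rjust(CORE_LEN, "0")
    return CanonicalID(
        breed=breed.upper(),
        country=registration_country.upper(),
        sex=sex.upper(),
        core=core,
    )


def core_birth_country(id_string: str) -> str | None:
    """Birth-country code inside a 23-character ID string, or None."""
    try:
        return CanonicalID.from_string(id_string).birth_country
    except IDFormatError:
        return None
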