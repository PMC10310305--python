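"""Temporary allele labels and their base32 identifier encoding.

Before a receptor gene or allele is ratified and given a permanent name,
an allele discovered in (say) an AIRR-seq inference study still needs a
stable, citable name.  The temporary label used here follows the familiar
``<locus><type><subgroup>-<identifier>*<allele>`` shape (for example
``IGHV0-A5B2*00``) but is deliberately distinguishable from ratified
names: the subgroup and allele designators hold null values (``0`` and
``00``) until real values are assigned, and the identifier is a random
20-bit number rendered in the RFC 4648 section 6 base32 alphabet, from
which the visually ambiguous digits 0, 1, 8 and 9 are absent.

Everything in this module is a pure function over strings and small
value objects; registry state (uniqueness, no re-use) lives in
:mod:`germline_kit.registry`.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

from .model import Locus, SequenceType

__all__ = [
    "IDENTIFIER_ALPHABET",
    "IDENTIFIER_SPACE",
    "TempLabel",
    "LegacyLabel",
    "AlphabetError",
    "LabelParseError",
    "identifier_alphabet",
    "encode_identifier",
    "decode_identifier",
    "format_label",
    "parse_label",
    "null_label_for",
]

#: RFC 4648 section 6 base32 alphabet: A-Z then 2-7. No 0, 1, 8 or 9.
IDENTIFIER_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ234567"

#: Number of encodable identifiers: 32**4 == 2**20.
IDENTIFIER_SPACE = 32**4

_SYMBOL_INDEX = {c: i for i, c in enumerate(IDENTIFIER_ALPHABET)}
_IDENTIFIER_RE = re.compile(r"^[A-Z2-7]{4}$")
_ALLELE_RE = re.compile(r"^[0-9]{2}$")

# Longest locus names first so e.g. IGH does not shadow a hypothetical
# longer prefix; all seven loci are 3 characters, so plain order is fine.
_LOCUS_NAMES = tuple(l.value for l in Locus)

_TEMP_RE = re.compile(
    r"^(?P<locus>IGH|IGK|IGL|TRA|TRB|TRG|TRD)"
    r"(?P<type>[VDJ])"
    r"(?P<subgroup>[0-9A-Z]+)"
    r"-(?P<identifier>[A-Z0-9]{4})"
    r"\*(?P<allele>[0-9]{2})$"
)


class AlphabetError(ValueError):
    """A string is not a valid 4-character base32 identifier."""


class LabelParseError(ValueError):
    """A string cannot be read as either a temporary or a legacy label."""


@dataclass(frozen=True)
class TempLabel:
    """A parsed temporary label.

    ``subgroup`` is ``"0"`` and ``allele`` is ``"00"`` while the real
    values are undetermined.
    """

    locus: Locus
    sequence_type: SequenceType
    subgroup: str
    identifier: str
    allele: str

    def __str__(self) -> str:
        return format_label(self)


@dataclass(frozen=True)
class LegacyLabel:
    """A gene*allele style name that is not a temporary label.

    Carries the raw string verbatim plus a best-effort locus and
    sequence type read from the leading characters.  No further meaning
    is parsed out of the name: downstream code must treat it as opaque.
    """

    raw: str
    locus: Locus | None = None
    sequence_type: SequenceType | None = None

    def __str__(self) -> str:
        return self.raw


def identifier_alphabet() -> str:
    """Return the ordered identifier alphabet (length 32)."""
    return IDENTIFIER_ALPHABET


def encode_identifier(value: int) -> str:
    """Encode a 20-bit integer as a 4-character identifier.

    The value is split into four 5-bit groups, most-significant first,
    and each group is mapped through the alphabet.  The mapping is a
    bijection between ``range(2**20)`` and the identifier strings.
    """
    if not 0 <= value < IDENTIFIER_SPACE:
        raise ValueError(
            f"identifier value {value} out of range [0, {IDENTIFIER_SPACE - 1}]"
        )
    return "".join(
        IDENTIFIER_ALPHABET[(value >> shift) & 0x1F] for shift in (15, 10, 5, 0)
    )


def decode_identifier(s: str) -> int:
    """Decode a 4-character identifier back to its integer value.

    Inverse of :func:`encode_identifier`.  Rejects strings of the wrong
    length and any symbol outside the alphabet — including the omitted
    digits 0, 1, 8 and 9.
    """
    if len(s) != 4:
        raise AlphabetError(f"identifier {s!r} must be exactly 4 characters")
    value = 0
    for ch in s:
        idx = _SYMBOL_INDEX.get(ch)
        if idx is None:
            raise AlphabetError(
                f"character {ch!r} in identifier {s!r} is not in the "
                "base32 alphabet (digits 0, 1, 8 and 9 are omitted)"
            )
        value = (value << 5) | idx
    return value


def format_label(t: TempLabel) -> str:
    """Render a :class:`TempLabel` to its string form."""
    if not _IDENTIFIER_RE.match(t.identifier):
        raise AlphabetError(f"invalid identifier {t.identifier!r}")
    if not _ALLELE_RE.match(t.allele):
        raise ValueError(f"invalid allele designator {t.allele!r}")
    if not t.subgroup or not re.match(r"^[0-9A-Z]+$", t.subgroup):
        raise ValueError(f"invalid subgroup {t.subgroup!r}")
    return (
        f"{t.locus.value}{t.sequence_type.value}{t.subgroup}"
        f"-{t.identifier}*{t.allele}"
    )


def _is_temporary(subgroup: str, identifier: str, allele: str) -> bool:
    # All-digit identifiers such as "2345" are visually ambiguous with
    # ratified gene numbers; treat them as temporary only when the
    # subgroup/allele still carry the null values.
    if not _IDENTIFIER_RE.match(identifier):
        return False
    if any(c.isalpha() for c in identifier):
        return True
    return subgroup == "0" and allele == "00"


def parse_label(s: str) -> TempLabel | LegacyLabel:
    """Parse a label string into a :class:`TempLabel` or :class:`LegacyLabel`.

    A string is a temporary label when it matches the full template and
    its identifier is drawn from the base32 alphabet (with the all-digit
    ambiguity rule above).  Any other gene*allele style string with a
    recognised locus prefix is returned as a legacy label; the name is
    kept verbatim and nothing beyond locus and sequence type is
    interpreted.
    """
    if not s:
        raise LabelParseError("empty label")
    if s != s.upper():
        warnings.warn(f"label {s!r} was lowercased on input; uppercasing")
        s = s.upper()
    locus = next((l for l in Locus if s.startswith(l.value)), None)
    if locus is None:
        raise LabelParseError(f"label {s!r} has no recognised locus prefix")
    rest = s[len(locus.value):]
    seq_type = None
    if rest and rest[0] in "VDJ":
        seq_type = SequenceType(rest[0])
    m = _TEMP_RE.match(s)
    if m and _is_temporary(m["subgroup"], m["identifier"], m["allele"]):
        return TempLabel(
            locus=Locus(m["locus"]),
            sequence_type=SequenceType(m["type"]),
            subgroup=m["subgroup"],
            identifier=m["identifier"],
            allele=m["allele"],
        )
    return LegacyLabel(raw=s, locus=locus, sequence_type=seq_type)


def null_label_for(
    locus: Locus, sequence_type: SequenceType, identifier: str
) -> TempLabel:
    """Build the null-valued temporary label for a fresh identifier.

    Subgroup and allele take their null values ``"0"`` and ``"00"``
    until specific values are determined by curators.
    """
    decode_identifier(identifier)  # validates; raises AlphabetError
    return TempLabel(
        locus=locus,
        sequence_type=sequence_type,
        subgroup="0",
        identifier=identifier,
        allele="00",
    )
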