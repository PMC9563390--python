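"""Three-character ICD-10 code groups.

ICD-10 codes are too granular for a per-code association screen, so codes
are collapsed to their three-character group: an uppercase letter followed
by two digits (``S06.5X1A`` -> ``S06``).  The grid of possible groups is
26 letters x 100 two-digit suffixes = 2,600, which bounds the size of the
testing family.
"""

from __future__ import annotations

import re
import string

__all__ = [
    "CodeParseError",
    "truncate_to_group",
    "enumerate_universe",
    "is_valid_group",
    "UNIVERSE_SIZE",
]

UNIVERSE_SIZE = 2600

_GROUP_RE = re.compile(r"^[A-Z][0-9]{2}$")
# punctuation / whitespace that administrative extracts insert inside codes
_STRIP_RE = re.compile(r"[^A-Za-z0-9]")


class CodeParseError(ValueError):
    """Raised when a recorded code cannot be reduced to a valid group."""

    def __init__(self, raw: str, reason: str):
        self.raw = raw
        self.reason = reason
        super().__init__(f"invalid ICD-10 code {raw!r}: {reason}")


def truncate_to_group(code: str) -> str:
    """Reduce a recorded ICD-10 code to its three-character group.

    The code is uppercased and stripped of punctuation and whitespace
    before the prefix is taken, so dialect differences (``S06.5X1A``,
    ``s065``, ``S06 5``) all map to the same group.  Idempotent on
    inputs that are already three-character groups.

    Raises
    ------
    CodeParseError
        If the cleaned code is shorter than three characters, does not
        start with a letter, or has a non-digit where a digit belongs.
    """
    if not isinstance(code, str) or not code.strip():
        raise CodeParseError(str(code), "empty or non-text code")
    cleaned = _STRIP_RE.sub("", code).upper()
    if len(cleaned) < 3:
        raise CodeParseError(code, "fewer than 3 alphanumeric characters")
    prefix = cleaned[:3]
    if not prefix[0].isalpha():
        raise CodeParseError(code, "first character must be a letter A-Z")
    if not prefix[1].isdigit() or not prefix[2].isdigit():
        raise CodeParseError(code, "characters 2-3 must be digits")
    return prefix


def enumerate_universe() -> list[str]:
    """All 2,600 possible three-character groups, ``A00`` ... ``Z99``.

    Lexicographically ordered with no duplicates.  Some groups are unused
    in ICD-10 itself; the full grid is enumerated because group validity,
    not clinical assignment, is what is decided here.
    """
    return [
        f"{letter}{i:02d}"
        for letter in string.ascii_uppercase
        for i in range(100)
    ]


def is_valid_group(group: str) -> bool:
    """True iff ``group`` is a member of the enumerated universe."""
    return isinstance(group, str) and bool(_GROUP_RE.match(group))
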