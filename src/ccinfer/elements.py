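"""Element tables: valences and nominal integer masses.

An element *code* is a chemical symbol with an optional valence suffix,
e.g. ``"C"``, ``"O"``, ``"S(2)"``, ``"S(6)"``.  Elements that occur with
several valences (sulfur, and nitrogen/oxygen/carbon in some data sets)
are treated as distinct codes for descriptor purposes, because local
configuration patterns are indexed by these suffixed codes.

Masses default to nominal integer atomic masses (H=1, C=12, N=14, O=16,
...), which is what every worked arithmetic example in the cycle-
configuration literature uses; the table is a plain mapping and can be
replaced wholesale by users wanting monoisotopic masses.
"""

from __future__ import annotations

import json
import re
from typing import Iterator, Mapping

_CODE_RE = re.compile(r"^([A-Z][a-z]?)(?:\((\d)\))?$")

#: (valence, nominal mass) for the default element codes.  Order matters:
#: the position of a code in this table is its rank, used for canonical
#: orientation of configuration tuples.
_DEFAULT_ENTRIES: dict[str, tuple[int, int]] = {
    "H": (1, 1),
    "C": (4, 12),
    "C(2)": (2, 12),
    "C(3)": (3, 12),
    "C(4)": (4, 12),
    "C(5)": (5, 12),
    "N": (3, 14),
    "N(1)": (1, 14),
    "N(2)": (2, 14),
    "N(3)": (3, 14),
    "N(4)": (4, 14),
    "O": (2, 16),
    "O(1)": (1, 16),
    "O(2)": (2, 16),
    "O(3)": (3, 16),
    "F": (1, 19),
    "Si": (4, 28),
    "P": (5, 31),
    "S(2)": (2, 32),
    "S(4)": (4, 32),
    "S(6)": (6, 32),
    "Cl": (1, 35),
}


class UnknownElementError(KeyError):
    """Raised when an element code is not present in the table."""


class ElementTable:
    """Ordered mapping from element codes to (valence, mass).

    Invariants checked on construction: valences lie in [1, 6], masses are
    positive integers, and a plain (unsuffixed) symbol appears at most once
    per chemical element.
    """

    def __init__(self, entries: Mapping[str, tuple[int, int]] | None = None):
        entries = dict(_DEFAULT_ENTRIES if entries is None else entries)
        plain_seen: set[str] = set()
        for code, (valence, mass) in entries.items():
            m = _CODE_RE.match(code)
            if m is None:
                raise ValueError(f"malformed element code: {code!r}")
            if not 1 <= int(valence) <= 6:
                raise ValueError(f"valence of {code} out of [1,6]: {valence}")
            if int(mass) <= 0:
                raise ValueError(f"mass of {code} must be positive: {mass}")
            if m.group(2) is None:
                if m.group(1) in plain_seen:
                    raise ValueError(f"duplicate plain symbol: {m.group(1)}")
                plain_seen.add(m.group(1))
        self._entries: dict[str, tuple[int, int]] = {
            code: (int(v), int(ms)) for code, (v, ms) in entries.items()
        }
        self._rank = {code: i for i, code in enumerate(self._entries)}

    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def codes(self) -> list[str]:
        return list(self._entries)

    def valence(self, code: str) -> int:
        try:
            return self._entries[code][0]
        except KeyError:
            raise UnknownElementError(code) from None

    def mass(self, code: str) -> int:
        try:
            return self._entries[code][1]
        except KeyError:
            raise UnknownElementError(code) from None

    def rank(self, code: str) -> int:
        """Position of ``code`` in the table; total order for tuple orientation."""
        try:
            return self._rank[code]
        except KeyError:
            raise UnknownElementError(code) from None

    @staticmethod
    def symbol(code: str) -> str:
        """Chemical symbol of a code, e.g. ``symbol("S(6)") == "S"``."""
        m = _CODE_RE.match(code)
        if m is None:
            raise ValueError(f"malformed element code: {code!r}")
        return m.group(1)

    def code_for(self, symbol: str, valence: int) -> str:
        """Element code for an atom of ``symbol`` realising ``valence``.

        Prefers the plain symbol when its tabulated valence matches,
        otherwise falls back to the suffixed code.
        """
        if symbol in self._entries and self._entries[symbol][0] == valence:
            return symbol
        suffixed = f"{symbol}({valence})"
        if suffixed in self._entries:
            return suffixed
        if symbol in self._entries:
            return symbol  # valence mismatch surfaces later in validate()
        raise UnknownElementError(f"{symbol} with valence {valence}")

    def to_json(self) -> str:
        return json.dumps({c: list(vm) for c, vm in self._entries.items()}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ElementTable":
        raw = json.loads(text)
        return cls({c: (v[0], v[1]) for c, v in raw.items()})


def default_element_table() -> ElementTable:
    return ElementTable()
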