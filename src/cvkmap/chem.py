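"""Chemical formulas and the elemental ratios behind van Krevelen coordinates.

Every compound on a van Krevelen map is placed by its molecular formula
alone.  The classic diagram plots H:C against O:C; for biological molecules
a heteroatom axis with broader spread is useful, so this package also
computes a mass-weighted NOPS:C ratio

    NOPS:C = (nN*14 + nO*16 + nP*31 + nS*32) / (nC*12)

using nominal integer masses.  For C26H43NO5 (an N-acyl amino acid sized
molecule): H:C = 43/26 = 1.654, O:C = 5/26 = 0.192 and
NOPS:C = (1*14 + 5*16)/(26*12) = 0.301.

The weights live in an explicit, overridable :class:`MassTable`, so the
metric extends to isotope-labeled formulas: a mass-13 carbon written
``[13C]`` counts as carbon but contributes 13 to any mass-weighted term,
and ``D``/``T`` are accepted as hydrogen isotopes of mass 2 and 3.
"""

from __future__ import annotations

import logging
import re
from collections.abc import Iterator, Mapping
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ._elements import ELEMENT_SYMBOLS, ISOTOPE_SHORTHAND

logger = logging.getLogger(__name__)

__all__ = [
    "CarbonFreeError",
    "ElementCount",
    "FormulaError",
    "MassTable",
    "RatioSet",
    "compute_ratios",
    "parse_formula",
    "ratio_table",
    "to_hill_notation",
]

#: Nominal integer masses (unified atomic mass units) for the elements the
#: NOPS:C metric touches, plus the hydrogen isotope shorthands.
DEFAULT_NOMINAL_MASSES: dict[str, int] = {
    "H": 1,
    "D": 2,
    "T": 3,
    "C": 12,
    "N": 14,
    "O": 16,
    "P": 31,
    "S": 32,
}

_ISOTOPE_RE = re.compile(r"^(\d+)([A-Z][a-z]?)$")


class FormulaError(ValueError):
    """A formula string could not be parsed; carries the offending position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (position {position})"
        super().__init__(message)


class CarbonFreeError(ValueError):
    """Ratios were requested for a compound without carbon."""


def _split_symbol(symbol: str) -> tuple[str, int | None]:
    """Return (base element, mass number or None) for a stored symbol."""
    if symbol in ISOTOPE_SHORTHAND:
        return ISOTOPE_SHORTHAND[symbol]
    m = _ISOTOPE_RE.match(symbol)
    if m:
        return m.group(2), int(m.group(1))
    return symbol, None


def base_element(symbol: str) -> str:
    """Base element of a possibly isotope-qualified symbol ('13C' -> 'C')."""
    return _split_symbol(symbol)[0]


@dataclass(frozen=True)
class MassTable:
    """Nominal integer masses used by the weighted heteroatom ratio.

    Isotope-qualified symbols not listed explicitly fall back to their mass
    number (``'13C'`` weighs 13).  Override entries to substitute e.g.
    monoisotopic masses.
    """

    weights: Mapping[str, int] = None  # type: ignore[assignment]

    def __post_init__(self):
        merged = dict(DEFAULT_NOMINAL_MASSES)
        if self.weights:
            merged.update(self.weights)
        object.__setattr__(self, "weights", merged)

    def mass(self, symbol: str) -> int:
        if symbol in self.weights:
            return self.weights[symbol]
        base, mass_number = _split_symbol(symbol)
        if mass_number is not None:
            return mass_number
        raise KeyError(f"no nominal mass known for element {symbol!r}")

    def __eq__(self, other) -> bool:
        return isinstance(other, MassTable) and dict(self.weights) == dict(other.weights)

    def __hash__(self) -> int:
        return hash(frozenset(self.weights.items()))


class ElementCount(Mapping):
    """Immutable multiset of element (or isotope) symbols with positive counts.

    Zero counts are dropped on construction; negative counts are rejected.
    Keys are validated element symbols, optionally isotope-qualified
    (``'13C'``) or the shorthands ``'D'``/``'T'``.
    """

    __slots__ = ("_entries", "_hash")

    def __init__(self, entries: Mapping[str, int] | None = None, **kwargs: int):
        merged: dict[str, int] = {}
        for source in (entries or {}), kwargs:
            for symbol, count in dict(source).items():
                merged[symbol] = merged.get(symbol, 0) + int(count)
        clean: dict[str, int] = {}
        for symbol, count in merged.items():
            base, _ = _split_symbol(symbol)
            if base not in ELEMENT_SYMBOLS:
                raise ValueError(f"unknown element symbol {symbol!r}")
            if count < 0:
                raise ValueError(f"negative count for {symbol!r}: {count}")
            if count == 0:
                continue
            clean[symbol] = count
        self._entries = dict(sorted(clean.items()))
        self._hash = hash(frozenset(self._entries.items()))

    @property
    def entries(self) -> dict[str, int]:
        return dict(self._entries)

    def __getitem__(self, symbol: str) -> int:
        return self._entries[symbol]

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __hash__(self) -> int:
        return self._hash

    def __eq__(self, other) -> bool:
        if isinstance(other, ElementCount):
            return self._entries == other._entries
        if isinstance(other, Mapping):
            return self._entries == dict(other)
        return NotImplemented

    def __repr__(self) -> str:
        return f"ElementCount({self._entries!r})"

    def total(self, element: str) -> int:
        """Total atoms of a base element, summing its isotopes (D counts as H)."""
        return sum(
            n for sym, n in self._entries.items() if base_element(sym) == element
        )

    def add(self, other: Mapping[str, int]) -> "ElementCount":
        merged = dict(self._entries)
        for sym, n in dict(other).items():
            merged[sym] = merged.get(sym, 0) + n
        return ElementCount(merged)

    def subtract(self, other: Mapping[str, int]) -> "ElementCount":
        merged = dict(self._entries)
        for sym, n in dict(other).items():
            merged[sym] = merged.get(sym, 0) - n
        return ElementCount(merged)

    def scale(self, k: int) -> "ElementCount":
        if k < 1:
            raise ValueError("scale factor must be a positive integer")
        return ElementCount({sym: n * k for sym, n in self._entries.items()})


@dataclass(frozen=True)
class RatioSet:
    """Formula-derived elemental ratios of one compound (all unitless)."""

    hc: float
    oc: float
    nc: float
    nops_c: float


# ---------------------------------------------------------------------------
# Formula grammar
#
#   formula := unit+ charge?
#   unit    := '(' unit+ ')' count?  |  token count?
#   token   := '[' massnumber symbol ']'  |  symbol      (symbol incl. D, T)
#   charge  := digits? ('+'|'-')                         (trailing; ignored)
#
# Whitespace and underscores are stripped first (model exports and markup
# write e.g. "C_26_H_43_NO_5_").  Hydrate dots and adduct brackets are
# rejected: callers normalize adducts before parsing.
# ---------------------------------------------------------------------------

_CHARGE_RE = re.compile(r"(\d?[+-])$")
_BRACKET_RE = re.compile(r"\[(\d+)([A-Z][a-z]?)\]")


def _read_count(s: str, i: int) -> tuple[int, int]:
    j = i
    while j < len(s) and s[j].isdigit():
        j += 1
    if j == i:
        return 1, i
    count = int(s[i:j])
    if count == 0:
        raise FormulaError("zero count is not allowed", i)
    return count, j


def _normalize_isotope(mass_number: int, element: str, position: int) -> str:
    if element not in ELEMENT_SYMBOLS:
        raise FormulaError(f"unknown element symbol {element!r}", position)
    if not 1 <= mass_number <= 300:
        raise FormulaError(f"implausible mass number {mass_number}", position)
    if element == "H" and mass_number == 2:
        return "D"
    if element == "H" and mass_number == 3:
        return "T"
    return f"{mass_number}{element}"


def _parse_units(s: str, i: int, depth: int) -> tuple[dict[str, int], int]:
    counts: dict[str, int] = {}

    def bump(sym: str, n: int) -> None:
        counts[sym] = counts.get(sym, 0) + n

    while i < len(s):
        ch = s[i]
        if ch == "(":
            inner, j = _parse_units(s, i + 1, depth + 1)
            if j >= len(s) or s[j] != ")":
                raise FormulaError("unclosed '('", i)
            mult, j = _read_count(s, j + 1)
            for sym, n in inner.items():
                bump(sym, n * mult)
            i = j
        elif ch == ")":
            if depth == 0:
                raise FormulaError("unbalanced ')'", i)
            return counts, i
        elif ch == "[":
            m = _BRACKET_RE.match(s, i)
            if not m:
                raise FormulaError("malformed isotope bracket", i)
            sym = _normalize_isotope(int(m.group(1)), m.group(2), i)
            count, j = _read_count(s, m.end())
            bump(sym, count)
            i = j
        elif ch.isupper():
            two = s[i : i + 2]
            if len(two) == 2 and two[1].islower() and two in ELEMENT_SYMBOLS:
                sym, j = two, i + 2
            elif ch in ELEMENT_SYMBOLS or ch in ISOTOPE_SHORTHAND:
                sym, j = ch, i + 1
            else:
                raise FormulaError(f"unknown element symbol {ch!r}", i)
            count, j = _read_count(s, j)
            bump(sym, count)
            i = j
        else:
            raise FormulaError(f"unexpected character {ch!r}", i)
    if depth > 0:
        raise FormulaError("unclosed '('", len(s))
    return counts, i


def parse_formula(formula: str) -> ElementCount:
    """Parse a Hill-style formula string into an :class:`ElementCount`.

    Accepts parenthesized groups ("Ca(NO3)2"), implicit count 1, a trailing
    charge annotation ("+", "2-", stripped and ignored), underscore/markup
    decorations, and isotope notation ("[13C]6H12O6", "D2O").

    A single digit directly before a trailing sign is read as the charge
    magnitude ("Ca2+" is one calcium, "SO42-" is sulfate): write neutral
    formulas without trailing signs to avoid the inherent ambiguity.
    Hydrate dots and adduct notation are rejected; normalize adducts
    before parsing.

    Raises
    ------
    FormulaError
        If the string is empty or any token cannot be interpreted; the
        error names the offending position in the cleaned string.
    """
    if formula is None:
        raise FormulaError("formula is None")
    cleaned = "".join(ch for ch in str(formula) if not ch.isspace() and ch != "_")
    if not cleaned:
        raise FormulaError("empty formula", 0)
    body = _CHARGE_RE.sub("", cleaned)
    if not body:
        raise FormulaError("formula contains only a charge annotation", 0)
    counts, _ = _parse_units(body, 0, 0)
    if not counts:
        raise FormulaError("no element tokens found", 0)
    return ElementCount(counts)


def _hill_sort_key(symbol: str, has_carbon: bool) -> tuple:
    base, mass_number = _split_symbol(symbol)
    rank = 2
    if has_carbon:
        rank = 0 if base == "C" else 1 if base == "H" else 2
    else:
        rank = 2  # pure alphabetical, hydrogen sorts in place
    return (rank, base, mass_number if mass_number is not None else 0)


def to_hill_notation(counts: ElementCount) -> str:
    """Serialize counts to Hill notation: C, H, then alphabetical.

    Carbon-free formulas are written purely alphabetically.  Isotopes
    serialize as ``D``/``T`` or ``[13C]`` and sort directly after their
    base element, lightest first.  Round-trips through
    :func:`parse_formula` to an identical :class:`ElementCount`.
    """
    if len(counts) == 0:
        raise ValueError("cannot serialize an empty ElementCount")
    has_carbon = counts.total("C") > 0
    parts = []
    for sym in sorted(counts, key=lambda s: _hill_sort_key(s, has_carbon)):
        token = sym if sym in ELEMENT_SYMBOLS or sym in ISOTOPE_SHORTHAND else None
        if token is None:
            mass_number, elem = _ISOTOPE_RE.match(sym).groups()
            token = f"[{mass_number}{elem}]"
        n = counts[sym]
        parts.append(token if n == 1 else f"{token}{n}")
    return "".join(parts)


def compute_ratios(counts: ElementCount, masses: MassTable | None = None) -> RatioSet:
    """Compute H:C, O:C, N:C and the mass-weighted NOPS:C ratio.

    Isotope-qualified atoms count toward their base element's atom tally
    but contribute their own isotope mass to the weighted numerator and
    (for carbon isotopes) denominator.

    Raises
    ------
    CarbonFreeError
        If the compound contains no carbon; batch callers typically skip
        such compounds with a warning.
    """
    masses = masses if masses is not None else MassTable()
    n_c = counts.total("C")
    if n_c == 0:
        raise CarbonFreeError(
            f"compound {to_hill_notation(counts)!r} contains no carbon"
        )
    n_h = counts.total("H")
    n_o = counts.total("O")
    n_n = counts.total("N")

    numerator = 0
    denominator = 0
    for sym, n in counts.items():
        base = base_element(sym)
        if base in ("N", "O", "P", "S"):
            numerator += n * masses.mass(sym)
        elif base == "C":
            denominator += n * masses.mass(sym)
    return RatioSet(
        hc=n_h / n_c,
        oc=n_o / n_c,
        nc=n_n / n_c,
        nops_c=numerator / denominator,
    )


def ratio_table(
    compounds: pd.DataFrame | str | Path,
    masses: MassTable | None = None,
) -> pd.DataFrame:
    """Batch-compute ratios for a (compound_id, formula) table.

    `compounds` is a DataFrame with columns ``compound_id`` and ``formula``,
    or a path to a tab-separated file with those columns (header row).
    Carbon-free compounds are skipped with a logged warning.  Returns a
    DataFrame with columns compound_id, formula, hc, oc, nc, nops_c at full
    floating precision (display rounding is left to serialization).
    """
    if not isinstance(compounds, pd.DataFrame):
        compounds = pd.read_csv(compounds, sep="\t", dtype=str)
    missing = {"compound_id", "formula"} - set(compounds.columns)
    if missing:
        raise ValueError(f"ratio table input lacks columns: {sorted(missing)}")
    rows = []
    skipped = 0
    for rec in compounds.itertuples(index=False):
        counts = parse_formula(rec.formula)
        try:
            ratios = compute_ratios(counts, masses)
        except CarbonFreeError:
            logger.warning(
                "skipping carbon-free compound %s (%s)", rec.compound_id, rec.formula
            )
            skipped += 1
            continue
        rows.append(
            {
                "compound_id": rec.compound_id,
                "formula": to_hill_notation(counts),
                "hc": ratios.hc,
                "oc": ratios.oc,
                "nc": ratios.nc,
                "nops_c": ratios.nops_c,
            }
        )
    if skipped:
        logger.warning("skipped %d carbon-free compounds", skipped)
    return pd.DataFrame(
        rows, columns=["compound_id", "formula", "hc", "oc", "nc", "nops_c"]
    )
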