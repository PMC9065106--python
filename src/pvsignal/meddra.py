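"""MedDRA-style adverse-event dictionary.

MedDRA (Medical Dictionary for Regulatory Activities) codes adverse events
on five levels of increasing generality:

    LLT (Lowest Level Term) -> PT (Preferred Term) -> HLT (High Level Term)
        -> HLGT (High Level Group Term) -> SOC (System Organ Class)

Every LLT belongs to exactly one PT; links above PT may be one-to-many
(multi-axiality: a PT can sit in several SOCs, one of which is designated
its *primary* SOC).  This module models that hierarchy, loads it from a
single CSV file, and resolves any term to its ancestors at any level.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "TermLevel",
    "Term",
    "MedDRADictionary",
    "load_dictionary",
    "write_dictionary",
    "ancestors_at_level",
    "terms_at_level",
    "DictionaryFormatError",
    "DictionaryIntegrityError",
]


class DictionaryFormatError(ValueError):
    """Raised when a dictionary file is missing required structure."""


class DictionaryIntegrityError(ValueError):
    """Raised when dictionary content violates a hierarchy invariant."""


class TermLevel(enum.IntEnum):
    """Hierarchy levels, ordered from most specific to most general."""

    LLT = 1
    PT = 2
    HLT = 3
    HLGT = 4
    SOC = 5

    @classmethod
    def from_string(cls, s: str) -> "TermLevel":
        try:
            return cls[str(s).strip().upper()]
        except KeyError:
            raise DictionaryFormatError(f"unknown hierarchy level: {s!r}") from None


@dataclass(frozen=True)
class Term:
    """One dictionary entry.

    ``parent_codes`` are the codes of the term's parents at the next level
    up (exactly one for an LLT, possibly several for PT and above, none for
    a SOC).  ``primary_soc`` is only meaningful on PT rows and marks the
    primary axis used for SOC-level counting in ``soc_axis='primary'`` mode.
    """

    code: str
    name: str
    level: TermLevel
    parent_codes: frozenset[str] = field(default_factory=frozenset)
    primary_soc: str | None = None


class MedDRADictionary:
    """Validated five-level term hierarchy with parent/child navigation.

    Parameters
    ----------
    terms
        Iterable of :class:`Term`.  Validation enforces code uniqueness,
        parent links exactly one level up, single PT parent per LLT, no
        parents on SOC terms, and at least one parent on every non-SOC term
        (which, with the one-level-up rule, guarantees acyclicity and that
        every term reaches a SOC).
    """

    def __init__(self, terms) -> None:
        self.terms: dict[str, Term] = {}
        for t in terms:
            if t.code in self.terms:
                raise DictionaryIntegrityError(f"duplicate term code: {t.code!r}")
            self.terms[t.code] = t
        self.level_index: dict[TermLevel, list[str]] = {
            lvl: [] for lvl in TermLevel
        }
        for code, t in self.terms.items():
            self.level_index[t.level].append(code)
        for lvl in TermLevel:
            self.level_index[lvl].sort()
        self._children: dict[str, set[str]] = defaultdict(set)
        self._validate()
        for code, t in self.terms.items():
            for p in t.parent_codes:
                self._children[p].add(code)

    def _validate(self) -> None:
        for code, t in self.terms.items():
            if t.level == TermLevel.SOC:
                if t.parent_codes:
                    raise DictionaryIntegrityError(
                        f"SOC term {code!r} must not have parents"
                    )
                continue
            if not t.parent_codes:
                raise DictionaryIntegrityError(
                    f"non-SOC term {code!r} has no parent and cannot reach a SOC"
                )
            if t.level == TermLevel.LLT and len(t.parent_codes) != 1:
                raise DictionaryIntegrityError(
                    f"LLT {code!r} must have exactly one PT parent, "
                    f"got {sorted(t.parent_codes)}"
                )
            for p in t.parent_codes:
                if p not in self.terms:
                    raise DictionaryIntegrityError(
                        f"term {code!r} references dangling parent code {p!r}"
                    )
                if self.terms[p].level != t.level + 1:
                    raise DictionaryIntegrityError(
                        f"parent {p!r} of {code!r} is at level "
                        f"{self.terms[p].level.name}, expected "
                        f"{TermLevel(t.level + 1).name}"
                    )
            if t.level == TermLevel.PT and t.primary_soc is not None:
                if t.primary_soc not in self.terms or (
                    self.terms[t.primary_soc].level != TermLevel.SOC
                ):
                    raise DictionaryIntegrityError(
                        f"primary SOC {t.primary_soc!r} of PT {code!r} "
                        "is not a SOC term"
                    )

    # -- navigation ---------------------------------------------------------

    def __contains__(self, code: str) -> bool:
        return code in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def level_of(self, code: str) -> TermLevel:
        try:
            return self.terms[code].level
        except KeyError:
            raise KeyError(f"unknown term code: {code!r}") from None

    def ancestors_at_level(
        self, code: str, target: TermLevel, soc_axis: str = "all"
    ) -> set[str]:
        """All codes at ``target`` level reachable from ``code`` by parent links.

        ``ancestors_at_level(x, level(x)) == {x}``.  With
        ``soc_axis='primary'`` and ``target=SOC``, a PT (or a descendant of
        a single PT) that carries a primary-SOC marker resolves to that SOC
        alone, mirroring UMC convention of counting each report once per
        primary axis.
        """
        if soc_axis not in ("all", "primary"):
            raise ValueError(f"soc_axis must be 'all' or 'primary', got {soc_axis!r}")
        term = self.terms.get(code)
        if term is None:
            raise KeyError(f"unknown term code: {code!r}")
        if target < term.level:
            raise ValueError(
                f"target level {TermLevel(target).name} is below the level "
                f"of {code!r} ({term.level.name})"
            )
        frontier = {code}
        level = term.level
        while level < target:
            if (
                soc_axis == "primary"
                and target == TermLevel.SOC
                and level == TermLevel.PT
            ):
                primaries = set()
                ok = True
                for c in frontier:
                    ps = self.terms[c].primary_soc
                    if ps is None:
                        ok = False
                        break
                    primaries.add(ps)
                if ok:
                    return primaries
            frontier = {
                p for c in frontier for p in self.terms[c].parent_codes
            }
            level = TermLevel(level + 1)
        return frontier

    def terms_at_level(self, level: TermLevel) -> list[Term]:
        """All terms at ``level``, sorted by code (deterministic order)."""
        return [self.terms[c] for c in self.level_index[level]]

    def children(self, code: str) -> set[str]:
        if code not in self.terms:
            raise KeyError(f"unknown term code: {code!r}")
        return set(self._children.get(code, ()))

    def descendants_at_level(self, code: str, target: TermLevel) -> set[str]:
        """All codes at ``target`` (a more specific level) below ``code``."""
        term = self.terms.get(code)
        if term is None:
            raise KeyError(f"unknown term code: {code!r}")
        if target > term.level:
            raise ValueError(
                f"target level {TermLevel(target).name} is above the level "
                f"of {code!r} ({term.level.name})"
            )
        frontier = {code}
        level = term.level
        while level > target:
            frontier = {c for f in frontier for c in self._children.get(f, ())}
            level = TermLevel(level - 1)
        return frontier

    def pt_ancestor_frame(self, target: TermLevel, soc_axis: str = "all") -> pd.DataFrame:
        """Long table mapping every PT to its ancestor(s) at ``target`` level.

        Columns ``pt_code``, ``ancestor_code``; one row per (PT, ancestor)
        pair.  The scan stages use this for vectorised report counting.
        """
        rows: list[tuple[str, str]] = []
        for code in self.level_index[TermLevel.PT]:
            for anc in self.ancestors_at_level(code, target, soc_axis=soc_axis):
                rows.append((code, anc))
        return pd.DataFrame(rows, columns=["pt_code", "ancestor_code"])


_REQUIRED_COLUMNS = ("code", "name", "level", "parent_codes")
PARENT_SEPARATOR = "|"  # intra-cell separator in the parent_codes column


def load_dictionary(path) -> MedDRADictionary:
    """Load and validate a dictionary from a single UTF-8 CSV file.

    Expected columns: ``code,name,level,parent_codes[,primary_soc]`` with
    ``parent_codes`` joining multiple parents by ``|``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DictionaryFormatError(
            f"dictionary file {path} is missing column(s): {', '.join(missing)}"
        )
    has_primary = "primary_soc" in df.columns
    terms = []
    for row in df.itertuples(index=False):
        parents = frozenset(
            p for p in str(row.parent_codes).split(PARENT_SEPARATOR) if p
        )
        primary = None
        if has_primary and str(row.primary_soc):
            primary = str(row.primary_soc)
        terms.append(
            Term(
                code=str(row.code),
                name=str(row.name),
                level=TermLevel.from_string(row.level),
                parent_codes=parents,
                primary_soc=primary,
            )
        )
    return MedDRADictionary(terms)


def write_dictionary(d: MedDRADictionary, path) -> None:
    """Write a dictionary back to the CSV dialect read by :func:`load_dictionary`."""
    rows = []
    for code in sorted(d.terms):
        t = d.terms[code]
        rows.append(
            {
                "code": t.code,
                "name": t.name,
                "level": t.level.name,
                "parent_codes": PARENT_SEPARATOR.join(sorted(t.parent_codes)),
                "primary_soc": t.primary_soc or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def ancestors_at_level(
    d: MedDRADictionary, code: str, target: TermLevel, soc_axis: str = "all"
) -> set[str]:
    """Module-level convenience wrapper over the dictionary method."""
    return d.ancestors_at_level(code, target, soc_axis=soc_axis)


def terms_at_level(d: MedDRADictionary, level: TermLevel) -> list[Term]:
    return d.terms_at_level(level)
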