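"""Trimer reference database: the three-level 9-mer hierarchy.

The reference table stores amino-acid trimers observed in protein secondary
structures together with the 3-codon DNA 9-mers that encode them.  Keys form
a three-level hierarchy: characteristic trimer (top) -> amino-acid trimer ->
set of 9-mers.  Query 9-mers are matched by descending this hierarchy; only
a full (9-mer level) match carries a usage bias and contributes to scoring.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .genetic_code import (
    STOP,
    ninemer_to_trimer,
    synonymous_ninemers,
    trimer_to_char_trimer,
)

__all__ = ["MatchLevel", "MatchResult", "TrimerRefDB", "load_refdb", "match_ninemer"]


class MatchLevel(str, enum.Enum):
    """Deepest level of the reference hierarchy reached by a query 9-mer."""

    NONE = "none"
    CHAR_ONLY = "char_only"
    TRIMER_ONLY = "trimer_only"
    FULL = "full"


@dataclass(frozen=True)
class MatchResult:
    level: MatchLevel
    ninemer: str | None = None
    trimer: str | None = None
    char_trimer: str | None = None

    @property
    def is_full(self) -> bool:
        return self.level is MatchLevel.FULL


class TrimerRefDB:
    """Immutable reference hierarchy with O(1) 9-mer matching.

    Construct from (trimer, ninemer) pairs via :meth:`from_pairs` or from a
    two-column TSV via :meth:`load`.  Consistency (each 9-mer translates to
    its parent trimer; trimers are stop-free) is enforced at construction.
    """

    def __init__(self, hierarchy: Mapping[str, Mapping[str, Iterable[str]]]):
        h: dict[str, dict[str, frozenset[str]]] = {}
        flat: dict[str, tuple[str, str]] = {}
        for char_trimer, trimers in hierarchy.items():
            inner: dict[str, frozenset[str]] = {}
            for trimer, ninemers in trimers.items():
                if STOP in trimer:
                    raise ValueError(f"reference trimer contains a stop: {trimer!r}")
                if trimer_to_char_trimer(trimer) != char_trimer:
                    raise ValueError(
                        f"trimer {trimer!r} filed under wrong characteristic "
                        f"trimer {char_trimer!r}"
                    )
                nset = frozenset(n.upper() for n in ninemers)
                if not nset:
                    raise ValueError(f"trimer {trimer!r} has an empty 9-mer set")
                for n in nset:
                    if ninemer_to_trimer(n) != trimer:
                        raise ValueError(
                            f"9-mer {n!r} does not translate to trimer {trimer!r}"
                        )
                    flat[n] = (char_trimer, trimer)
                inner[trimer] = nset
            if inner:
                h[char_trimer] = inner
        if not flat:
            raise ValueError("empty reference table")
        self._hierarchy = h
        self._flat = flat
        self._trimers = frozenset(t for inner in h.values() for t in inner)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "TrimerRefDB":
        """Build from (amino-acid trimer, 9-mer) rows; duplicates collapse."""
        hierarchy: dict[str, dict[str, set[str]]] = {}
        for row, (trimer, ninemer) in enumerate(pairs, start=1):
            trimer = trimer.strip().upper()
            ninemer = ninemer.strip().upper()
            try:
                if ninemer_to_trimer(ninemer) != trimer:
                    raise ValueError(
                        f"9-mer {ninemer!r} translates to "
                        f"{ninemer_to_trimer(ninemer)!r}, not {trimer!r}"
                    )
                char_trimer = trimer_to_char_trimer(trimer)
            except ValueError as exc:
                raise ValueError(f"reference row {row}: {exc}") from None
            hierarchy.setdefault(char_trimer, {}).setdefault(trimer, set()).add(ninemer)
        if not hierarchy:
            raise ValueError("empty reference table")
        return cls(hierarchy)

    @classmethod
    def load(cls, path: str | Path) -> "TrimerRefDB":
        """Load a two-column (trimer, 9-mer) TSV; '#' lines are comments."""
        pairs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValueError(
                        f"{path}: line {lineno}: expected 2 tab-separated "
                        f"columns, got {len(fields)}"
                    )
                pairs.append((fields[0], fields[1]))
        try:
            return cls.from_pairs(pairs)
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from None

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# trimer reference table: amino-acid trimer <TAB> 9-mer\n")
            for char_trimer in sorted(self._hierarchy):
                for trimer in sorted(self._hierarchy[char_trimer]):
                    for ninemer in sorted(self._hierarchy[char_trimer][trimer]):
                        fh.write(f"{trimer}\t{ninemer}\n")

    # -- matching ----------------------------------------------------------

    def match(self, ninemer: str) -> MatchResult:
        """Match a 9-mer against the hierarchy, deepest level first."""
        ninemer = ninemer.upper()
        hit = self._flat.get(ninemer)
        if hit is not None:
            char_trimer, trimer = hit
            return MatchResult(MatchLevel.FULL, ninemer, trimer, char_trimer)
        trimer = ninemer_to_trimer(ninemer)
        char_trimer = trimer_to_char_trimer(trimer)
        inner = self._hierarchy.get(char_trimer)
        if inner is None:
            return MatchResult(MatchLevel.NONE)
        if trimer in inner:
            return MatchResult(MatchLevel.TRIMER_ONLY, None, trimer, char_trimer)
        return MatchResult(MatchLevel.CHAR_ONLY, None, None, char_trimer)

    # -- views -------------------------------------------------------------

    @property
    def hierarchy(self) -> dict[str, dict[str, frozenset[str]]]:
        return self._hierarchy

    @property
    def char_trimers(self) -> frozenset[str]:
        return frozenset(self._hierarchy)

    @property
    def trimers(self) -> frozenset[str]:
        return self._trimers

    @property
    def ninemers(self) -> frozenset[str]:
        return frozenset(self._flat)

    def parent_of(self, ninemer: str) -> tuple[str, str]:
        """(char_trimer, trimer) under which a reference 9-mer is filed."""
        return self._flat[ninemer.upper()]

    def ninemers_of(self, trimer: str) -> frozenset[str]:
        return self._hierarchy[trimer_to_char_trimer(trimer)][trimer]

    def missing_synonyms(self, trimer: str) -> list[str]:
        """Synonymous 9-mers of a stored trimer absent from its 9-mer set."""
        stored = self.ninemers_of(trimer)
        return [n for n in synonymous_ninemers(trimer) if n not in stored]

    def __contains__(self, ninemer: str) -> bool:
        return ninemer.upper() in self._flat

    def __len__(self) -> int:
        return len(self._flat)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._flat))

    @property
    def n_char_trimers(self) -> int:
        return len(self._hierarchy)

    @property
    def n_trimers(self) -> int:
        return len(self._trimers)

    @property
    def n_ninemers(self) -> int:
        return len(self._flat)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"TrimerRefDB({self.n_char_trimers} char trimers, "
            f"{self.n_trimers} trimers, {self.n_ninemers} 9-mers)"
        )


def load_refdb(path: str | Path) -> TrimerRefDB:
    """Load a trimer reference TSV (thin wrapper over ``TrimerRefDB.load``)."""
    return TrimerRefDB.load(path)


def match_ninemer(db: TrimerRefDB, ninemer: str) -> MatchResult:
    """Match a 9-mer against the reference hierarchy."""
    return db.match(ninemer)
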