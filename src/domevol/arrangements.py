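"""Core value types for protein domain arrangements.

A *domain arrangement* is the ordered, linear sequence of domains in a
protein.  Because the copy number of tandemly repeated domains varies a lot
even between closely related species (and split domains are a common
annotation artifact), consecutive repeats of the same domain are collapsed
to a single instance at ingest: the canonical form of ``A-B-B-B-C`` is
``A-B-C``.  All arrangements handled by this package are canonical.

Arrangements are order-sensitive (``A-B`` != ``B-A``) and are compared by
exact ordered content.  A node's repertoire is a plain presence/absence set
of arrangements: copy number is never stored.
"""
from __future__ import annotations

from itertools import groupby
from typing import Iterable, Iterator

from .errors import InvalidArrangementError

#: Separator used in the textual ``A-B-C`` notation.  Domain identifiers
#: may therefore not contain it.
SEPARATOR = "-"


def _check_domain_id(accession: object) -> str:
    if not isinstance(accession, str) or not accession:
        raise InvalidArrangementError(
            f"domain identifier must be a non-empty string, got {accession!r}"
        )
    if SEPARATOR in accession:
        raise InvalidArrangementError(
            f"domain identifier {accession!r} contains the reserved separator {SEPARATOR!r}"
        )
    return accession


class DomainArrangement(tuple):
    """An ordered, repeat-collapsed sequence of domain identifiers.

    Behaves as a tuple of strings (hashable, sliceable, comparable) and
    enforces canonical form on construction: non-empty, valid identifiers,
    and no two equal consecutive entries.  Use :func:`collapse_repeats` to
    canonicalize raw annotation output before constructing one.
    """

    __slots__ = ()

    def __new__(cls, domains: Iterable[str]) -> "DomainArrangement":
        doms = tuple(domains)
        if not doms:
            raise InvalidArrangementError("an arrangement must contain at least one domain")
        for d in doms:
            _check_domain_id(d)
        for a, b in zip(doms, doms[1:]):
            if a == b:
                raise InvalidArrangementError(
                    f"arrangement {SEPARATOR.join(doms)!r} is not repeat-collapsed "
                    f"(consecutive {a!r}); apply collapse_repeats() first"
                )
        return super().__new__(cls, doms)

    @classmethod
    def parse(cls, text: str) -> "DomainArrangement":
        """Parse the dash-separated ``A-B-C`` notation (must be canonical)."""
        return cls(text.strip().split(SEPARATOR))

    def __str__(self) -> str:
        return SEPARATOR.join(self)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"DomainArrangement({str(self)!r})"


def collapse_repeats(raw: Iterable[str]) -> DomainArrangement:
    """Collapse every maximal run of identical consecutive domains to one.

    ``A-B-B-B-C`` becomes ``A-B-C``; order is otherwise preserved.  This is
    the canonicalization applied to every arrangement read from annotation
    data.  Idempotent.
    """
    collapsed = [key for key, _ in groupby(raw)]
    return DomainArrangement(collapsed)


def concat_collapse(x: Iterable[str], y: Iterable[str]) -> DomainArrangement:
    """Canonical fusion product of two arrangements.

    Concatenates ``x`` and ``y`` and re-collapses; the result has length
    ``|x| + |y|`` or ``|x| + |y| - 1`` when the junction domains merge
    (``A-B`` + ``B-C`` -> ``A-B-C``).
    """
    return collapse_repeats(tuple(x) + tuple(y))


def terminal_truncations(arr: DomainArrangement) -> frozenset:
    """All single-terminus truncations of ``arr``.

    Returns every proper non-empty prefix and proper non-empty suffix, i.e.
    the products of removing >= 1 contiguous domains from exactly one end.
    A single-domain arrangement has no proper truncation (empty set).
    """
    n = len(arr)
    out = set()
    for i in range(1, n):
        out.add(DomainArrangement(arr[:i]))
        out.add(DomainArrangement(arr[i:]))
    return frozenset(out)


class ArrangementSet:
    """Presence/absence repertoire of arrangements at one tree node.

    An immutable set of :class:`DomainArrangement` with no multiplicity.
    Iteration order is deterministic (lexicographic on the textual form).
    """

    __slots__ = ("_arrs", "_content")

    def __init__(self, arrangements: Iterable = ()) -> None:
        arrs = frozenset(
            a if isinstance(a, DomainArrangement) else DomainArrangement(a)
            for a in arrangements
        )
        object.__setattr__(self, "_arrs", arrs)
        object.__setattr__(self, "_content", None)

    def __setattr__(self, name, value):  # immutability guard
        raise AttributeError("ArrangementSet is immutable")

    @property
    def arrangements(self) -> frozenset:
        return self._arrs

    @property
    def domain_content(self) -> frozenset:
        """Set of all domain identifiers appearing in any member arrangement."""
        if self._content is None:
            object.__setattr__(
                self, "_content", frozenset(d for arr in self._arrs for d in arr)
            )
        return self._content

    def __contains__(self, arr: object) -> bool:
        return arr in self._arrs

    def __iter__(self) -> Iterator[DomainArrangement]:
        return iter(sorted(self._arrs, key=str))

    def __len__(self) -> int:
        return len(self._arrs)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ArrangementSet):
            return self._arrs == other._arrs
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self._arrs)

    def __or__(self, other: "ArrangementSet") -> "ArrangementSet":
        return ArrangementSet(self._arrs | other._arrs)

    def difference(self, other: "ArrangementSet") -> frozenset:
        return self._arrs - other._arrs

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        inner = ", ".join(str(a) for a in self)
        return f"ArrangementSet({{{inner}}})"
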