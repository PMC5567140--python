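"""Gene-set collections and the GMT format.

A collection represents a merged pathway / GO-biological-process
database (Reactome, KEGG, Panther, WikiPathways, NCI Nature, Pathway
Commons, GO BP and the like) as named member sets.  Member identifiers
are case-sensitive opaque strings; no symbol aliasing is attempted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from mirmint.errors import FormatError


@dataclass
class GeneSet:
    """A named gene set; ``members`` keeps file order, duplicate-free."""

    name: str
    description: str = ""
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("gene set needs a non-empty name")
        seen: set[str] = set()
        deduped = []
        for m in self.members:
            if m not in seen:
                seen.add(m)
                deduped.append(m)
        if len(deduped) != len(self.members):
            warnings.warn(
                f"gene set {self.name!r}: duplicate members deduplicated"
            )
        self.members = deduped
        if not self.members:
            raise FormatError(f"gene set {self.name!r} has no members")

    @property
    def member_set(self) -> frozenset:
        return frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)


class GeneSetCollection:
    """Ordered, name-unique container of :class:`GeneSet`."""

    def __init__(self, sets=()):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            self.add(s)

    def add(self, s: GeneSet) -> None:
        if s.name in self._sets:
            raise FormatError(f"duplicate gene set name {s.name!r}")
        self._sets[s.name] = s

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets.values())

    def __contains__(self, name) -> bool:
        return name in self._sets

    def __getitem__(self, name) -> GeneSet:
        return self._sets[name]

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return [(s.name, s.description, s.members) for s in self] == [
            (s.name, s.description, s.members) for s in other
        ]


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (name<TAB>description<TAB>member...)."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            try:
                coll.add(GeneSet(name=name, description=desc, members=members))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return coll


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in coll:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


def size_filter(
    coll: GeneSetCollection,
    universe,
    min_size: int = 15,
    max_size: int = 500,
) -> GeneSetCollection:
    """Intersect sets with the analysis universe and filter by size.

    Members outside ``universe`` are dropped (file order kept for the
    survivors); sets whose effective size falls outside
    [min_size, max_size] are removed.  Effective sizes are recorded in the
    returned sets' descriptions only implicitly via ``len``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("size_filter: empty universe")
    if min_size > max_size:
        raise ValueError("min_size must be <= max_size")
    if max_size is None or math.isinf(max_size):
        max_size = math.inf
    out = GeneSetCollection()
    for s in coll:
        members = [m for m in s.members if m in universe]
        if min_size <= len(members) <= max_size:
            out.add(GeneSet(name=s.name, description=s.description,
                            members=members))
    return out
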