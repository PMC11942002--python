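"""Gene-set containers and GMT input/output.

A :class:`GeneSet` is a named, optionally directional collection of gene
identifiers (a reference signature, a marker panel, or an annotation source
list). A :class:`SignatureLibrary` is a name-keyed mapping of gene sets and
round-trips through the GMT format (one set per line: name, description,
then tab-separated gene ids). Direction and source labels are carried in the
description field as ``key=value`` pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, Mapping, Optional

__all__ = ["GeneSet", "SignatureLibrary", "read_gmt", "write_gmt"]


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers.

    Parameters
    ----------
    name
        Set label (e.g. ``"day7_top50"`` or ``"melanoma_up"``).
    genes
        Gene identifiers; order is preserved, duplicates are rejected.
    direction
        Optional ``"up"``/``"down"`` annotation, e.g. for disease signatures
        where it records the direction of dysregulation in the reference
        contrast.
    source
        Optional provenance label (database or generator name).
    """

    name: str
    genes: tuple
    direction: Optional[str] = None
    source: Optional[str] = None

    def __post_init__(self):
        genes = tuple(self.genes)
        if len(set(genes)) != len(genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate ids")
        if self.direction not in (None, "up", "down"):
            raise ValueError(f"direction must be 'up', 'down' or None, got {self.direction!r}")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __contains__(self, gene: object) -> bool:
        return gene in set(self.genes)

    def as_set(self) -> frozenset:
        return frozenset(self.genes)


class SignatureLibrary(Dict[str, GeneSet]):
    """Name-keyed collection of :class:`GeneSet` objects."""

    def add(self, gene_set: GeneSet) -> None:
        self[gene_set.name] = gene_set

    @classmethod
    def from_sets(cls, sets: Iterable[GeneSet]) -> "SignatureLibrary":
        lib = cls()
        for s in sets:
            lib.add(s)
        return lib


def _format_description(gene_set: GeneSet) -> str:
    parts = []
    if gene_set.direction:
        parts.append(f"direction={gene_set.direction}")
    if gene_set.source:
        parts.append(f"source={gene_set.source}")
    return ";".join(parts) if parts else "na"


def _parse_description(desc: str):
    direction = source = None
    for token in desc.split(";"):
        if token.startswith("direction="):
            direction = token.split("=", 1)[1] or None
        elif token.startswith("source="):
            source = token.split("=", 1)[1] or None
    return direction, source


def write_gmt(library: Mapping[str, GeneSet], path) -> None:
    """Write a signature library in GMT format (tab-delimited, one set/line)."""
    path = Path(path)
    with path.open("w") as fh:
        for name in library:
            gs = library[name]
            fields = [gs.name, _format_description(gs), *gs.genes]
            fh.write("\t".join(fields) + "\n")


def read_gmt(path) -> SignatureLibrary:
    """Read a GMT file into a :class:`SignatureLibrary`.

    Lines with fewer than three fields (name, description, ≥1 gene) are
    rejected — an empty gene set is not representable in GMT.
    """
    path = Path(path)
    library = SignatureLibrary()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc = fields[0], fields[1]
            direction, source = _parse_description(desc)
            library.add(GeneSet(name=name, genes=tuple(fields[2:]), direction=direction, source=source))
    return library
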