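"""Rooted region ontologies (neuroanatomical part-of hierarchies).

Brain-region nomenclatures are organised as rooted trees in which each named
region is a part of exactly one parent region. The ontology drives three
analysis steps: up-propagation of connections to a coarser parcellation,
selection of leaf regions (regions with no subparts in the expression atlas),
and the nomenclature similarity between two regions (their number of shared
ancestors).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .errors import DataError


@dataclass(frozen=True)
class Region:
    """One named region: an ontology node."""

    id: str
    name: str
    parent_id: str | None  # None only for the root


class RegionOntology:
    """A rooted tree of named brain regions.

    Parameters
    ----------
    regions
        Iterable of ``(id, name, parent_id)`` triples; exactly one region must
        have ``parent_id`` of ``None`` (the root). Ids must be unique and
        parent links acyclic.
    """

    def __init__(self, regions: Iterable[tuple[str, str, str | None]]):
        self._regions: dict[str, Region] = {}
        self._children: dict[str, list[str]] = {}
        roots = []
        for rid, name, parent in regions:
            rid = str(rid)
            if rid in self._regions:
                raise DataError(f"duplicate region id {rid!r}")
            parent = None if parent in (None, "") else str(parent)
            self._regions[rid] = Region(rid, str(name), parent)
            if parent is None:
                roots.append(rid)
        if len(roots) != 1:
            raise DataError(f"ontology must have exactly one root, found {len(roots)}")
        self._root = roots[0]
        for rid, reg in self._regions.items():
            if reg.parent_id is not None:
                if reg.parent_id not in self._regions:
                    raise DataError(f"region {rid!r} has unknown parent {reg.parent_id!r}")
                self._children.setdefault(reg.parent_id, []).append(rid)
        # acyclicity: every node must reach the root
        for rid in self._regions:
            seen = set()
            cur: str | None = rid
            while cur is not None:
                if cur in seen:
                    raise DataError(f"cycle in parent links involving {cur!r}")
                seen.add(cur)
                cur = self._regions[cur].parent_id
            # loop exits only at the root

    # -- basic accessors ---------------------------------------------------
    @property
    def root(self) -> str:
        return self._root

    @property
    def ids(self) -> list[str]:
        return list(self._regions)

    def __contains__(self, rid: str) -> bool:
        return rid in self._regions

    def __len__(self) -> int:
        return len(self._regions)

    def __iter__(self) -> Iterator[str]:
        return iter(self._regions)

    def name(self, rid: str) -> str:
        return self._get(rid).name

    def parent(self, rid: str) -> str | None:
        return self._get(rid).parent_id

    def children(self, rid: str) -> list[str]:
        self._get(rid)
        return list(self._children.get(rid, ()))

    def is_leaf(self, rid: str) -> bool:
        return not self._children.get(self._get(rid).id)

    def leaves(self) -> list[str]:
        return [rid for rid in self._regions if self.is_leaf(rid)]

    def _get(self, rid: str) -> Region:
        try:
            return self._regions[rid]
        except KeyError:
            raise DataError(f"unknown region id {rid!r}") from None

    # -- tree walks --------------------------------------------------------
    def ancestors(self, rid: str) -> list[str]:
        """Proper ancestors of ``rid`` from its parent up to the root."""
        out = []
        cur = self._get(rid).parent_id
        while cur is not None:
            out.append(cur)
            cur = self._regions[cur].parent_id
        return out

    def descendants(self, rid: str) -> set[str]:
        """Proper descendants (all subparts, recursively)."""
        self._get(rid)
        out: set[str] = set()
        queue = deque(self._children.get(rid, ()))
        while queue:
            cur = queue.popleft()
            out.add(cur)
            queue.extend(self._children.get(cur, ()))
        return out

    def depth(self, rid: str) -> int:
        return len(self.ancestors(rid))

    def top_division(self, rid: str) -> str:
        """The child of the root on the path to ``rid`` (``rid`` itself if a
        root child; the root for the root)."""
        if rid == self._root:
            return rid
        path = [rid] + self.ancestors(rid)
        return path[-2]

    # -- IO ----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": [r.id for r in self._regions.values()],
                "name": [r.name for r in self._regions.values()],
                "parent_id": [r.parent_id or "" for r in self._regions.values()],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RegionOntology":
        cols = {"region_id", "name", "parent_id"}
        if not cols.issubset(frame.columns):
            raise DataError(f"ontology table needs columns {sorted(cols)}")
        frame = frame.fillna({"parent_id": ""})
        return cls(zip(frame["region_id"], frame["name"], frame["parent_id"]))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionOntology":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False))
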