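"""Hierarchical region ontology (structure graph) and the two-level
leaf/parent decomposition that drives region-by-region registration.

Two annotation versions of the same brain share one hierarchy but carry
partially disjoint label sets.  Regions labelled identically in both volumes
are registered at *leaf* level; a region present in only one volume is covered
by walking rootward from its parent to the first ancestor with voxel support
(after descendant aggregation) in both volumes — the *parent* level.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .volio import LabeledVolume


class OntologyError(ValueError):
    """Structured parse/validation error naming the offending region id."""

    def __init__(self, message: str, region_id=None):
        super().__init__(message)
        self.region_id = region_id


@dataclass
class StructureNode:
    id: int
    acronym: str = ""
    name: str = ""
    parent_id: int | None = None
    children: list = field(default_factory=list)
    color: tuple = (128, 128, 128)


@dataclass
class StructureGraph:
    """Validated region hierarchy: unique positive ids, a single root,
    consistent parent/child pointers and no cycles."""

    nodes: dict  # id -> StructureNode

    def __post_init__(self):
        self._validate()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(cls, records) -> "StructureGraph":
        """Build from an iterable of dicts with ``id``/``parent_structure_id``
        (AIBS naming) or ``id``/``parent_id``."""
        nodes = {}
        for rec in records:
            rid = int(rec["id"])
            if rid in nodes:
                raise OntologyError(f"duplicate region id {rid}", rid)
            if rid <= 0:
                raise OntologyError(f"region id must be positive, got {rid}", rid)
            parent = rec.get("parent_structure_id", rec.get("parent_id"))
            parent = int(parent) if parent is not None else None
            color = rec.get("color_hex_triplet", rec.get("color"))
            if isinstance(color, str):
                color = tuple(int(color[i:i + 2], 16) for i in (0, 2, 4))
            elif color is None:
                color = (128, 128, 128)
            else:
                color = tuple(color)
            nodes[rid] = StructureNode(rid, rec.get("acronym", ""),
                                       rec.get("name", ""), parent, [], color)
        for node in nodes.values():
            if node.parent_id is not None:
                if node.parent_id not in nodes:
                    raise OntologyError(
                        f"region {node.id} references absent parent "
                        f"{node.parent_id}", node.id)
                nodes[node.parent_id].children.append(node.id)
        for node in nodes.values():
            node.children.sort()
        return cls(nodes)

    def _validate(self):
        roots = [n.id for n in self.nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise OntologyError(f"expected exactly one root, found {roots}")
        # cycle check: every node must reach the root
        root = roots[0]
        for nid in self.nodes:
            seen = set()
            cur = nid
            while cur is not None:
                if cur in seen:
                    raise OntologyError(f"cycle through region {cur}", cur)
                seen.add(cur)
                cur = self.nodes[cur].parent_id
            if root not in seen:
                raise OntologyError(f"region {nid} unreachable from root", nid)
        for node in self.nodes.values():
            for ch in node.children:
                if self.nodes[ch].parent_id != node.id:
                    raise OntologyError(
                        f"child {ch} parent pointer mismatch", ch)

    # -- queries ----------------------------------------------------------
    @property
    def root(self) -> int:
        return next(n.id for n in self.nodes.values() if n.parent_id is None)

    def __contains__(self, rid) -> bool:
        return rid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def leaves(self) -> set:
        return {n.id for n in self.nodes.values() if not n.children}

    def ancestors(self, rid: int) -> list:
        """Ancestor ids from the parent rootward (deterministic order)."""
        self._check(rid)
        out = []
        cur = self.nodes[rid].parent_id
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent_id
        return out

    def _check(self, rid):
        if rid not in self.nodes:
            raise OntologyError(f"unknown region id {rid}", rid)


def load_structure_graph(path) -> StructureGraph:
    """Parse an AIBS-style structure-graph JSON (nested ``msg`` document or
    flat list of nodes) into a validated :class:`StructureGraph`."""
    with open(path) as fh:
        doc = json.load(fh)
    if isinstance(doc, dict) and "msg" in doc:
        doc = doc["msg"]
    records = []
    if isinstance(doc, list) and doc and "children" in doc[0]:
        def walk(node, parent=None):
            rec = {k: v for k, v in node.items() if k != "children"}
            rec.setdefault("parent_structure_id", parent)
            records.append(rec)
            for ch in node.get("children", []):
                walk(ch, node["id"])
        for top in doc:
            walk(top)
    elif isinstance(doc, list):
        records = doc
    else:
        raise OntologyError("unrecognised structure-graph document")
    return StructureGraph.from_records(records)


def descendants(graph: StructureGraph, rid: int) -> set:
    """Transitive closure of children, excluding ``rid`` itself."""
    graph._check(rid)
    out = set()
    stack = list(graph.nodes[rid].children)
    while stack:
        cur = stack.pop()
        out.add(cur)
        stack.extend(graph.nodes[cur].children)
    return out


def _support_counts(ann: LabeledVolume) -> dict:
    return ann.label_counts()


def _aggregated_support(graph, counts, rid) -> int:
    """Voxel support of ``rid`` counting its own label and all descendants."""
    total = counts.get(rid, 0)
    for d in descendants(graph, rid):
        total += counts.get(d, 0)
    return total


def _warn_unknown(graph, counts, which):
    unknown = sorted(set(counts) - set(graph.nodes))
    if unknown:
        warnings.warn(f"labels in {which} absent from the structure graph: "
                      f"{unknown}", stacklevel=3)
    return unknown


def comparable_leaves(graph: StructureGraph, annA: LabeledVolume,
                      annB: LabeledVolume) -> set:
    """Leaf regions with at least one voxel carrying the same label in both
    annotation volumes."""
    ca, cb = _support_counts(annA), _support_counts(annB)
    _warn_unknown(graph, ca, "first annotation volume")
    _warn_unknown(graph, cb, "second annotation volume")
    leaves = graph.leaves()
    return {rid for rid in leaves if ca.get(rid, 0) > 0 and cb.get(rid, 0) > 0}


@dataclass
class LevelAssignment:
    """Two-level decomposition: ``leaf_ids`` register directly; every other
    voxel-supported leaf maps to its first common ancestor in ``parent_map``."""

    leaf_ids: set
    parent_map: dict  # leaf id -> assigned ancestor id

    def __post_init__(self):
        overlap = self.leaf_ids & set(self.parent_map)
        if overlap:
            raise OntologyError(f"regions assigned at both levels: {sorted(overlap)}")

    def parent_levels(self) -> set:
        return set(self.parent_map.values())


def assign_levels(graph: StructureGraph, annA: LabeledVolume,
                  annB: LabeledVolume) -> LevelAssignment:
    """Compute the leaf/parent decomposition for a pair of annotations.

    Leaves supported in both volumes register at leaf level.  A leaf
    supported in only one volume is covered by walking strictly rootward from
    its parent to the first ancestor whose descendant-aggregated support
    (own-label voxels included) is non-empty in both volumes.
    """
    ca, cb = _support_counts(annA), _support_counts(annB)
    shared = comparable_leaves(graph, annA, annB)
    parent_map = {}
    for rid in sorted(graph.leaves()):
        if rid in shared:
            continue
        if ca.get(rid, 0) == 0 and cb.get(rid, 0) == 0:
            continue  # no voxel support anywhere — nothing to cover
        assigned = None
        for anc in graph.ancestors(rid):
            if (_aggregated_support(graph, ca, anc) > 0
                    and _aggregated_support(graph, cb, anc) > 0):
                assigned = anc
                break
        if assigned is None:
            raise OntologyError(
                f"no ancestor of region {rid} has support in both volumes", rid)
        parent_map[rid] = assigned
    return LevelAssignment(shared, parent_map)


def region_mask(ann: LabeledVolume, graph: StructureGraph, rid: int,
                include_descendants: bool = True) -> np.ndarray:
    """Boolean mask of a region's voxels, optionally descendant-aggregated."""
    graph._check(rid)
    ids = {rid}
    if include_descendants:
        ids |= descendants(graph, rid)
    return np.isin(ann.labels, sorted(ids))
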