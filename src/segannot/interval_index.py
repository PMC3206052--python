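"""Binned segment-tree index answering stabbing and range-overlap queries.

Each chromosome is cut into fixed-size bins (UCSC-style).  A bin whose
feature count exceeds ``tree_threshold`` stores its features in a segment
tree: a balanced binary tree over the elementary intervals between the
sorted unique endpoints of the features (clipped to the bin for endpoint
collection).  Each stored feature decomposes into O(log n) canonical nodes,
so a stabbing query collects payloads along a single root-to-leaf path and a
range query follows the classic vsplit strategy: descend to the node where
the two query endpoints separate, then walk the two flanking paths,
harvesting whole right subtrees while walking left and whole left subtrees
while walking right.

Features spanning k bins are registered in all k; results are deduplicated
and sorted by (start, end, id) for deterministic output.

The on-disk index is a versioned JSON-lines container holding the feature
list plus build parameters; trees are rebuilt on load (building is fast, so
structural serialization would add complexity for no benefit).
"""

from __future__ import annotations

import datetime
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .gene_model import GenericFeature, Transcript

__all__ = [
    "IntervalIndex",
    "IndexFormatError",
    "OpCounter",
    "build_index",
    "stab",
    "range_query",
    "save_index",
    "load_index",
    "RANGE_CAP",
    "DEFAULT_BIN_SIZE",
    "DEFAULT_TREE_THRESHOLD",
]

MAGIC = "segannot-index"
FORMAT_VERSION = 1
RANGE_CAP = 100_000_000  # maximum query span in bp
DEFAULT_BIN_SIZE = 1_000_000
DEFAULT_TREE_THRESHOLD = 64
_NO_BINNING_SPAN = 1 << 62

Feature = Union[Transcript, GenericFeature]


class IndexFormatError(ValueError):
    """Raised when an index file is unreadable, truncated or wrong-version."""


@dataclass
class OpCounter:
    """Counts elementary work done by a query, for scaling diagnostics."""

    nodes: int = 0           # tree or bin nodes visited
    feature_checks: int = 0  # feature payload touches / interval comparisons

    @property
    def total(self) -> int:
        return self.nodes + self.feature_checks


class _Node:
    __slots__ = ("lo", "hi", "left", "right", "payload")

    def __init__(self, lo: int, hi: int):
        self.lo = lo
        self.hi = hi
        self.left: Optional[_Node] = None
        self.right: Optional[_Node] = None
        self.payload: list[Feature] = []


def _build_balanced(leaves: Sequence[tuple[int, int]], lo_i: int, hi_i: int) -> _Node:
    if hi_i - lo_i == 1:
        return _Node(*leaves[lo_i])
    mid = (lo_i + hi_i) // 2
    node = _Node(leaves[lo_i][0], leaves[hi_i - 1][1])
    node.left = _build_balanced(leaves, lo_i, mid)
    node.right = _build_balanced(leaves, mid, hi_i)
    return node


def _insert(node: _Node, s: int, e: int, feat: Feature) -> None:
    if s <= node.lo and node.hi <= e:
        node.payload.append(feat)
        return
    for child in (node.left, node.right):
        if child is not None and s < child.hi and child.lo < e:
            _insert(child, s, e, feat)


def _collect_subtree(node: _Node, out: list[Feature], counter: OpCounter) -> None:
    stack = [node]
    while stack:
        n = stack.pop()
        counter.nodes += 1
        if n.payload:
            out.extend(n.payload)
            counter.feature_checks += len(n.payload)
        if n.left is not None:
            stack.append(n.left)
            stack.append(n.right)


def tree_depth(node: Optional[_Node]) -> int:
    """Number of edges on the longest root-to-leaf path."""
    if node is None or node.left is None:
        return 0
    return 1 + max(tree_depth(node.left), tree_depth(node.right))


def tree_node_count(node: Optional[_Node]) -> int:
    if node is None:
        return 0
    return 1 + tree_node_count(node.left) + tree_node_count(node.right)


class _Bin:
    __slots__ = ("start", "end", "features", "root")

    def __init__(self, start: int, end: int):
        self.start = start
        self.end = end
        self.features: list[Feature] = []
        self.root: Optional[_Node] = None

    def build(self, tree_threshold: float) -> None:
        self.root = None
        if len(self.features) <= tree_threshold:
            return
        endpoints = set()
        for f in self.features:
            endpoints.add(max(f.start, self.start))
            endpoints.add(min(f.end, self.end))
        eps = sorted(endpoints)
        leaves = [(eps[i], eps[i + 1]) for i in range(len(eps) - 1)]
        if not leaves:
            return
        self.root = _build_balanced(leaves, 0, len(leaves))
        for f in self.features:
            _insert(self.root, max(f.start, self.start), min(f.end, self.end), f)

    # --- queries -----------------------------------------------------------

    def stab(self, pos: int, out: list[Feature], counter: OpCounter) -> None:
        if self.root is None:
            for f in self.features:
                counter.feature_checks += 1
                if f.start <= pos < f.end:
                    out.append(f)
            return
        node: Optional[_Node] = self.root
        if pos < node.lo or pos >= node.hi:
            return
        while node is not None:
            counter.nodes += 1
            if node.payload:
                out.extend(node.payload)
                counter.feature_checks += len(node.payload)
            if node.left is None:
                break
            node = node.left if pos < node.left.hi else node.right

    def range(self, qs: int, qe: int, out: list[Feature], counter: OpCounter) -> None:
        if self.root is None:
            for f in self.features:
                counter.feature_checks += 1
                if f.start < qe and qs < f.end:
                    out.append(f)
            return
        root = self.root
        p1, p2 = qs, qe - 1  # closed query points
        if p2 < root.lo or p1 >= root.hi:
            return
        node: Optional[_Node] = root
        while node is not None:
            counter.nodes += 1
            if node.payload:
                out.extend(node.payload)
                counter.feature_checks += len(node.payload)
            if node.left is None:
                return
            if p2 < node.left.hi:
                node = node.left
            elif p1 >= node.right.lo:
                node = node.right
            else:
                self._walk_left(node.left, p1, out, counter)
                self._walk_right(node.right, p2, out, counter)
                return

    @staticmethod
    def _walk_left(node: Optional[_Node], p1: int, out: list[Feature], counter: OpCounter) -> None:
        while node is not None:
            counter.nodes += 1
            if node.payload:
                out.extend(node.payload)
                counter.feature_checks += len(node.payload)
            if node.left is None:
                return
            if p1 < node.left.hi:
                _collect_subtree(node.right, out, counter)
                node = node.left
            else:
                node = node.right

    @staticmethod
    def _walk_right(node: Optional[_Node], p2: int, out: list[Feature], counter: OpCounter) -> None:
        while node is not None:
            counter.nodes += 1
            if node.payload:
                out.extend(node.payload)
                counter.feature_checks += len(node.payload)
            if node.left is None:
                return
            if p2 >= node.right.lo:
                _collect_subtree(node.left, out, counter)
                node = node.right
            else:
                node = node.left


def _normalize_bin_size(bin_size) -> Optional[int]:
    if bin_size is None or bin_size == math.inf:
        return None
    bin_size = int(bin_size)
    if bin_size <= 0:
        raise ValueError("bin_size must be positive (or None for no binning)")
    return bin_size


class IntervalIndex:
    """Per-chromosome binned store of features, dense bins held as trees."""

    def __init__(
        self,
        bin_size=DEFAULT_BIN_SIZE,
        tree_threshold: float = DEFAULT_TREE_THRESHOLD,
        provenance: Optional[dict] = None,
    ):
        self.bin_size = _normalize_bin_size(bin_size)
        self.tree_threshold = tree_threshold
        self.provenance = provenance or {}
        self._bins: dict[str, dict[int, _Bin]] = {}
        self._features: dict[str, list[Feature]] = {}
        self._built = True

    # --- construction ------------------------------------------------------

    def _bin_indices(self, start: int, end: int) -> range:
        if self.bin_size is None:
            return range(0, 1)
        return range(start // self.bin_size, (end - 1) // self.bin_size + 1)

    def _bin_bounds(self, i: int) -> tuple[int, int]:
        if self.bin_size is None:
            return 0, _NO_BINNING_SPAN
        return i * self.bin_size, (i + 1) * self.bin_size

    def add(self, feature: Feature) -> None:
        if feature.start >= feature.end:
            raise ValueError(f"feature {feature.id}: start must be < end")
        self._features.setdefault(feature.chrom, []).append(feature)
        chrom_bins = self._bins.setdefault(feature.chrom, {})
        for i in self._bin_indices(feature.start, feature.end):
            b = chrom_bins.get(i)
            if b is None:
                b = chrom_bins[i] = _Bin(*self._bin_bounds(i))
            b.features.append(feature)
        self._built = False

    def build(self) -> "IntervalIndex":
        for chrom_bins in self._bins.values():
            for b in chrom_bins.values():
                b.build(self.tree_threshold)
        self._built = True
        return self

    def _ensure_built(self) -> None:
        if not self._built:
            self.build()

    # --- queries -----------------------------------------------------------

    @staticmethod
    def _finish(out: list[Feature]) -> list[Feature]:
        seen: set[int] = set()
        unique = []
        for f in out:
            if id(f) not in seen:
                seen.add(id(f))
                unique.append(f)
        unique.sort(key=lambda f: (f.start, f.end, f.id))
        return unique

    def stab(self, chrom: str, pos: int, counter: Optional[OpCounter] = None) -> list[Feature]:
        """All features f on chrom with f.start <= pos < f.end."""
        if pos < 0:
            raise ValueError("position must be >= 0")
        self._ensure_built()
        counter = counter if counter is not None else OpCounter()
        chrom_bins = self._bins.get(chrom)
        if not chrom_bins:
            return []
        i = 0 if self.bin_size is None else pos // self.bin_size
        b = chrom_bins.get(i)
        if b is None:
            return []
        out: list[Feature] = []
        b.stab(pos, out, counter)
        return self._finish(out)

    def range_query(
        self, chrom: str, start: int, end: int, counter: Optional[OpCounter] = None
    ) -> list[Feature]:
        """All features overlapping [start, end); span capped at 100 Mbp."""
        if start >= end:
            raise ValueError("range query needs start < end")
        if end - start > RANGE_CAP:
            raise ValueError(f"query span {end - start} exceeds the {RANGE_CAP} bp cap")
        self._ensure_built()
        counter = counter if counter is not None else OpCounter()
        chrom_bins = self._bins.get(chrom)
        if not chrom_bins:
            return []
        out: list[Feature] = []
        for i in self._bin_indices(max(start, 0), end):
            b = chrom_bins.get(i)
            if b is not None:
                b.range(start, end, out, counter)
        return self._finish(out)

    # --- introspection -----------------------------------------------------

    @property
    def n_features(self) -> int:
        return sum(len(v) for v in self._features.values())

    def describe(self) -> dict:
        self._ensure_built()
        n_bins = sum(len(v) for v in self._bins.values())
        n_tree_bins = sum(
            1 for v in self._bins.values() for b in v.values() if b.root is not None
        )
        return {
            "format_version": FORMAT_VERSION,
            "bin_size": self.bin_size,
            "tree_threshold": self.tree_threshold,
            "chromosomes": sorted(self._features),
            "n_features": self.n_features,
            "n_bins": n_bins,
            "n_tree_bins": n_tree_bins,
            "provenance": self.provenance,
        }

    def iter_features(self) -> Iterable[Feature]:
        for chrom in sorted(self._features):
            yield from self._features[chrom]

    # --- serialization -----------------------------------------------------

    def save(self, path: str) -> None:
        feats = list(self.iter_features())
        header = {
            "magic": MAGIC,
            "version": FORMAT_VERSION,
            "bin_size": self.bin_size,
            "tree_threshold": (
                None if self.tree_threshold == math.inf else self.tree_threshold
            ),
            "provenance": self.provenance,
            "n_features": len(feats),
        }
        with open(path, "w") as fh:
            fh.write(json.dumps(header) + "\n")
            for f in feats:
                fh.write(json.dumps(_feature_to_dict(f)) + "\n")
            fh.write(json.dumps({"end": len(feats)}) + "\n")

    @classmethod
    def load(cls, path: str) -> "IntervalIndex":
        try:
            with open(path) as fh:
                text = fh.read()
        except OSError as exc:
            raise IndexFormatError(f"cannot read index file: {exc}") from exc
        if not text:
            raise IndexFormatError("empty index file")
        if not text.endswith("\n"):
            raise IndexFormatError("truncated index: incomplete final line")
        lines = text.splitlines()
        try:
            header = json.loads(lines[0])
        except json.JSONDecodeError as exc:
            raise IndexFormatError(f"corrupt index header: {exc}") from exc
        if not isinstance(header, dict) or header.get("magic") != MAGIC:
            raise IndexFormatError("not a segannot index file (bad magic)")
        if header.get("version") != FORMAT_VERSION:
            raise IndexFormatError(
                f"unsupported index version {header.get('version')!r}; "
                f"this build reads version {FORMAT_VERSION}"
            )
        n = header.get("n_features")
        body = lines[1:]
        if len(body) != n + 1:
            raise IndexFormatError(
                f"truncated index: expected {n} feature rows plus end marker"
            )
        try:
            end_marker = json.loads(body[-1])
        except json.JSONDecodeError as exc:
            raise IndexFormatError(f"corrupt end marker: {exc}") from exc
        if end_marker != {"end": n}:
            raise IndexFormatError("truncated index: end marker mismatch")
        threshold = header.get("tree_threshold")
        index = cls(
            bin_size=header.get("bin_size"),
            tree_threshold=math.inf if threshold is None else threshold,
            provenance=header.get("provenance") or {},
        )
        for lineno, raw in enumerate(body[:-1], 2):
            try:
                index.add(_feature_from_dict(json.loads(raw)))
            except (json.JSONDecodeError, ValueError, KeyError) as exc:
                raise IndexFormatError(f"corrupt feature at line {lineno}: {exc}") from exc
        return index.build()


def _feature_to_dict(f: Feature) -> dict:
    if isinstance(f, Transcript):
        return {
            "kind": "transcript",
            "id": f.id,
            "gene": f.gene,
            "chrom": f.chrom,
            "strand": f.strand,
            "tx_start": f.tx_start,
            "tx_end": f.tx_end,
            "cds_start": f.cds_start,
            "cds_end": f.cds_end,
            "exons": [list(x) for x in f.exons],
        }
    if isinstance(f, GenericFeature):
        return {
            "kind": "feature",
            "id": f.id,
            "chrom": f.chrom,
            "strand": f.strand,
            "start": f.start,
            "end": f.end,
            "blocks": None if f.blocks is None else [list(x) for x in f.blocks],
        }
    raise TypeError(f"cannot serialize feature of type {type(f).__name__}")


def _feature_from_dict(d: dict) -> Feature:
    kind = d.get("kind")
    if kind == "transcript":
        return Transcript(
            id=d["id"],
            gene=d["gene"],
            chrom=d["chrom"],
            strand=d["strand"],
            tx_start=d["tx_start"],
            tx_end=d["tx_end"],
            cds_start=d["cds_start"],
            cds_end=d["cds_end"],
            exons=tuple(tuple(x) for x in d["exons"]),
        )
    if kind == "feature":
        blocks = d.get("blocks")
        return GenericFeature(
            id=d["id"],
            chrom=d["chrom"],
            strand=d["strand"],
            start=d["start"],
            end=d["end"],
            blocks=None if blocks is None else tuple(tuple(x) for x in blocks),
        )
    raise ValueError(f"unknown feature kind {kind!r}")


# ---------------------------------------------------------------------------
# functional wrappers


def build_index(
    features: Iterable[Feature],
    bin_size=DEFAULT_BIN_SIZE,
    tree_threshold: float = DEFAULT_TREE_THRESHOLD,
    provenance: Optional[dict] = None,
) -> IntervalIndex:
    """Build a query-ready index; an empty feature list is a valid index."""
    if provenance is not None and "built" not in provenance:
        provenance = dict(provenance)
        provenance["built"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    index = IntervalIndex(bin_size=bin_size, tree_threshold=tree_threshold, provenance=provenance)
    for f in features:
        index.add(f)
    return index.build()


def stab(index: IntervalIndex, chrom: str, pos: int) -> list[Feature]:
    return index.stab(chrom, pos)


def range_query(index: IntervalIndex, chrom: str, start: int, end: int) -> list[Feature]:
    return index.range_query(chrom, start, end)


def save_index(index: IntervalIndex, path: str) -> None:
    index.save(path)


def load_index(path: str) -> IntervalIndex:
    return IntervalIndex.load(path)
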