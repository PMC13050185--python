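"""Construction of kinship networks from pairwise IBD sharing.

A kinship network is an undirected simple graph on sampled individuals in
which an edge records "sufficient" genomic sharing between two people.  The
raw data are pairwise measures of identity-by-descent (IBD): either a list of
shared segment lengths in centimorgans (cM) for each pair, or pre-summarised
counts of segments above fixed length thresholds.  The network is obtained by
thresholding these measures; non-qualifying pairs are coded as non-edges, not
as missing, so the full set of n(n-1)/2 dyads is the unit of observation for
downstream regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "NodeTable",
    "IBDPairRecord",
    "ScalarRule",
    "TwoBlockRule",
    "KinNetwork",
    "threshold_network",
    "read_nodes",
    "read_pairs",
    "read_network",
    "write_network",
]

# Fixed segment-length thresholds (cM) carried by summary-format pair records.
SUMMARY_L1 = 12.0
SUMMARY_L2 = 16.0


class NodeTable:
    """Individuals and their categorical attributes, in first-appearance order.

    Parameters
    ----------
    ids
        Unique string identifiers, one per individual.  The order given here
        fixes the node order used for dyad enumeration everywhere else.
    attributes
        Mapping attribute name -> sequence of level labels (one per node).
        ``None`` marks a missing value.
    levels
        Optional declared level sets per attribute.  Defaults to the sorted
        observed levels.  Declaring levels lets an unobserved category keep a
        slot in mixing tables.
    """

    def __init__(
        self,
        ids: Sequence[str],
        attributes: Mapping[str, Sequence[str | None]] | None = None,
        levels: Mapping[str, Sequence[str]] | None = None,
    ) -> None:
        self.ids: list[str] = [str(i) for i in ids]
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate node_id values: {dupes}")
        self.attributes: dict[str, list[str | None]] = {}
        self.levels: dict[str, list[str]] = {}
        attributes = attributes or {}
        for name, values in attributes.items():
            if name == "id":
                raise ValueError('attribute may not be named "id"')
            vals = [None if _is_missing(v) else str(v) for v in values]
            if len(vals) != len(self.ids):
                raise ValueError(
                    f"attribute {name!r}: {len(vals)} values for {len(self.ids)} nodes"
                )
            observed = sorted({v for v in vals if v is not None})
            if levels is not None and name in levels:
                declared = [str(l) for l in levels[name]]
                extra = set(observed) - set(declared)
                if extra:
                    raise ValueError(
                        f"attribute {name!r}: values {sorted(extra)} outside "
                        f"declared levels {declared}"
                    )
            else:
                declared = observed
            self.attributes[name] = vals
            self.levels[name] = declared
        self._index = {node_id: k for k, node_id in enumerate(self.ids)}

    # -- basic protocol ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return len(self.ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NodeTable):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.attributes == other.attributes
            and self.levels == other.levels
        )

    def index_of(self, node_id: str) -> int:
        try:
            return self._index[node_id]
        except KeyError:
            raise KeyError(f"unknown node ID: {node_id!r}") from None

    def codes(self, attribute: str) -> np.ndarray:
        """Integer level codes for ``attribute`` (-1 for missing)."""
        level_index = {l: k for k, l in enumerate(self.levels[attribute])}
        return np.array(
            [-1 if v is None else level_index[v] for v in self.attributes[attribute]],
            dtype=np.int64,
        )

    def with_combined(
        self, attrs: Sequence[str], name: str | None = None, sep: str = "/"
    ) -> "NodeTable":
        """Return a copy with a composite attribute formed from ``attrs``.

        Level labels are the ``sep``-joined component labels; a missing
        component makes the composite missing.  This is the explicit route to
        e.g. a joint sex-by-age class used as a single mixing variable.
        """
        name = name or sep.join(attrs)
        combined: list[str | None] = []
        for k in range(self.n):
            parts = [self.attributes[a][k] for a in attrs]
            combined.append(None if any(p is None for p in parts) else sep.join(parts))
        new_attrs = dict(self.attributes)
        new_attrs[name] = combined
        new_levels = dict(self.levels)
        new_levels.pop(name, None)
        nt = NodeTable(self.ids, new_attrs)
        for a, lv in new_levels.items():
            nt.levels[a] = list(lv)
        return nt

    def to_frame(self) -> pd.DataFrame:
        data = {"id": self.ids}
        data.update({a: v for a, v in self.attributes.items()})
        return pd.DataFrame(data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"NodeTable(n={self.n}, attributes={list(self.attributes)})"


def _is_missing(v: object) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return False


@dataclass(frozen=True)
class IBDPairRecord:
    """IBD sharing between one unordered pair of individuals.

    Either ``segments`` (per-segment cM lengths) or the summary triple
    (``n_ge12``, ``n_ge16``, ``total_cm``) must be supplied; the summary
    counts refer to the fixed 12 cM / 16 cM length thresholds.
    """

    id_i: str
    id_j: str
    segments: tuple[float, ...] | None = None
    n_ge12: int | None = None
    n_ge16: int | None = None
    total_cm: float | None = None

    def __post_init__(self) -> None:
        if self.id_i == self.id_j:
            raise ValueError(f"self-pair not allowed: {self.id_i!r}")
        if self.segments is not None:
            segs = tuple(float(s) for s in self.segments)
            if any(not math.isfinite(s) or s < 0 for s in segs):
                raise ValueError(f"pair ({self.id_i},{self.id_j}): segment lengths "
                                 "must be finite and non-negative")
            object.__setattr__(self, "segments", segs)
            if self.total_cm is None:
                object.__setattr__(self, "total_cm", float(sum(segs)))
        elif self.total_cm is None:
            raise ValueError(
                f"pair ({self.id_i},{self.id_j}): need segments or a summary triple"
            )
        if self.total_cm is not None and (
            not math.isfinite(self.total_cm) or self.total_cm < 0
        ):
            raise ValueError(f"pair ({self.id_i},{self.id_j}): total_cm must be "
                             "finite and non-negative")

    @property
    def key(self) -> tuple[str, str]:
        return (self.id_i, self.id_j) if self.id_i < self.id_j else (self.id_j, self.id_i)

    def blocks_ge(self, length: float) -> int:
        """Number of shared segments of length >= ``length`` cM."""
        if self.segments is not None:
            return int(sum(1 for s in self.segments if s >= length))
        if length == SUMMARY_L1 and self.n_ge12 is not None:
            return int(self.n_ge12)
        if length == SUMMARY_L2 and self.n_ge16 is not None:
            return int(self.n_ge16)
        raise ValueError(
            f"pair ({self.id_i},{self.id_j}): block count at {length} cM requires "
            "segment-level data (summary records carry counts at 12 and 16 cM only)"
        )

    def scalar(self, field_name: str = "total_cm") -> float:
        value = getattr(self, field_name, None)
        if value is None:
            raise ValueError(
                f"pair ({self.id_i},{self.id_j}): field {field_name!r} not available"
            )
        return float(value)


@dataclass(frozen=True)
class ScalarRule:
    """Edge iff a scalar sharing statistic e_ij >= cutoff (boundary inclusive)."""

    cutoff: float
    field: str = "total_cm"

    def __post_init__(self) -> None:
        if not math.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")

    def fires(self, rec: IBDPairRecord) -> bool:
        return rec.scalar(self.field) >= self.cutoff


@dataclass(frozen=True)
class TwoBlockRule:
    """Edge iff >= k1 segments of length >= l1 cM and >= k2 of length >= l2 cM.

    The default (12, 2; 16, 1) is the empirical rule: at least two blocks of
    at least 12 cM and at least one block of at least 16 cM, roughly at least
    seventh-degree relatedness.
    """

    l1: float = 12.0
    k1: int = 2
    l2: float = 16.0
    k2: int = 1

    def __post_init__(self) -> None:
        if not (self.l2 >= self.l1 > 0):
            raise ValueError("need L2 >= L1 > 0")
        if not (self.k1 >= self.k2 >= 1):
            raise ValueError("need k1 >= k2 >= 1")

    def fires(self, rec: IBDPairRecord) -> bool:
        return rec.blocks_ge(self.l1) >= self.k1 and rec.blocks_ge(self.l2) >= self.k2


ThresholdRule = ScalarRule | TwoBlockRule


@dataclass
class KinNetwork:
    """An undirected simple kinship network over a fixed node table.

    Isolated nodes are retained: a non-edge is an observation (a dyad with
    response 0), not missing data.  Edge weights, where present, are total
    shared cM.
    """

    nodes: NodeTable
    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        g = nx.Graph()
        g.add_nodes_from(self.nodes.ids)
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            if u not in self.nodes._index or v not in self.nodes._index:
                missing = u if u not in self.nodes._index else v
                raise ValueError(f"edge endpoint {missing!r} not in node table")
            w = data.get("weight")
            if w is not None and not (float(w) > 0):
                raise ValueError(f"edge ({u},{v}): weight must be > 0")
            g.add_edge(u, v, **data)
        self.graph = g

    @property
    def n(self) -> int:
        return self.nodes.n

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_dyads(self) -> int:
        return self.n * (self.n - 1) // 2

    @property
    def density(self) -> float:
        return self.n_edges / self.n_dyads if self.n_dyads else 0.0

    def edge_index_pairs(self) -> set[tuple[int, int]]:
        idx = self.nodes._index
        out = set()
        for u, v in self.graph.edges():
            a, b = idx[u], idx[v]
            out.add((a, b) if a < b else (b, a))
        return out

    def y_vector(self) -> np.ndarray:
        """0/1 response over dyads (i, j), i < j, in node-table order."""
        n = self.n
        adj = np.zeros((n, n), dtype=bool)
        for a, b in self.edge_index_pairs():
            adj[a, b] = True
        iu, ju = np.triu_indices(n, 1)
        return adj[iu, ju].astype(np.uint8)

    @classmethod
    def from_edges(
        cls,
        nodes: NodeTable,
        edges: Iterable[tuple[str, str]],
        weights: Mapping[tuple[str, str], float] | None = None,
    ) -> "KinNetwork":
        g = nx.Graph()
        g.add_nodes_from(nodes.ids)
        for u, v in edges:
            attrs = {}
            if weights is not None:
                w = weights.get((u, v), weights.get((v, u)))
                if w is not None:
                    attrs["weight"] = float(w)
            g.add_edge(u, v, **attrs)
        return cls(nodes, g)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KinNetwork):
            return NotImplemented
        if self.nodes != other.nodes:
            return False
        mine = {tuple(sorted(e)): d.get("weight") for *e, d in self.graph.edges(data=True)}
        theirs = {tuple(sorted(e)): d.get("weight") for *e, d in other.graph.edges(data=True)}
        return mine == theirs


def threshold_network(
    pairs: Iterable[IBDPairRecord],
    nodes: NodeTable,
    rule: ThresholdRule,
) -> KinNetwork:
    """Build the kinship network by applying ``rule`` to each pair record.

    Pairs absent from the input are treated as e_ij = 0 (no measured
    sharing), so they simply remain non-edges.  Nodes with no qualifying
    pair are retained as isolates.

    Raises
    ------
    KeyError
        If a pair references an ID not present in ``nodes``.
    ValueError
        If the same unordered pair occurs more than once.
    """
    seen: set[tuple[str, str]] = set()
    g = nx.Graph()
    g.add_nodes_from(nodes.ids)
    for rec in pairs:
        for nid in (rec.id_i, rec.id_j):
            if nid not in nodes._index:
                raise KeyError(f"pair references unknown node ID: {nid!r}")
        if rec.key in seen:
            raise ValueError(f"duplicate unordered pair: {rec.key}")
        seen.add(rec.key)
        if rule.fires(rec):
            attrs = {}
            if rec.total_cm is not None and rec.total_cm > 0:
                attrs["weight"] = float(rec.total_cm)
            g.add_edge(rec.id_i, rec.id_j, **attrs)
    return KinNetwork(nodes, g)


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------

def read_nodes(path) -> NodeTable:
    """Read a node metadata CSV: an ``id`` column plus one column per attribute."""
    df = pd.read_csv(path, dtype=str)
    if "id" not in df.columns:
        raise ValueError(f"{path}: node CSV must have an 'id' column "
                         f"(found {list(df.columns)})")
    ids = df["id"].tolist()
    bad = df.index[df["id"].isna()].tolist()
    if bad:
        raise ValueError(f"{path}: missing id on data line(s) {[i + 2 for i in bad]}")
    dupe_mask = df["id"].duplicated(keep=False)
    if dupe_mask.any():
        lines = [i + 2 for i in df.index[dupe_mask]]
        raise ValueError(f"{path}: duplicated node_id on data line(s) {lines}")
    attrs = {c: df[c].tolist() for c in df.columns if c != "id"}
    return NodeTable(ids, attrs)


def read_pairs(path) -> list[IBDPairRecord]:
    """Read a pairwise IBD CSV.

    Two layouts are accepted:

    * segment-level: columns ``id1,id2,length_cM``, one row per segment
      (rows for the same unordered pair are aggregated into one record);
    * summary: columns ``id1,id2,n_ge12,n_ge16,total_cM``, one row per pair.
    """
    df = pd.read_csv(path, dtype=str)
    cols = set(df.columns)
    if {"id1", "id2", "length_cM"} <= cols:
        segs: dict[tuple[str, str], list[float]] = {}
        for row_idx, row in df.iterrows():
            line = row_idx + 2
            try:
                length = float(row["length_cM"])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: line {line}: bad length_cM {row['length_cM']!r}"
                ) from None
            i, j = str(row["id1"]), str(row["id2"])
            key = (i, j) if i < j else (j, i)
            segs.setdefault(key, []).append(length)
        return [
            IBDPairRecord(i, j, segments=tuple(lengths))
            for (i, j), lengths in segs.items()
        ]
    if {"id1", "id2", "n_ge12", "n_ge16", "total_cM"} <= cols:
        out = []
        for row_idx, row in df.iterrows():
            line = row_idx + 2
            try:
                out.append(
                    IBDPairRecord(
                        str(row["id1"]),
                        str(row["id2"]),
                        n_ge12=int(row["n_ge12"]),
                        n_ge16=int(row["n_ge16"]),
                        total_cm=float(row["total_cM"]),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}: line {line}: {exc}") from None
        return out
    raise ValueError(
        f"{path}: unrecognised pair CSV columns {sorted(cols)}; expected "
        "id1,id2,length_cM or id1,id2,n_ge12,n_ge16,total_cM"
    )


def write_network(net: KinNetwork, path, fmt: str | None = None) -> None:
    """Write a network as edge-list CSV or GraphML (inferred from extension).

    GraphML embeds node attributes and preserves node order, so it round
    trips on its own; the edge-list CSV needs the node CSV alongside to
    restore isolates and attributes.
    """
    path = str(path)
    fmt = fmt or ("graphml" if path.endswith(".graphml") else "csv")
    if fmt == "csv":
        rows = []
        for u, v, data in net.graph.edges(data=True):
            a, b = (u, v) if net.nodes.index_of(u) < net.nodes.index_of(v) else (v, u)
            rows.append({"id1": a, "id2": b, "weight": data.get("weight", "")})
        rows.sort(key=lambda r: (net.nodes.index_of(r["id1"]), net.nodes.index_of(r["id2"])))
        pd.DataFrame(rows, columns=["id1", "id2", "weight"]).to_csv(path, index=False)
    elif fmt == "graphml":
        g = nx.Graph()
        for k, nid in enumerate(net.nodes.ids):
            attrs = {a: v for a, v in ((a, net.nodes.attributes[a][k])
                                       for a in net.nodes.attributes) if v is not None}
            g.add_node(nid, _order=k, **attrs)
        for u, v, data in net.graph.edges(data=True):
            g.add_edge(u, v, **{k: v2 for k, v2 in data.items() if v2 is not None})
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format: {fmt!r}")


def read_network(path, nodes: NodeTable | None = None) -> KinNetwork:
    """Read a network written by :func:`write_network`.

    For edge-list CSV a ``nodes`` table is required (the CSV records edges
    only).  For GraphML, node attributes and order are recovered from the
    file; a supplied ``nodes`` table overrides them.
    """
    path = str(path)
    if path.endswith(".graphml"):
        g = nx.read_graphml(path)
        if nodes is None:
            order = sorted(g.nodes(), key=lambda u: int(g.nodes[u].get("_order", 0)))
            attr_names = sorted(
                {a for u in g.nodes for a in g.nodes[u] if a != "_order"}
            )
            attrs = {a: [g.nodes[u].get(a) for u in order] for a in attr_names}
            nodes = NodeTable([str(u) for u in order], attrs)
        h = nx.Graph()
        h.add_nodes_from(nodes.ids)
        for u, v, data in g.edges(data=True):
            h.add_edge(str(u), str(v), **{k: w for k, w in data.items()})
        return KinNetwork(nodes, h)
    if nodes is None:
        raise ValueError("reading an edge-list CSV requires the node table")
    df = pd.read_csv(path, dtype={"id1": str, "id2": str})
    weights = {}
    edges = []
    for _, row in df.iterrows():
        edges.append((row["id1"], row["id2"]))
        if "weight" in df.columns and pd.notna(row["weight"]) and row["weight"] != "":
            weights[(row["id1"], row["id2"])] = float(row["weight"])
    return KinNetwork.from_edges(nodes, edges, weights)
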