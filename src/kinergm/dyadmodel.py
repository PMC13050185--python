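"""Dyad-level design matrices for dyad-independent ERGM terms.

A dyad-independent ERGM on an undirected simple graph is a Bernoulli model:
each of the n(n-1)/2 unordered dyads (i, j) has an independent edge
indicator whose log-odds is a linear function of covariates built from the
two endpoints' attributes,

    log(p_ij / (1 - p_ij)) = theta_0 + sum_k theta_k z_ijk + sum_l lambda_l w_ijl.

The z_ijk here are homophily/mixing indicators:

* ``nodematch`` — one column, I(v_i = v_j): simple homophily;
* ``nodematch_diff`` — one column per level a, I(v_i = v_j = a):
  differential homophily;
* ``nodemix`` — one column per unordered level pair except a reference cell:
  full attribute mixing;
* ``edgecov`` — a user-supplied real dyad covariate w_ij.

Dyads are enumerated (i, j) with i < j in node-table order, so the matrix
layout is deterministic.  Columns are named ``<kind>.<attribute>.<levels>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Mapping, Sequence

import numpy as np

from .netbuild import KinNetwork, NodeTable

__all__ = ["TermSpec", "ModelSpec", "DyadDesign", "build_design",
           "edges", "nodematch", "nodematch_diff", "nodemix", "edgecov"]

_KINDS = {"edges", "nodematch", "nodematch_diff", "nodemix", "edgecov"}


@dataclass(frozen=True)
class TermSpec:
    """One model term: an intercept, a homophily/mixing family, or an edge covariate."""

    kind: str
    attribute: str | None = None
    base_cell: tuple[str, str] | None = None
    name: str | None = None  # edgecov covariate name

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown term kind: {self.kind!r}")
        if self.kind in {"nodematch", "nodematch_diff", "nodemix"} and not self.attribute:
            raise ValueError(f"{self.kind} term requires an attribute")
        if self.kind == "edgecov" and not self.name:
            raise ValueError("edgecov term requires a covariate name")
        if self.base_cell is not None and self.kind != "nodemix":
            raise ValueError("base_cell applies to nodemix terms only")

    # -- column bookkeeping -------------------------------------------------
    def mix_cells(self, levels: Sequence[str]) -> list[tuple[str, str]]:
        """Unordered level-pair cells minus the reference cell, in lexicographic order."""
        cells = list(combinations_with_replacement(sorted(levels), 2))
        base = self.base_cell or cells[0]
        base = tuple(sorted(base))
        if base not in cells:
            raise ValueError(f"base_cell {base} is not a valid level pair of "
                             f"{sorted(levels)}")
        return [c for c in cells if c != base]

    def column_names(self, nodes: NodeTable) -> list[str]:
        if self.kind == "edges":
            return ["edges"]
        if self.kind == "edgecov":
            return [f"edgecov.{self.name}"]
        levels = nodes.levels[self.attribute]
        if len(levels) < 2:
            raise ValueError(
                f"attribute {self.attribute!r} has {len(levels)} level(s); "
                "matched terms need at least 2"
            )
        if self.kind == "nodematch":
            return [f"nodematch.{self.attribute}"]
        if self.kind == "nodematch_diff":
            return [f"nodematch_diff.{self.attribute}.{a}" for a in levels]
        return [f"nodemix.{self.attribute}.{a}.{b}" for a, b in self.mix_cells(levels)]

    def key(self) -> tuple[str, str | None]:
        return (self.kind, self.attribute if self.kind != "edgecov" else self.name)


def edges() -> TermSpec:
    return TermSpec("edges")


def nodematch(attribute: str) -> TermSpec:
    return TermSpec("nodematch", attribute)


def nodematch_diff(attribute: str) -> TermSpec:
    return TermSpec("nodematch_diff", attribute)


def nodemix(attribute: str, base_cell: tuple[str, str] | None = None) -> TermSpec:
    if base_cell is not None:
        base_cell = tuple(sorted(str(x) for x in base_cell))  # type: ignore[assignment]
    return TermSpec("nodemix", attribute, base_cell=base_cell)


def edgecov(name: str) -> TermSpec:
    return TermSpec("edgecov", name=name)


@dataclass(frozen=True)
class ModelSpec:
    """An ordered list of terms; the first must be the ``edges`` intercept."""

    terms: tuple[TermSpec, ...]
    label: str = ""

    def __init__(self, terms: Sequence[TermSpec], label: str | None = None) -> None:
        terms = tuple(terms)
        if not terms or terms[0].kind != "edges":
            raise ValueError("first term must be the edges intercept")
        if sum(1 for t in terms if t.kind == "edges") != 1:
            raise ValueError("exactly one edges term allowed")
        keys = [t.key() for t in terms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicated (kind, attribute) term")
        object.__setattr__(self, "terms", terms)
        if label is None:
            label = "+".join(
                t.kind if t.kind == "edges" else f"{t.kind}({t.attribute or t.name})"
                for t in terms
            )
        object.__setattr__(self, "label", label)

    def attributes(self) -> list[str]:
        return [t.attribute for t in self.terms if t.attribute]

    def column_names(self, nodes: NodeTable) -> list[str]:
        out: list[str] = []
        for t in self.terms:
            out.extend(t.column_names(nodes))
        return out

    def n_params(self, nodes: NodeTable) -> int:
        """Total parameter count k, including the intercept."""
        return len(self.column_names(nodes))


@dataclass
class DyadDesign:
    """Response vector and design matrix over all dyads (i, j), i < j."""

    nodes: NodeTable
    spec: ModelSpec
    pair_i: np.ndarray
    pair_j: np.ndarray
    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    term_slices: dict[int, slice] = field(default_factory=dict)

    @property
    def n_dyads(self) -> int:
        return len(self.y)

    @property
    def k(self) -> int:
        return self.X.shape[1]


def _term_columns(
    term: TermSpec,
    nodes: NodeTable,
    iu: np.ndarray,
    ju: np.ndarray,
    edge_covariates: Mapping[str, np.ndarray] | None,
) -> np.ndarray:
    m = len(iu)
    if term.kind == "edges":
        return np.ones((m, 1))
    if term.kind == "edgecov":
        if not edge_covariates or term.name not in edge_covariates:
            raise ValueError(f"edge covariate {term.name!r} not supplied")
        w = np.asarray(edge_covariates[term.name], dtype=float)
        if w.shape != (m,):
            raise ValueError(
                f"edge covariate {term.name!r}: expected {m} dyad values, got {w.shape}"
            )
        return w[:, None]
    codes = nodes.codes(term.attribute)
    missing = np.flatnonzero(codes < 0)
    if missing.size:
        names = [nodes.ids[k] for k in missing]
        raise ValueError(
            f"attribute {term.attribute!r} missing on node(s) {names}; "
            "supply values or rebuild with drop_incomplete=True"
        )
    ci, cj = codes[iu], codes[ju]
    levels = nodes.levels[term.attribute]
    if len(levels) < 2:
        raise ValueError(
            f"attribute {term.attribute!r} has {len(levels)} level(s); "
            "matched terms need at least 2"
        )
    if term.kind == "nodematch":
        return (ci == cj).astype(float)[:, None]
    if term.kind == "nodematch_diff":
        return np.column_stack(
            [((ci == a) & (cj == a)).astype(float) for a in range(len(levels))]
        )
    # nodemix
    cells = term.mix_cells(levels)
    index = {l: k for k, l in enumerate(levels)}
    lo = np.minimum(ci, cj)
    hi = np.maximum(ci, cj)
    cols = []
    for a, b in cells:
        ca, cb = index[a], index[b]
        cols.append(((lo == min(ca, cb)) & (hi == max(ca, cb))).astype(float))
    return np.column_stack(cols)


def design_matrix(
    nodes: NodeTable,
    spec: ModelSpec,
    edge_covariates: Mapping[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], dict[int, slice]]:
    """Covariate matrix over dyads i < j, without a response.

    Returns ``(pair_i, pair_j, X, columns, term_slices)``; ``term_slices``
    maps the index of each term in ``spec.terms`` to its column block.
    """
    n = nodes.n
    iu, ju = np.triu_indices(n, 1)
    blocks: list[np.ndarray] = []
    names: list[str] = []
    slices: dict[int, slice] = {}
    for t_idx, term in enumerate(spec.terms):
        block = _term_columns(term, nodes, iu, ju, edge_covariates)
        slices[t_idx] = slice(len(names), len(names) + block.shape[1])
        names.extend(term.column_names(nodes))
        blocks.append(block)
    X = np.hstack(blocks) if blocks else np.empty((len(iu), 0))
    return iu, ju, X, names, slices


def build_design(
    net: KinNetwork,
    spec: ModelSpec,
    edge_covariates: Mapping[str, np.ndarray] | None = None,
    drop_incomplete: bool = False,
) -> DyadDesign:
    """Assemble the dyad response and design matrix for ``spec`` on ``net``.

    ``drop_incomplete=True`` removes every dyad touching a node with a
    missing value on any attribute the model uses (the default is a hard
    error, since silent dropping changes the observed density).
    """
    nodes = net.nodes
    if drop_incomplete:
        keep_mask = np.ones(nodes.n, dtype=bool)
        for attr in spec.attributes():
            keep_mask &= nodes.codes(attr) >= 0
        if not keep_mask.all():
            kept = [nodes.ids[k] for k in np.flatnonzero(keep_mask)]
            sub_nodes = NodeTable(
                kept,
                {a: [v for v, m in zip(vals, keep_mask) if m]
                 for a, vals in nodes.attributes.items()},
            )
            for a, lv in nodes.levels.items():
                sub_nodes.levels[a] = list(lv)
            keep_set = set(kept)
            sub_edges = [
                (u, v) for u, v in net.graph.edges() if u in keep_set and v in keep_set
            ]
            weights = {
                (u, v): d["weight"]
                for u, v, d in net.graph.edges(data=True)
                if "weight" in d and u in keep_set and v in keep_set
            }
            net = KinNetwork.from_edges(sub_nodes, sub_edges, weights)
            nodes = sub_nodes
    iu, ju, X, names, slices = design_matrix(nodes, spec, edge_covariates)
    return DyadDesign(
        nodes=nodes, spec=spec, pair_i=iu, pair_j=ju,
        y=net.y_vector(), X=X, columns=names, term_slices=slices,
    )
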