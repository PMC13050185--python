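"""Simulation of attributes and networks from dyad-independent ERGMs.

Everything here is driven by the same model objects used for fitting: given
a node table and a :class:`~kinergm.dyadmodel.ModelSpec` with coefficient
vector theta, each dyad (i, j) is an independent Bernoulli draw with
p_ij = logistic(x_ij' theta).  The module also provides the exact expected
edge count (grouped by dyad covariate pattern, so it scales to large n),
its inversion to a node count for experiment sizing, and a reproducible
synthetic cohort shaped like a multi-site early-medieval cemetery study.

Randomness: every experiment takes one integer seed; replicate r of
experiment component c draws from ``numpy.random.SeedSequence(seed,
spawn_key=(c, r))``, so any replicate is reproducible in isolation.
"""

from __future__ import annotations

from itertools import combinations_with_replacement
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .dyadmodel import (
    ModelSpec,
    TermSpec,
    design_matrix,
    edges,
    nodematch,
    nodematch_diff,
    nodemix,
)
from .fit import theta_for_fold
from .netbuild import IBDPairRecord, KinNetwork, NodeTable

__all__ = [
    "generate_attributes",
    "simulate_network",
    "expected_edges",
    "nodes_for_expected_edges",
    "make_avar_fixture",
    "simulate_pair_table",
]

AttributeSpecs = Mapping[str, tuple[Sequence[str], Sequence[float]]]


def rng_for(seed: int, *key: int) -> np.random.Generator:
    """Generator for one replicate of one experiment component."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def generate_attributes(n: int, attribute_specs: AttributeSpecs,
                        seed: int = 0) -> NodeTable:
    """Allocate categorical attributes to ``n`` nodes by deterministic quotas.

    Each level receives floor(n * proportion) nodes; the remaining nodes (at
    most one per level) are assigned by a seeded draw weighted by the
    fractional parts.  Exact proportions therefore yield exact counts
    regardless of seed (e.g. 300 nodes at 50/50 -> 150/150).  Level
    assignments are shuffled independently per attribute so distinct
    attributes are uncorrelated by construction.
    """
    ids = [f"I{k:04d}" for k in range(n)]
    attrs: dict[str, list[str]] = {}
    declared: dict[str, list[str]] = {}
    for a_idx, (name, (levels, props)) in enumerate(attribute_specs.items()):
        levels = [str(l) for l in levels]
        props = np.asarray(props, dtype=float)
        if len(levels) != len(props):
            raise ValueError(f"attribute {name!r}: {len(levels)} levels, "
                             f"{len(props)} proportions")
        if not np.isclose(props.sum(), 1.0):
            raise ValueError(f"attribute {name!r}: proportions sum to {props.sum()}")
        nonzero = int((props > 0).sum())
        if n < nonzero:
            raise ValueError(
                f"attribute {name!r}: n={n} below the {nonzero} levels with "
                "nonzero proportion"
            )
        quota = np.floor(n * props).astype(int)
        remainder = n - quota.sum()
        rng = rng_for(seed, a_idx, 0)
        frac = n * props - quota
        if remainder > 0:
            if frac.sum() > 0:
                p = frac / frac.sum()
            else:
                p = props
            extra = rng.choice(len(levels), size=remainder, replace=False, p=p)
            for e in extra:
                quota[e] += 1
        values = np.repeat(np.arange(len(levels)), quota)
        rng.shuffle(values)
        attrs[name] = [levels[v] for v in values]
        declared[name] = levels
    return NodeTable(ids, attrs, levels=declared)


def simulate_network(
    nodes: NodeTable,
    spec: ModelSpec,
    theta: Sequence[float],
    seed: int = 0,
    edge_covariates: Mapping[str, np.ndarray] | None = None,
) -> KinNetwork:
    """Draw one network: independent Bernoulli dyads with logistic link."""
    iu, ju, X, _, _ = design_matrix(nodes, spec, edge_covariates)
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (X.shape[1],):
        raise ValueError(
            f"theta has {theta.shape} entries; spec needs {X.shape[1]}"
        )
    rng = rng_for(seed, 0, 0)
    y = draw_dyads(X, theta, rng)
    g_edges = [
        (nodes.ids[int(iu[d])], nodes.ids[int(ju[d])]) for d in np.flatnonzero(y)
    ]
    return KinNetwork.from_edges(nodes, g_edges)


def draw_dyads(X: np.ndarray, theta: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    """One 0/1 dyad response vector for design ``X`` under ``theta``."""
    p = expit(X @ theta)
    return (rng.random(X.shape[0]) < p).astype(np.uint8)


# ---------------------------------------------------------------------------
# Expected edge counts and experiment sizing
# ---------------------------------------------------------------------------

def _pair_covariates(spec: ModelSpec, nodes: NodeTable,
                     tup_a: tuple[str, ...], tup_b: tuple[str, ...],
                     attr_order: list[str]) -> np.ndarray:
    """Covariate row for a dyad whose endpoints have attribute tuples a, b."""
    va = dict(zip(attr_order, tup_a))
    vb = dict(zip(attr_order, tup_b))
    row: list[float] = []
    for term in spec.terms:
        if term.kind == "edges":
            row.append(1.0)
        elif term.kind == "edgecov":
            raise ValueError("expected_edges does not support edgecov terms")
        elif term.kind == "nodematch":
            row.append(float(va[term.attribute] == vb[term.attribute]))
        elif term.kind == "nodematch_diff":
            for lvl in nodes.levels[term.attribute]:
                row.append(float(va[term.attribute] == vb[term.attribute] == lvl))
        else:  # nodemix
            cell = tuple(sorted((va[term.attribute], vb[term.attribute])))
            for c in term.mix_cells(nodes.levels[term.attribute]):
                row.append(float(cell == c))
    return np.asarray(row)


def expected_edges(nodes: NodeTable, spec: ModelSpec,
                   theta: Sequence[float]) -> float:
    """Exact expected number of edges, sum over dyads of p_ij.

    Computed by grouping nodes into joint attribute classes and summing
    class-pair counts times class-pair probabilities, so the cost depends on
    the number of attribute patterns, not on n^2.
    """
    theta = np.asarray(theta, dtype=float)
    if nodes.n < 2:
        return 0.0
    attr_order = spec.attributes()
    if not attr_order:
        p = float(expit(theta[0]))
        return nodes.n * (nodes.n - 1) / 2.0 * p
    tuples = list(zip(*(nodes.attributes[a] for a in attr_order)))
    if any(any(v is None for v in t) for t in tuples):
        raise ValueError("expected_edges: missing attribute values")
    counts: dict[tuple[str, ...], int] = {}
    for t in tuples:
        counts[t] = counts.get(t, 0) + 1
    classes = sorted(counts)
    total = 0.0
    for a_idx, tup_a in enumerate(classes):
        for tup_b in classes[a_idx:]:
            if tup_a == tup_b:
                m = counts[tup_a] * (counts[tup_a] - 1) / 2.0
            else:
                m = counts[tup_a] * counts[tup_b]
            if m == 0:
                continue
            x = _pair_covariates(spec, nodes, tup_a, tup_b, attr_order)
            if x.shape != theta.shape:
                raise ValueError(
                    f"theta has {theta.shape} entries; spec needs {x.shape}"
                )
            total += m * float(expit(x @ theta))
    return total


def nodes_for_expected_edges(
    target_edges: float,
    spec: ModelSpec,
    theta: Sequence[float],
    attribute_specs: AttributeSpecs | None = None,
    n_max: int = 1_000_000,
) -> int:
    """Smallest node count n whose expected edge count reaches ``target_edges``.

    Attribute proportions (not realised tables) define the design at each
    candidate n; attributes are allocated by the same deterministic quotas
    as :func:`generate_attributes`.
    """
    if target_edges < 1:
        raise ValueError("target_edges must be >= 1")
    attribute_specs = attribute_specs or {}

    def f(n: int) -> float:
        nt = generate_attributes(n, attribute_specs, seed=0)
        return expected_edges(nt, spec, theta)

    lo, hi = 1, 2
    while f(hi) < target_edges:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise ValueError(
                f"target of {target_edges} expected edges unreachable below "
                f"n={n_max} (connection probabilities too small)"
            )
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if f(mid) >= target_edges:
            hi = mid
        else:
            lo = mid
    return hi


# ---------------------------------------------------------------------------
# Synthetic multi-site cohort fixture
# ---------------------------------------------------------------------------

# Baseline log-odds for the synthetic cohort.  Must be strongly negative so
# that probability folds of several hundred (differential site homophily)
# remain valid probabilities: the fold is capped at 1/logistic(theta0).
AVAR_THETA0 = -9.0


def make_avar_fixture(seed: int = 0):
    """A reproducible 237-individual, 4-site synthetic cohort plus one draw.

    Returns ``(nodes, spec, theta, net)`` where ``theta`` is the generating
    coefficient vector, so that estimator recovery can be asserted against
    the truth.  Attributes: site (HNJ/KFJ/KUP/RK), period (Early vs
    Middle/Late), sex, age class, burial orientation, a rare-valuable item
    flag (harness) and a common item flag (buckle).  The buckle flag is
    generated but not part of the model — a deliberately null variable.
    """
    n = 237
    specs: AttributeSpecs = {
        "site": (["HNJ", "KFJ", "KUP", "RK"], [0.17, 0.13, 0.11, 0.59]),
        "period": (["Early", "Middle/Late"], [0.4, 0.6]),
        "sex": (["F", "M"], [0.45, 0.55]),
        "age": (["Adult", "Subadult"], [0.78, 0.22]),
        "orientation": (["NW-SE", "W-E", "N-S"], [0.5, 0.35, 0.15]),
        "harness": (["none", "with"], [0.8, 0.2]),
        "buckle": (["none", "with"], [0.65, 0.35]),
    }
    nodes = generate_attributes(n, specs, seed=seed)
    sex_age = [
        f"{a}{s}" for a, s in zip(nodes.attributes["age"], nodes.attributes["sex"])
    ]
    nodes = NodeTable(
        nodes.ids,
        {**nodes.attributes, "sex_age": sex_age},
        levels={**nodes.levels,
                "sex_age": ["AdultF", "AdultM", "SubadultF", "SubadultM"]},
    )
    spec = ModelSpec(
        [
            edges(),
            nodematch_diff("site"),
            nodematch_diff("period"),
            nodemix("sex_age", base_cell=("AdultF", "AdultM")),
            nodematch("orientation"),
            nodemix("harness", base_cell=("none", "none")),
        ],
        label="avar_fixture",
    )
    folds = {
        "nodematch_diff.site.HNJ": 549.0,
        "nodematch_diff.site.KFJ": 857.0,
        "nodematch_diff.site.KUP": 691.0,
        "nodematch_diff.site.RK": 185.0,
        "nodematch_diff.period.Early": 5.16,
        "nodematch_diff.period.Middle/Late": 9.17,
        "nodemix.sex_age.AdultF.AdultF": 0.26,
        "nodemix.sex_age.AdultF.SubadultF": 0.89,
        "nodemix.sex_age.AdultF.SubadultM": 1.18,
        "nodemix.sex_age.AdultM.AdultM": 6.62,
        "nodemix.sex_age.AdultM.SubadultF": 7.29,
        "nodemix.sex_age.AdultM.SubadultM": 7.12,
        "nodemix.sex_age.SubadultF.SubadultF": 4.40,
        "nodemix.sex_age.SubadultF.SubadultM": 9.14,
        "nodemix.sex_age.SubadultM.SubadultM": 12.8,
        "nodematch.orientation": 2.86,
        "nodemix.harness.none.with": 0.64,
        "nodemix.harness.with.with": 2.56,
    }
    columns = spec.column_names(nodes)
    theta = np.empty(len(columns))
    theta[0] = AVAR_THETA0
    for j, col in enumerate(columns[1:], start=1):
        theta[j] = theta_for_fold(AVAR_THETA0, folds[col])
    net = simulate_network(nodes, spec, theta, seed=seed)
    return nodes, spec, theta, net


def simulate_pair_table(
    nodes: NodeTable,
    spec: ModelSpec,
    theta: Sequence[float],
    seed: int = 0,
    base_cutoff: float = 12.0,
    background_rate: float = 0.01,
) -> list[IBDPairRecord]:
    """Pairwise total-cM records whose thresholding reproduces a model draw.

    Dyads that are "related" under the model receive a total shared cM of
    ``base_cutoff * (0.6 + Exponential(1))`` — mostly above the cutoff but
    with a tail crossing it, so nearby cutoffs prune edges smoothly.
    A small fraction of unrelated dyads receive background sharing below
    0.7 * base_cutoff.  Only nonzero records are returned.
    """
    iu, ju, X, _, _ = design_matrix(nodes, spec)
    theta = np.asarray(theta, dtype=float)
    rng = rng_for(seed, 1, 0)
    related = draw_dyads(X, theta, rng).astype(bool)
    m = len(iu)
    cm = np.zeros(m)
    cm[related] = base_cutoff * (0.6 + rng.exponential(1.0, size=int(related.sum())))
    background = (~related) & (rng.random(m) < background_rate)
    cm[background] = base_cutoff * rng.uniform(0.0, 0.7, size=int(background.sum()))
    out = []
    for d in np.flatnonzero(cm > 0):
        out.append(
            IBDPairRecord(nodes.ids[int(iu[d])], nodes.ids[int(ju[d])],
                          total_cm=float(cm[d]))
        )
    return out
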