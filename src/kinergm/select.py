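"""Candidate-model enumeration, information-criterion selection, and the
confusion-matrix and cutoff-sensitivity experiments.

Selection compares every candidate on the same dyad set; the chosen model
minimises the requested criterion (BIC by default), with ties broken toward
the smaller parameter count, then candidate order.  A p-value strategy
(backward elimination from the largest candidate) is provided as the
baseline that information-criterion selection is meant to beat.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dyadmodel import (
    DyadDesign,
    ModelSpec,
    build_design,
    design_matrix,
    edges,
    nodematch,
    nodematch_diff,
    nodemix,
)
from scipy.special import expit

from .fit import FitResult, fit_grouped, fit_model, group_design
from .netbuild import IBDPairRecord, KinNetwork, NodeTable, ThresholdRule, threshold_network
from .simulate import AttributeSpecs, generate_attributes, rng_for

__all__ = [
    "SelectionResult",
    "ConfusionMatrix",
    "select_model",
    "confusion_experiment",
    "cutoff_sensitivity",
    "SensitivityResult",
    "default_family",
    "DEFAULT_ATTRIBUTE_SPECS",
]

CRITERIA = ("bic", "aic", "aicc", "pvalue")


@dataclass
class SelectionResult:
    """Comparison table over candidates plus the chosen model per criterion."""

    table: pd.DataFrame                      # label, k, loglik, bic, aic, aicc, failed
    fits: dict[str, FitResult]
    chosen: dict[str, str]                   # criterion -> label
    criterion: str

    @property
    def chosen_label(self) -> str:
        return self.chosen[self.criterion]

    @property
    def chosen_fit(self) -> FitResult:
        return self.fits[self.chosen_label]

    def significant_attributes(self, alpha: float = 0.05) -> frozenset[str]:
        """Attributes with at least one significant coefficient in the chosen model."""
        fit = self.chosen_fit
        out = set()
        for col, p in zip(fit.columns, fit.pvalues):
            if col == "edges" or not math.isfinite(p) or p > alpha:
                continue
            parts = col.split(".")
            out.add(parts[1] if len(parts) > 1 else col)
        return frozenset(out)


def _argmin_with_ties(table: pd.DataFrame, column: str, tol: float = 1e-9) -> str:
    ok = table[~table["failed"]]
    vals = ok[column].to_numpy(dtype=float)
    best = np.nanmin(vals)
    tied = ok[np.abs(vals - best) <= tol]
    tied = tied.sort_values(["k", "order"], kind="stable")
    return str(tied.iloc[0]["label"])


def _select_from_designs(
    designs: Sequence[DyadDesign | None],
    labels: Sequence[str],
    criterion: str = "bic",
) -> SelectionResult:
    criterion = criterion.lower()
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}")
    rows = []
    fits: dict[str, FitResult] = {}
    for order, (label, design) in enumerate(zip(labels, designs)):
        if design is None:
            rows.append(dict(label=label, order=order, k=0, loglik=np.nan,
                             bic=np.nan, aic=np.nan, aicc=np.nan, failed=True))
            continue
        try:
            res = fit_model(design)
            fits[label] = res
            rows.append(dict(label=label, order=order, k=res.k, loglik=res.loglik,
                             bic=res.bic, aic=res.aic, aicc=res.aicc, failed=False))
        except (KeyError, ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"candidate {label!r} failed to fit: {exc}")
            rows.append(dict(label=label, order=order, k=design.k, loglik=np.nan,
                             bic=np.nan, aic=np.nan, aicc=np.nan, failed=True))
    table = pd.DataFrame(rows)
    if table["failed"].all():
        raise ValueError("every candidate failed to fit")
    chosen = {c: _argmin_with_ties(table, c) for c in ("bic", "aic", "aicc")}
    if criterion == "pvalue":
        chosen["pvalue"] = _backward_eliminate(designs, fits, table)
    return SelectionResult(table=table.drop(columns="order"), fits=fits,
                           chosen=chosen, criterion=criterion)


def _backward_eliminate(
    designs: Sequence[DyadDesign],
    fits: dict[str, FitResult],
    table: pd.DataFrame,
    alpha: float = 0.05,
) -> str:
    """Backward elimination from the largest fittable candidate.

    Repeatedly drops the non-intercept term whose coefficient block is least
    significant (block p = smallest coefficient p within the block) while
    that block p exceeds ``alpha``.  Returns the label of the surviving
    model; intermediate models are fitted on the same dyads and added to the
    fit table.
    """
    ok = table[~table["failed"]].sort_values(["k", "order"], kind="stable")
    start = designs[int(ok.iloc[-1]["order"])]
    design = start
    while True:
        res = fits.get(design.spec.label) or fit_model(design)
        fits[design.spec.label] = res
        block_p = {}
        for t_idx, sl in design.term_slices.items():
            if design.spec.terms[t_idx].kind == "edges":
                continue
            pvals = res.pvalues[sl]
            finite = pvals[np.isfinite(pvals)]
            block_p[t_idx] = float(finite.min()) if finite.size else 1.0
        if not block_p:
            return design.spec.label
        worst = max(block_p, key=lambda t: block_p[t])
        if block_p[worst] <= alpha:
            return design.spec.label
        remaining = [t for k, t in enumerate(design.spec.terms) if k != worst]
        sub_spec = ModelSpec(remaining)
        iu, ju, X, cols, slices = design_matrix(design.nodes, sub_spec)
        design = DyadDesign(design.nodes, sub_spec, iu, ju, design.y, X, cols, slices)


def select_model(
    net: KinNetwork,
    candidates: Sequence[ModelSpec],
    criterion: str = "bic",
) -> SelectionResult:
    """Fit every candidate on the same dyad set and choose by ``criterion``.

    A candidate whose design cannot be built or fitted is recorded as
    failed, excluded from the argmin, and reported with a warning.
    """
    if not candidates:
        raise ValueError("need at least one candidate model")
    designs: list[DyadDesign | None] = []
    for spec in candidates:
        try:
            designs.append(build_design(net, spec))
        except (KeyError, ValueError) as exc:
            warnings.warn(f"candidate {spec.label!r} failed to fit: {exc}")
            designs.append(None)
    return _select_from_designs(designs, [s.label for s in candidates], criterion)


# ---------------------------------------------------------------------------
# Confusion experiment
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """True-model x selected-model tally from a simulation experiment."""

    counts: pd.DataFrame      # index: true label, columns: selected labels (+failed)
    reps: int

    def __post_init__(self) -> None:
        sums = self.counts.sum(axis=1)
        if not (sums == self.reps).all():
            raise ValueError("confusion rows must each sum to the replicate count")

    @property
    def accuracy(self) -> float:
        labels = [l for l in self.counts.index if l in self.counts.columns]
        diag = sum(self.counts.loc[l, l] for l in labels)
        return float(diag) / float(self.counts.to_numpy().sum())

    def specificity(self) -> pd.Series:
        """Per model: fraction of replicates from OTHER truths not assigned to it."""
        total = self.counts.to_numpy().sum()
        out = {}
        for label in self.counts.index:
            col = self.counts[label].sum() if label in self.counts.columns else 0
            tp = self.counts.loc[label, label] if label in self.counts.columns else 0
            fp = col - tp
            negatives = total - self.counts.loc[label].sum()
            out[label] = 1.0 - fp / negatives if negatives else 1.0
        return pd.Series(out, name="specificity")


DEFAULT_ATTRIBUTE_SPECS: AttributeSpecs = {
    "sex": (["1", "2"], [0.5, 0.5]),
    "site": (["A", "B", "C"], [1 / 3, 1 / 3, 1 / 3]),
}

# Heterogeneous truth coefficients for the multi-parameter models keep each
# truth identifiable: equal within-level effects would collapse differential
# homophily onto simple homophily (and mixing onto differential homophily),
# making a diagonal confusion matrix impossible in principle.
_DIFF_SITE = (0.4, 0.8, 1.2)
_MIX_SITE = (0.8, 0.0, 1.0, 0.3, 1.4)   # cells (A,B),(A,C),(B,B),(B,C),(C,C)


def default_family(theta0: float = -4.0,
                   match_effect: float = 0.75) -> list[tuple[ModelSpec, np.ndarray]]:
    """The default 7-model family over a binary "sex" and 3-level "site".

    M1 intercept only; M2 +sexmatch; M3 +sitematch; M4 +differential
    sitematch; M5 +sitemix; M6 sexmatch+differential sitematch;
    M7 sexmatch+sitemix.  Paired with generating coefficient vectors.
    """
    e = match_effect
    fam: list[tuple[ModelSpec, np.ndarray]] = [
        (ModelSpec([edges()], "M1_edges"), np.array([theta0])),
        (ModelSpec([edges(), nodematch("sex")], "M2_sexmatch"),
         np.array([theta0, e])),
        (ModelSpec([edges(), nodematch("site")], "M3_sitematch"),
         np.array([theta0, e])),
        (ModelSpec([edges(), nodematch_diff("site")], "M4_sitediff"),
         np.array([theta0, *_DIFF_SITE])),
        (ModelSpec([edges(), nodemix("site")], "M5_sitemix"),
         np.array([theta0, *_MIX_SITE])),
        (ModelSpec([edges(), nodematch("sex"), nodematch_diff("site")],
                   "M6_sexmatch_sitediff"),
         np.array([theta0, e, *_DIFF_SITE])),
        (ModelSpec([edges(), nodematch("sex"), nodemix("site")],
                   "M7_sexmatch_sitemix"),
         np.array([theta0, e, *_MIX_SITE])),
    ]
    return fam


def confusion_experiment(
    model_family: Sequence[tuple[ModelSpec, Sequence[float]]] | None = None,
    n_nodes: int = 300,
    reps: int = 100,
    seed: int = 0,
    criterion: str = "bic",
    attribute_specs: AttributeSpecs | None = None,
) -> ConfusionMatrix:
    """Simulate ``reps`` networks per true model and tally the selected model.

    All truths share one attribute table (deterministic quotas), and every
    candidate design is built once and reused, so the experiment cost is
    ``reps * len(family)`` simulate+select cycles.  Replicate r of truth t
    uses the generator spawned at ``(t, r)`` from ``seed``.
    """
    if model_family is None:
        model_family = default_family()
    if not model_family:
        raise ValueError("model family must be non-empty")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if criterion.lower() not in ("bic", "aic", "aicc"):
        raise ValueError("confusion_experiment supports information criteria only")
    attribute_specs = attribute_specs or DEFAULT_ATTRIBUTE_SPECS
    nodes = generate_attributes(n_nodes, attribute_specs, seed=seed)
    labels = [spec.label for spec, _ in model_family]

    # Stack every candidate's columns, group dyads once into joint covariate
    # patterns, and simulate binomial successes per pattern: distributionally
    # identical to per-dyad draws, and every candidate's sufficient statistics
    # follow by aggregation, so each replicate costs O(#patterns).
    candidates = []
    for spec, _ in model_family:
        _, _, X, cols, _ = design_matrix(nodes, spec)
        candidates.append((spec, X, cols))
    X_all = np.hstack([X for _, X, _ in candidates])
    Xp_all, _, trials = group_design(X_all)
    offset = 0
    cand_grouped = []
    for spec, X, cols in candidates:
        k = X.shape[1]
        block = Xp_all[:, offset:offset + k]
        # collapse further to the candidate's own patterns
        Xp_c, inv_c, _ = np.unique(block, axis=0, return_inverse=True,
                                   return_counts=True)
        trials_c = np.bincount(inv_c, weights=trials)
        cand_grouped.append((spec, cols, block, Xp_c, inv_c, trials_c))
        offset += k
    n_dyads = int(trials.sum())

    counts = pd.DataFrame(0, index=labels, columns=labels + ["failed"], dtype=int)
    crit = criterion.lower()
    for t_idx, (true_spec, theta) in enumerate(model_family):
        theta = np.asarray(theta, dtype=float)
        spec_t, cols_t, block_t, _, _, _ = cand_grouped[labels.index(true_spec.label)]
        if theta.shape != (block_t.shape[1],):
            raise ValueError(
                f"{true_spec.label}: theta has {theta.shape} entries, "
                f"needs {block_t.shape[1]}"
            )
        p_true = expit(block_t @ theta)
        int_trials = trials.astype(int)
        for r in range(reps):
            rng = rng_for(seed, t_idx, r)
            s_all = rng.binomial(int_trials, p_true).astype(float)
            rows = []
            fitted = {}
            for order, (spec, cols, _, Xp_c, inv_c, trials_c) in enumerate(cand_grouped):
                s_c = np.bincount(inv_c, weights=s_all)
                try:
                    res = fit_grouped(Xp_c, s_c, trials_c, cols, label=spec.label)
                    fitted[spec.label] = res
                    rows.append(dict(label=spec.label, order=order, k=res.k,
                                     bic=res.bic, aic=res.aic, aicc=res.aicc,
                                     failed=False))
                except (ValueError, np.linalg.LinAlgError):
                    rows.append(dict(label=spec.label, order=order,
                                     k=len(cols), bic=np.nan, aic=np.nan,
                                     aicc=np.nan, failed=True))
            table = pd.DataFrame(rows)
            if table["failed"].all():
                counts.loc[true_spec.label, "failed"] += 1
                continue
            counts.loc[true_spec.label, _argmin_with_ties(table, crit)] += 1
    return ConfusionMatrix(counts=counts, reps=reps)


# ---------------------------------------------------------------------------
# Cutoff sensitivity
# ---------------------------------------------------------------------------

@dataclass
class SensitivityResult:
    """Selection under each threshold rule plus significant-variable stability."""

    selections: dict[int, SelectionResult | None] = field(default_factory=dict)
    degenerate: list[int] = field(default_factory=list)
    significant_sets: dict[int, frozenset[str]] = field(default_factory=dict)
    intersection: frozenset[str] = frozenset()
    union: frozenset[str] = frozenset()

    @property
    def stable(self) -> bool:
        """True when every non-degenerate rule yields the same significant set."""
        sets = list(self.significant_sets.values())
        return bool(sets) and all(s == sets[0] for s in sets)


def cutoff_sensitivity(
    pairs: Iterable[IBDPairRecord],
    nodes: NodeTable,
    rules: Sequence[ThresholdRule],
    candidates: Sequence[ModelSpec],
    criterion: str = "bic",
    alpha: float = 0.05,
) -> SensitivityResult:
    """Re-threshold, re-select, and compare significant variables across rules.

    A rule producing an empty edge set is flagged degenerate and excluded
    from the stability summary.
    """
    if len(rules) < 2:
        raise ValueError("need at least two threshold rules")
    pairs = list(pairs)
    out = SensitivityResult()
    for r_idx, rule in enumerate(rules):
        net = threshold_network(pairs, nodes, rule)
        if net.n_edges == 0:
            out.degenerate.append(r_idx)
            out.selections[r_idx] = None
            continue
        sel = select_model(net, candidates, criterion)
        out.selections[r_idx] = sel
        out.significant_sets[r_idx] = sel.significant_attributes(alpha)
    sets = list(out.significant_sets.values())
    if sets:
        inter, uni = sets[0], sets[0]
        for s in sets[1:]:
            inter = inter & s
            uni = uni | s
        out.intersection, out.union = inter, uni
    return out
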