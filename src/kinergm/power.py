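"""Empirical power of the dyad-regression Wald test, and minimum detectable
effects as a function of expected network size.

The canonical experiment: nodes carry one binary attribute (two groups with
given proportions); networks are simulated from the match model
log-odds = theta0 + theta1 * I(match); each replicate is refitted with the
same model and the match coefficient's two-sided Wald p-value is compared
to alpha.  Power is the rejection fraction.  Degenerate replicates (empty
or complete graphs) are counted as non-rejections and reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from scipy.special import expit

from .dyadmodel import ModelSpec, design_matrix, edges, nodematch
from .fit import fit_grouped, fold_change, group_design
from .simulate import (
    AttributeSpecs,
    generate_attributes,
    nodes_for_expected_edges,
    rng_for,
)

__all__ = ["PowerCurve", "MDEResult", "empirical_power", "min_detectable_effect"]

MATCH_ATTR = "group"


def _match_specs(proportions: Sequence[float]) -> AttributeSpecs:
    levels = [str(k + 1) for k in range(len(proportions))]
    return {MATCH_ATTR: (levels, list(proportions))}


def _match_model() -> ModelSpec:
    return ModelSpec([edges(), nodematch(MATCH_ATTR)], "match")


def _power_at(
    Xp: np.ndarray,
    trials: np.ndarray,
    columns: list[str],
    theta: np.ndarray,
    reps: int,
    alpha: float,
    seed: int,
    component: int,
) -> tuple[float, int]:
    """Rejection fraction for the match coefficient, and degenerate count.

    Because dyads are independent given their covariate pattern, each
    replicate network is drawn as one binomial count per pattern (the
    sufficient statistics of the fit), which is distributionally identical
    to drawing every dyad and much cheaper.
    """
    rejections = 0
    degenerate = 0
    p_pattern = expit(Xp @ theta)
    int_trials = trials.astype(int)
    m = int(trials.sum())
    j = columns.index(f"nodematch.{MATCH_ATTR}")
    for r in range(reps):
        rng = rng_for(seed, component, r)
        s = rng.binomial(int_trials, p_pattern).astype(float)
        total = s.sum()
        if total == 0 or total == m:
            degenerate += 1
            continue
        res = fit_grouped(Xp, s, trials, columns, label="match")
        p = res.pvalues[j]
        if np.isfinite(p) and p <= alpha:
            rejections += 1
    return rejections / reps, degenerate


@dataclass
class PowerCurve:
    """Empirical power over a grid of match coefficients."""

    theta_grid: np.ndarray
    power: np.ndarray
    fold: np.ndarray
    reps: int
    alpha: float
    n: int
    proportions: tuple[float, ...]
    theta0: float
    degenerate: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.theta_grid) <= 0):
            raise ValueError("theta grid must be strictly increasing")
        if np.any((self.power < 0) | (self.power > 1)):
            raise ValueError("power must lie in [0, 1]")


def empirical_power(
    theta1_grid: Sequence[float],
    n: int = 300,
    proportions: Sequence[float] = (0.5, 0.5),
    theta0: float = -4.0,
    reps: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> PowerCurve:
    """Empirical power of the match-coefficient Wald test over ``theta1_grid``."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    grid = np.asarray(sorted(theta1_grid), dtype=float)
    nodes = generate_attributes(n, _match_specs(proportions), seed=seed)
    spec = _match_model()
    _, _, X, columns, _ = design_matrix(nodes, spec)
    Xp, _, trials = group_design(X)
    power = np.empty(len(grid))
    degen = np.empty(len(grid), dtype=int)
    for g, theta1 in enumerate(grid):
        power[g], degen[g] = _power_at(
            Xp, trials, columns, np.array([theta0, theta1]), reps, alpha, seed, g
        )
    fold = np.array([fold_change(theta0, t) for t in grid])
    return PowerCurve(
        theta_grid=grid, power=power, fold=fold, reps=reps, alpha=alpha,
        n=n, proportions=tuple(proportions), theta0=theta0, degenerate=degen,
    )


@dataclass
class MDEResult:
    """Minimum detectable match coefficient per expected-edge count."""

    edge_grid: np.ndarray
    n_nodes: np.ndarray
    min_theta: np.ndarray       # NaN where the target power was unattainable
    min_fold: np.ndarray
    found: np.ndarray
    target_power: float
    reps: int

    def __post_init__(self) -> None:
        ok = self.found & np.isfinite(self.min_fold)
        if np.any(self.min_fold[ok] < 1.0):
            raise ValueError("minimal fold must be >= 1")


def min_detectable_effect(
    edge_grid: Sequence[float],
    target_power: float = 0.8,
    theta0: float = -4.0,
    proportions: Sequence[float] = (0.5, 0.5),
    reps: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    resolution: float = 0.01,
    theta_max: float = 3.0,
) -> MDEResult:
    """Smallest match coefficient reaching ``target_power``, per network size.

    For each expected edge count the node count is chosen by inverting the
    intercept-only expectation (theta1 = 0); the minimal coefficient is then
    located by bisection on a grid of step ``resolution`` over (0,
    ``theta_max``], with ``reps`` simulated networks per evaluation.  If even
    ``theta_max`` misses the target the point is recorded as not found.
    """
    if not (0.0 < target_power < 1.0):
        raise ValueError("target_power must lie in (0, 1)")
    edge_grid = np.asarray(edge_grid, dtype=float)
    spec = _match_model()
    attr_specs = _match_specs(proportions)
    null_spec = ModelSpec([edges()], "null")
    n_nodes = np.empty(len(edge_grid), dtype=int)
    min_theta = np.full(len(edge_grid), np.nan)
    found = np.zeros(len(edge_grid), dtype=bool)
    for e_idx, target_edges in enumerate(edge_grid):
        n = nodes_for_expected_edges(target_edges, null_spec, [theta0])
        n_nodes[e_idx] = n
        nodes = generate_attributes(n, attr_specs, seed=seed)
        _, _, X, columns, _ = design_matrix(nodes, spec)
        Xp, _, trials = group_design(X)
        theta_steps = int(round(theta_max / resolution))

        cache: dict[int, float] = {}

        def power_at_step(step: int) -> float:
            if step not in cache:
                theta1 = step * resolution
                cache[step], _ = _power_at(
                    Xp, trials, columns, np.array([theta0, theta1]),
                    reps, alpha, seed, e_idx * (theta_steps + 1) + step,
                )
            return cache[step]

        if power_at_step(theta_steps) < target_power:
            continue
        lo, hi = 0, theta_steps   # invariant: power(hi) >= target, power(lo) unknown/low
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if power_at_step(mid) >= target_power:
                hi = mid
            else:
                lo = mid
        min_theta[e_idx] = hi * resolution
        found[e_idx] = True
    min_fold = np.array([
        fold_change(theta0, t) if np.isfinite(t) else np.nan for t in min_theta
    ])
    return MDEResult(
        edge_grid=edge_grid, n_nodes=n_nodes, min_theta=min_theta,
        min_fold=min_fold, found=found, target_power=target_power, reps=reps,
    )
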