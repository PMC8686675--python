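"""Feature rescaling, aggregate scoring, edge filtering and the weight grid.

The five evidence scores live on very different scales, so each is linearly
rescaled to map its empirical 1st and 99th quantiles onto [0, 1] (no
clamping).  The aggregate score is a weighted sum with unit weight on the
calibrated XCorr:

    w = w_T + alpha_P * w_P + alpha_F * w_F + alpha_R * w_R + alpha_E * w_E

Within each (spectrum, charge) group, any edge whose aggregate score is
lower than that of the top-XCorr edge is discarded; the top-XCorr edge
itself therefore always survives.  The four non-negative weights can be
selected by exhaustive or coordinate-wise search over the standard grid
{0, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6, 3.2, 6.4, 12.8}, maximizing the number
of peptides accepted at 1% FDR.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .config import SearchConfig, DEFAULT_CONFIG, ALPHA_GRID
from .search_core import BipartiteGraph, Edge

#: Aggregate-score feature names in canonical order.
FEATURES = ("tailor", "precursor", "fragment", "rt", "coelution")

_EDGE_ATTR = {
    "tailor": "tailor",
    "precursor": "w_p",
    "fragment": "w_f",
    "rt": "w_r",
    "coelution": "w_e",
}


@dataclass(frozen=True)
class AlphaWeights:
    """Non-negative weights of the four auxiliary features."""

    alpha_p: float = DEFAULT_CONFIG.alpha_p
    alpha_f: float = DEFAULT_CONFIG.alpha_f
    alpha_r: float = DEFAULT_CONFIG.alpha_r
    alpha_e: float = DEFAULT_CONFIG.alpha_e

    def __post_init__(self):
        if min(self.alpha_p, self.alpha_f, self.alpha_r, self.alpha_e) < 0:
            raise ValueError("alpha weights must be non-negative")

    def as_tuple(self) -> Tuple[float, float, float, float]:
        return (self.alpha_p, self.alpha_f, self.alpha_r, self.alpha_e)


@dataclass
class FeatureScaler:
    """Per-feature (q01, q99) quantiles; transform maps them onto [0, 1]."""

    quantiles: Dict[str, Tuple[float, float]]

    def transform(self, feature: str, value: float) -> float:
        q01, q99 = self.quantiles[feature]
        if q99 <= q01:
            return 0.5
        return (value - q01) / (q99 - q01)


def _edge_feature(edge: Edge, feature: str) -> float:
    value = getattr(edge, _EDGE_ATTR[feature])
    if value is None:
        raise ValueError(f"feature {feature!r} unset on edge {edge.scan_id}")
    return value


def fit_scaler(
    edges: Sequence[Edge],
    quantile_pair: Tuple[float, float] = DEFAULT_CONFIG.scaler_quantiles,
) -> FeatureScaler:
    """Empirical (linear-interpolation) quantiles of each feature over all
    edges, targets and decoys alike.  Fewer than two edges yields an
    identity scaler with a warning."""
    if len(edges) < 2:
        warnings.warn("fewer than 2 edges: identity feature scaler")
        return FeatureScaler({f: (0.0, 1.0) for f in FEATURES})
    lo_q, hi_q = quantile_pair
    quantiles = {}
    for feature in FEATURES:
        values = np.array([_edge_feature(e, feature) for e in edges])
        quantiles[feature] = (
            float(np.quantile(values, lo_q)),
            float(np.quantile(values, hi_q)),
        )
    return FeatureScaler(quantiles)


def aggregate_score(
    edge: Edge,
    scaler: FeatureScaler,
    alphas: AlphaWeights,
    feature_mask: Tuple[str, ...] = FEATURES,
) -> float:
    """Weighted sum of rescaled features (unit weight on calibrated XCorr).

    Features outside ``feature_mask`` are dropped, which supports ablation
    runs; masking ``tailor`` removes the unit-weight term as well.
    """
    weights = {
        "tailor": 1.0,
        "precursor": alphas.alpha_p,
        "fragment": alphas.alpha_f,
        "rt": alphas.alpha_r,
        "coelution": alphas.alpha_e,
    }
    total = 0.0
    for feature in FEATURES:
        if feature not in feature_mask:
            continue
        total += weights[feature] * scaler.transform(
            feature, _edge_feature(edge, feature)
        )
    return total


def score_edges(
    graph: BipartiteGraph,
    scaler: FeatureScaler,
    alphas: AlphaWeights,
    feature_mask: Tuple[str, ...] = FEATURES,
) -> BipartiteGraph:
    """Set ``edge.aggregate`` on every retained edge."""
    for edge in graph.edges:
        edge.aggregate = aggregate_score(edge, scaler, alphas, feature_mask)
    return graph


def filter_edges(
    graph: BipartiteGraph,
    scaler: Optional[FeatureScaler] = None,
    alphas: Optional[AlphaWeights] = None,
    feature_mask: Tuple[str, ...] = FEATURES,
) -> BipartiteGraph:
    """Discard edges whose aggregate score falls below that of the
    top-XCorr edge of their (spectrum, charge) group.

    If ``scaler``/``alphas`` are given, aggregate scores are (re)computed
    first.  Groups are never emptied: the reference edge always survives.
    """
    if scaler is not None and alphas is not None:
        score_edges(graph, scaler, alphas, feature_mask)
    new_groups: Dict[Tuple[int, int], List[int]] = {}
    keep_idx = set()
    for key, idx_list in graph.groups.items():
        if not idx_list:
            new_groups[key] = []
            continue
        # retained edges are stored in decreasing XCorr order with the
        # deterministic tie-break applied at construction; the first one is
        # the top-XCorr reference
        ref = graph.edges[idx_list[0]]
        if ref.aggregate is None:
            raise ValueError("aggregate scores not computed before filtering")
        survivors = [
            i for i in idx_list if graph.edges[i].aggregate >= ref.aggregate
        ]
        new_groups[key] = survivors
        keep_idx.update(survivors)

    old_to_new = {}
    new_edges = []
    for i, edge in enumerate(graph.edges):
        if i in keep_idx:
            old_to_new[i] = len(new_edges)
            new_edges.append(edge)
    remapped = {
        key: [old_to_new[i] for i in idx_list]
        for key, idx_list in new_groups.items()
    }
    return BipartiteGraph(new_edges, remapped, graph.candidate_scores, graph.flags)


def grid_search_alphas(
    objective: Callable[[AlphaWeights], float],
    grid: Iterable[float] = ALPHA_GRID,
    strategy: str = "full",
) -> AlphaWeights:
    """Maximize ``objective`` (e.g. accepted peptides at 1% FDR) over the
    weight grid.

    ``strategy='full'`` enumerates all |grid|^4 combinations;
    ``'coordinate'`` cycles coordinate-wise updates until a fixed point.
    Ties break toward the lexicographically smallest weight vector.
    """
    grid = sorted(set(float(g) for g in grid))
    if strategy == "full":
        best, best_val = None, -np.inf
        for combo in itertools.product(grid, repeat=4):
            val = objective(AlphaWeights(*combo))
            if val > best_val or (val == best_val and (best is None or combo < best)):
                best, best_val = combo, val
        return AlphaWeights(*best)
    if strategy == "coordinate":
        current = [grid[0]] * 4
        current_val = objective(AlphaWeights(*current))
        for _ in range(8):  # outer sweeps; converges quickly on a finite grid
            changed = False
            for axis in range(4):
                best_axis, best_val = current[axis], current_val
                for g in grid:
                    trial = current[:]
                    trial[axis] = g
                    val = objective(AlphaWeights(*trial))
                    if val > best_val or (val == best_val and g < best_axis):
                        best_axis, best_val = g, val
                if best_axis != current[axis]:
                    current[axis] = best_axis
                    current_val = best_val
                    changed = True
            if not changed:
                break
        return AlphaWeights(*current)
    raise ValueError(f"unknown strategy {strategy!r}")
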