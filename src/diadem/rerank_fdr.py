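"""Semi-supervised rescoring, precursor-level competition and FDR control.

The rescoring follows the Percolator protocol: edges are split into three
cross-validation folds *atomically by target/decoy pair* (so a decoy can
never train the model that scores its own target), an initial ranking
direction is chosen as the single best feature, and a regularized linear
max-margin classifier is refit iteratively with positives = target edges
currently accepted at q <= 0.01 and negatives = all decoy edges.  Held-out
scores are rank-normalized per fold before merging.

Competition then happens at the precursor level: among all edges of a
target/decoy pair (across charge states), only the top-scoring edge is
retained, and the surviving list is assigned q-values with the standard
decoy-counting estimate

    FDR(tau) = min(1, #decoys above tau / max(1, #targets above tau)).

An entrapment ("pseudo-target") harness doubles the database with disguised
decoys so any detection method's nominal q-values can be audited against an
independent estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.svm import LinearSVC

from .config import SearchConfig, DEFAULT_CONFIG
from .peptide_db import Peptide, Precursor, generate_decoys
from .search_core import Edge

#: Rescoring feature columns, in order.  The three search-context features
#: (charge and the two score-gap features) are always present; the five
#: evidence features follow the active feature mask.
BASE_FEATURES = ("charge", "delta_cn", "delta_lcn")
MASKABLE_FEATURES = ("tailor", "precursor", "fragment", "rt", "coelution")

_EDGE_ATTR = {
    "charge": "charge",
    "delta_cn": "delta_cn",
    "delta_lcn": "delta_lcn",
    "tailor": "tailor",
    "precursor": "w_p",
    "fragment": "w_f",
    "rt": "w_r",
    "coelution": "w_e",
}


def edge_feature_matrix(
    edges: Sequence[Edge],
    feature_mask: Tuple[str, ...] = MASKABLE_FEATURES,
) -> Tuple[np.ndarray, List[str]]:
    """Feature matrix (edges x features) and the column names used."""
    names = list(BASE_FEATURES) + [f for f in MASKABLE_FEATURES if f in feature_mask]
    mat = np.empty((len(edges), len(names)))
    for j, name in enumerate(names):
        attr = _EDGE_ATTR[name]
        for i, edge in enumerate(edges):
            value = getattr(edge, attr)
            if value is None:
                raise ValueError(f"feature {name!r} unset on an edge")
            mat[i, j] = value
    return mat, names


def _standardize(mat: np.ndarray) -> np.ndarray:
    """Label-blind z-scoring; constant columns map to zero."""
    mean = mat.mean(axis=0)
    std = mat.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return (mat - mean) / std


# ---------------------------------------------------------------------------
# q-value machinery (shared by training and reporting)
# ---------------------------------------------------------------------------

def tdc_qvalues(scores: np.ndarray, is_decoy: np.ndarray) -> np.ndarray:
    """q-values from the decoy-counting FDR estimate with a strict-``>``
    threshold: an item with score s is accepted at any tau < s, and its
    q-value is the minimum FDR over those thresholds.

    Tied scores share identical counts and hence identical q-values, which
    makes the result independent of input order.
    """
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    n = scores.size
    if n == 0:
        return np.empty(0)
    uniq, inverse = np.unique(-scores, return_inverse=True)  # ascending -> desc scores
    n_levels = uniq.size
    decoys_at = np.bincount(inverse, weights=is_decoy, minlength=n_levels)
    targets_at = np.bincount(inverse, weights=~is_decoy, minlength=n_levels)
    cum_d = np.cumsum(decoys_at)
    cum_t = np.cumsum(targets_at)
    fdr = np.minimum(1.0, cum_d / np.maximum(cum_t, 1.0))
    qvals = np.minimum.accumulate(fdr[::-1])[::-1]
    return qvals[inverse]


def count_accepted_targets(
    scores: np.ndarray, is_decoy: np.ndarray, q_threshold: float
) -> int:
    q = tdc_qvalues(scores, is_decoy)
    return int(np.sum((q <= q_threshold) & ~np.asarray(is_decoy, dtype=bool)))


# ---------------------------------------------------------------------------
# Percolator-protocol rescoring
# ---------------------------------------------------------------------------

def pair_folds(pair_ids: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Seeded pair-atomic fold assignment: all edges of a target/decoy pair
    land in the same fold, so a decoy never trains the model scoring its
    own target."""
    pair_ids = np.asarray(pair_ids)
    uniq_pairs = np.sort(np.unique(pair_ids))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(uniq_pairs.size)
    pair_to_fold = {
        int(pid): int(perm[i] % n_folds) for i, pid in enumerate(uniq_pairs)
    }
    return np.array([pair_to_fold[int(p)] for p in pair_ids])


@dataclass
class RerankModel:
    """Per-fold linear models and training diagnostics."""

    weights: List[Optional[np.ndarray]]
    intercepts: List[float]
    positives_trace: List[List[int]]
    feature_names: List[str]
    flags: List[str] = field(default_factory=list)


def _fit_svm(
    X_pos: np.ndarray, X_neg: np.ndarray, C: float
) -> Tuple[np.ndarray, float]:
    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(len(X_pos)), np.zeros(len(X_neg))])
    clf = LinearSVC(C=C, dual=False, tol=1e-4, class_weight="balanced")
    clf.fit(X, y)
    return clf.coef_[0], float(clf.intercept_[0])


def _best_initial_direction(
    X: np.ndarray, is_decoy: np.ndarray, q_threshold: float
) -> Tuple[np.ndarray, int]:
    """The single signed feature maximizing accepted targets at ``q_threshold``."""
    best_scores, best_count = X[:, 0], -1
    for j in range(X.shape[1]):
        for sign in (1.0, -1.0):
            scores = sign * X[:, j]
            count = count_accepted_targets(scores, is_decoy, q_threshold)
            if count > best_count:
                best_scores, best_count = scores, count
    return best_scores, best_count


def _select_c(
    X: np.ndarray,
    is_decoy: np.ndarray,
    pair_fold: np.ndarray,
    train_folds: Tuple[int, int],
    config: SearchConfig,
) -> float:
    """Nested selection of the SVM regularization constant: train on one
    constituent fold, validate accepted-target count on the other."""
    a, b = train_folds
    mask_a = pair_fold == a
    mask_b = pair_fold == b
    init_a, count_a = _best_initial_direction(
        X[mask_a], is_decoy[mask_a], config.rerank_train_q
    )
    if count_a == 0:
        return config.rerank_c_grid[len(config.rerank_c_grid) // 2]
    q_a = tdc_qvalues(init_a, is_decoy[mask_a])
    pos = (q_a <= config.rerank_train_q) & ~is_decoy[mask_a]
    neg = is_decoy[mask_a]
    best_c, best_val = None, -1
    for c in config.rerank_c_grid:
        if pos.sum() == 0 or neg.sum() == 0:
            break
        w, b0 = _fit_svm(X[mask_a][pos], X[mask_a][neg], c)
        val = count_accepted_targets(
            X[mask_b] @ w + b0, is_decoy[mask_b], config.rerank_train_q
        )
        if val > best_val:
            best_c, best_val = c, val
    if best_c is None:
        best_c = config.rerank_c_grid[len(config.rerank_c_grid) // 2]
    return best_c


def rerank(
    edges: Sequence[Edge],
    seed: int,
    config: SearchConfig = DEFAULT_CONFIG,
    feature_mask: Tuple[str, ...] = MASKABLE_FEATURES,
) -> Tuple[np.ndarray, RerankModel]:
    """Percolator-protocol rescoring of the surviving edges.

    Returns per-edge scores (held-out fold scores, rank-normalized within
    each fold) and the fitted :class:`RerankModel`.  Deterministic for a
    given input and seed.
    """
    n = len(edges)
    X_raw, names = edge_feature_matrix(edges, feature_mask)
    X = _standardize(X_raw)
    is_decoy = np.array([e.precursor.is_decoy for e in edges])
    pair_ids = np.array([e.precursor.pair_id for e in edges])

    fold = pair_folds(pair_ids, config.rerank_folds, seed)

    final = np.zeros(n)
    model = RerankModel([], [], [], names)
    tailor_col = names.index("tailor") if "tailor" in names else None

    for f in range(config.rerank_folds):
        test = fold == f
        train = ~test
        train_folds = tuple(g for g in range(config.rerank_folds) if g != f)[:2]
        trace: List[int] = []

        init_scores, init_count = _best_initial_direction(
            X[train], is_decoy[train], config.rerank_train_q
        )
        if init_count == 0 or is_decoy[train].sum() == 0:
            model.flags.append(
                f"fold {f}: no positives at initialization; ranking by calibrated XCorr"
            )
            model.weights.append(None)
            model.intercepts.append(0.0)
            model.positives_trace.append(trace)
            col = tailor_col if tailor_col is not None else 0
            fold_scores = X[test][:, col]
            final[test] = rankdata(fold_scores) / max(fold_scores.size, 1)
            continue

        c = _select_c(X, is_decoy, fold, train_folds, config)
        scores = init_scores
        w, b0 = None, 0.0
        for _ in range(config.rerank_iterations):
            q = tdc_qvalues(scores, is_decoy[train])
            pos = (q <= config.rerank_train_q) & ~is_decoy[train]
            trace.append(int(pos.sum()))
            if pos.sum() == 0:
                break
            w, b0 = _fit_svm(X[train][pos], X[train][is_decoy[train]], c)
            scores = X[train] @ w + b0
        model.weights.append(w)
        model.intercepts.append(b0)
        model.positives_trace.append(trace)
        if w is None:
            col = tailor_col if tailor_col is not None else 0
            fold_scores = X[test][:, col]
        else:
            fold_scores = X[test] @ w + b0
        final[test] = rankdata(fold_scores) / max(fold_scores.size, 1)

    return final, model


# ---------------------------------------------------------------------------
# Precursor-level competition and q-values
# ---------------------------------------------------------------------------

@dataclass
class ScoredPeptide:
    """The winning record of one target/decoy pair after competition."""

    pair_id: int
    precursor: Precursor
    scan_id: str
    score: float
    q_value: Optional[float] = None
    features: Optional[Dict[str, float]] = None


def _edge_features_dict(edge: Edge) -> Dict[str, float]:
    return {
        name: float(getattr(edge, attr))
        for name, attr in _EDGE_ATTR.items()
        if getattr(edge, attr) is not None
    }


def precursor_tdc(
    edges: Sequence[Edge], scores: Sequence[float]
) -> List[ScoredPeptide]:
    """Keep the single top-scoring edge per target/decoy pair.

    The pair competes across charge states and spectra; score ties break
    toward the decoy (conservative).
    """
    best: Dict[int, Tuple[float, int, int]] = {}
    for i, (edge, score) in enumerate(zip(edges, scores)):
        key = edge.precursor.pair_id
        cand = (float(score), 1 if edge.precursor.is_decoy else 0, i)
        if key not in best or cand[:2] > best[key][:2]:
            best[key] = cand
    out = []
    for pair_id in sorted(best):
        score, _, i = best[pair_id]
        edge = edges[i]
        out.append(
            ScoredPeptide(
                pair_id=pair_id,
                precursor=edge.precursor,
                scan_id=edge.scan_id,
                score=score,
                features=_edge_features_dict(edge),
            )
        )
    return out


def compute_qvalues(peptides: Sequence[ScoredPeptide]) -> List[ScoredPeptide]:
    """Assign q-values to competition winners; returns the list sorted by
    decreasing score (decoys first within ties, conservatively)."""
    if not peptides:
        return []
    scores = np.array([p.score for p in peptides])
    labels = np.array([p.precursor.is_decoy for p in peptides])
    q = tdc_qvalues(scores, labels)
    for p, qv in zip(peptides, q):
        p.q_value = float(qv)
    return sorted(peptides, key=lambda p: (-p.score, not p.precursor.is_decoy))


# ---------------------------------------------------------------------------
# Pseudo-target (entrapment) evaluation
# ---------------------------------------------------------------------------

def pseudo_target_evaluate(
    target_peptides: Sequence[Peptide],
    seed: int,
    pipeline: Callable[[Sequence[Peptide]], Sequence[ScoredPeptide]],
) -> pd.DataFrame:
    """Audit a detection pipeline's FDR estimates with disguised decoys.

    A decoy peptide is generated per target with an independent seed; both
    sets are fed to ``pipeline`` labeled as targets (the pipeline builds
    its own internal decoys).  The pipeline's nominal q-values are then
    compared with q-values recomputed from the hidden pseudo labels.

    Returns a frame with one row per reported (pipeline-)target record:
    sequence, modifications, score, nominal_q, pseudo_q, is_pseudo.
    """
    pseudo_pairs = generate_decoys(
        list(target_peptides), seed, forbidden={p.sequence for p in target_peptides}
    )
    pseudo_peptides = [
        pair.decoy for pair in pseudo_pairs if not pair.self_identical
    ]
    pseudo_keys = {p.key() for p in pseudo_peptides}
    combined = list(target_peptides) + pseudo_peptides

    results = pipeline(combined)
    records = [p for p in results if not p.precursor.is_decoy]
    if not records:
        return pd.DataFrame(
            columns=["sequence", "modifications", "score", "nominal_q", "pseudo_q", "is_pseudo"]
        )
    scores = np.array([p.score for p in records])
    is_pseudo = np.array(
        [p.precursor.peptide.key() in pseudo_keys for p in records]
    )
    pseudo_q = tdc_qvalues(scores, is_pseudo)
    return pd.DataFrame(
        {
            "sequence": [p.precursor.peptide.sequence for p in records],
            "modifications": [
                p.precursor.peptide.modification_string() for p in records
            ],
            "peptide": [p.precursor.peptide for p in records],
            "score": scores,
            "nominal_q": [p.q_value for p in records],
            "pseudo_q": pseudo_q,
            "is_pseudo": is_pseudo,
        }
    )
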