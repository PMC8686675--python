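"""End-to-end peptide detection: database -> graph -> features -> FDR.

``search_run`` wires the stages together: internal decoy generation and
precursor enumeration, optional single-scan noise reduction, bipartite
graph construction with XCorr, Tailor calibration and score-gap features,
the four auxiliary evidence features, quantile rescaling and aggregate
filtering, Percolator-protocol rescoring, precursor-level target/decoy
competition and q-value assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .config import SearchConfig, DEFAULT_CONFIG
from .dia_io import DIARun, denoise_run
from .edge_features import attach_features
from .peptide_db import (
    Peptide,
    PeptidePair,
    RTPredictor,
    HydrophobicityRTPredictor,
    enumerate_precursors,
    generate_decoys,
    predict_rt,
)
from .rerank_fdr import (
    RerankModel,
    ScoredPeptide,
    compute_qvalues,
    precursor_tdc,
    rerank,
)
from .score_filter import AlphaWeights, FeatureScaler, fit_scaler, filter_edges, score_edges
from .search_core import BipartiteGraph, build_graph, rank_gap_features, tailor_calibrate


@dataclass
class SearchResult:
    """Everything a downstream consumer might want from one search."""

    peptides: List[ScoredPeptide]
    graph: BipartiteGraph            # post-filter graph with scored edges
    scaler: FeatureScaler
    alphas: AlphaWeights
    rerank_model: RerankModel

    def accepted(self, q_threshold: float = 0.01) -> List[ScoredPeptide]:
        return [
            p
            for p in self.peptides
            if p.q_value is not None
            and p.q_value <= q_threshold
            and not p.precursor.is_decoy
        ]


def search_run(
    run: DIARun,
    peptides: Sequence[Peptide],
    seed: int,
    config: SearchConfig = DEFAULT_CONFIG,
    rt_predictor: Optional[RTPredictor] = None,
    alphas: Optional[AlphaWeights] = None,
    pairs: Optional[Sequence[PeptidePair]] = None,
) -> SearchResult:
    """Detect peptides from a DIA run given a target peptide list.

    Internal decoys are generated from ``seed + 1`` (pass prebuilt
    ``pairs`` to override); ``seed`` itself drives the rescoring folds.
    """
    if pairs is None:
        pairs = generate_decoys(list(peptides), seed + 1)
    precursors = enumerate_precursors(pairs, config.charges)

    if config.noise_reduction:
        run = denoise_run(run, config.effective_noise_tolerance_ppm)

    graph = build_graph(run, precursors, config)
    tailor_calibrate(graph)
    rank_gap_features(graph)

    predictor = rt_predictor or HydrophobicityRTPredictor()
    all_peptides = {p.peptide.key(): p.peptide for p in precursors}
    rt_map = predict_rt(predictor, list(all_peptides.values()))
    attach_features(graph, run, rt_map, config)

    alphas = alphas or AlphaWeights(
        config.alpha_p, config.alpha_f, config.alpha_r, config.alpha_e
    )
    scaler = fit_scaler(graph.edges, config.scaler_quantiles)
    score_edges(graph, scaler, alphas, config.feature_mask)
    filtered = filter_edges(graph, feature_mask=config.feature_mask)

    scores, model = rerank(filtered.edges, seed, config, config.feature_mask)
    winners = precursor_tdc(filtered.edges, scores)
    ranked = compute_qvalues(winners)
    return SearchResult(ranked, filtered, scaler, alphas, model)
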