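"""Auxiliary evidence features for candidate spectrum-precursor matches.

Four scores complement the calibrated XCorr:

* ``w_p`` - precursor intensity rank: negative sum of log-ranks of the
  monoisotopic, M+1 and M+2 precursor signals in the survey scan.  A missing
  signal receives the worst finite rank rather than zero, so peptides with
  undetectable precursors stay detectable.
* ``w_f`` - fragment matching P-value: negative log of the binomial tail
  probability of matching at least the observed number of theoretical
  fragments by chance, with the chance-match probability estimated from the
  m/z coverage of the 10 x 10 most intense picked peaks.
* ``w_r`` - retention time difference: negative absolute difference of the
  rank-normalized observed and predicted retention times (scan cycle is the
  proxy for observed RT); -0.5 for unpredictable peptides.
* ``w_e`` - precursor/fragment coelution: mean of the top-3 normalized dot
  products between the precursor's MS1 elution profile and each fragment's
  MS2 elution profile over a +/-2-cycle context.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammaln, logsumexp

from .config import SearchConfig, DEFAULT_CONFIG
from .dia_io import CentroidSpectrum, DIARun
from .search_core import BipartiteGraph, Edge


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------

def max_intensity_batch(
    mz: np.ndarray, intensity: np.ndarray, queries: np.ndarray, tol_ppm: float
) -> np.ndarray:
    """Per query m/z, the maximum intensity within +/- tol_ppm (0 if none)."""
    queries = np.asarray(queries, dtype=float)
    out = np.zeros(queries.shape)
    if mz.size == 0 or queries.size == 0:
        return out
    half = queries * tol_ppm * 1e-6
    lo = np.searchsorted(mz, queries - half, side="left")
    hi = np.searchsorted(mz, queries + half, side="right")
    for i in np.nonzero(hi > lo)[0]:
        out[i] = intensity[lo[i]: hi[i]].max()
    return out


# ---------------------------------------------------------------------------
# Feature 2: precursor intensity rank
# ---------------------------------------------------------------------------

def precursor_rank_score(
    ms1: Optional[CentroidSpectrum],
    precursor_mz: float,
    charge: int,
    tolerance_ppm: float,
    isotope_spacing: float = DEFAULT_CONFIG.isotope_spacing,
) -> float:
    """Negative sum of log intensity ranks of the M, M+1 and M+2 signals.

    The rank of a query is ``|{i in I : i >= I_q}|`` over all MS1 peak
    intensities; a query with no matching peak takes intensity 0 and hence
    the worst rank (all peaks).  An empty or missing survey scan yields 0
    (degenerate: every rank is formally 1).
    """
    if ms1 is None or ms1.mz.size == 0:
        return 0.0
    queries = np.array(
        [precursor_mz + j * isotope_spacing / charge for j in range(3)]
    )
    observed = max_intensity_batch(ms1.mz, ms1.intensity, queries, tolerance_ppm)
    sorted_int = np.sort(ms1.intensity)
    n = sorted_int.size
    # rank = count of intensities >= I  (ties share the worst rank)
    ranks = n - np.searchsorted(sorted_int, observed, side="left")
    ranks = np.maximum(ranks, 1)
    return float(-np.sum(np.log(ranks)))


# ---------------------------------------------------------------------------
# Feature 3: fragment matching P-value
# ---------------------------------------------------------------------------

@dataclass
class FragmentMatchModel:
    """Picked-peak model of one MS2 spectrum for chance-match estimation."""

    picked_mz: np.ndarray        # sorted
    p: float                     # per-fragment chance-match probability
    tau_ppm: Optional[float]     # ppm tolerance (None when absolute)
    tau_abs: Optional[float]     # absolute tolerance in Th (None when ppm)

    def half_widths(self, values: np.ndarray) -> np.ndarray:
        if self.tau_abs is not None:
            return np.full(values.shape, self.tau_abs)
        return values * self.tau_ppm * 1e-6


def pick_peaks(
    spectrum: CentroidSpectrum,
    n_segments: int = DEFAULT_CONFIG.n_segments,
    peaks_per_segment: int = DEFAULT_CONFIG.peaks_per_segment,
) -> np.ndarray:
    """The most intense peaks per equal-length m/z segment (sorted m/z).

    The raw m/z range is partitioned into ``n_segments`` half-open segments
    (the last one closed); within each, up to ``peaks_per_segment`` peaks
    are kept by intensity.
    """
    if spectrum.mz.size == 0:
        return np.empty(0)
    lo, hi = spectrum.mz[0], spectrum.mz[-1]
    if hi <= lo:
        return spectrum.mz[: peaks_per_segment].copy()
    edges = np.linspace(lo, hi, n_segments + 1)
    seg = np.minimum(
        np.searchsorted(edges, spectrum.mz, side="right") - 1, n_segments - 1
    )
    keep = []
    for s in range(n_segments):
        members = np.nonzero(seg == s)[0]
        if members.size == 0:
            continue
        order = members[np.argsort(-spectrum.intensity[members], kind="stable")]
        keep.extend(order[:peaks_per_segment])
    return np.sort(spectrum.mz[np.array(keep, dtype=int)])


def chance_match_probability(
    picked_mz: np.ndarray,
    tau_ppm: Optional[float] = None,
    tau_abs: Optional[float] = None,
) -> float:
    """Fraction of the padded observed m/z range covered by +/-tau intervals
    around the picked peaks (overlaps merged; capped at 1)."""
    if picked_mz.size < 2:
        return 1.0
    if tau_abs is not None:
        half = np.full(picked_mz.shape, float(tau_abs))
    else:
        half = picked_mz * tau_ppm * 1e-6
    starts = picked_mz - half
    ends = picked_mz + half
    total = 0.0
    cur_start, cur_end = starts[0], ends[0]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= cur_end:
            cur_end = max(cur_end, e)
        else:
            total += cur_end - cur_start
            cur_start, cur_end = s, e
    total += cur_end - cur_start
    span = ends[-1] - starts[0]
    if span <= 0:
        return 1.0
    return min(total / span, 1.0)


def build_fragment_match_model(
    spectrum: CentroidSpectrum, config: SearchConfig = DEFAULT_CONFIG
) -> FragmentMatchModel:
    picked = pick_peaks(spectrum, config.n_segments, config.peaks_per_segment)
    p = chance_match_probability(picked, tau_ppm=config.fragment_tolerance_ppm)
    return FragmentMatchModel(
        picked, p, tau_ppm=config.fragment_tolerance_ppm, tau_abs=None
    )


def count_fragment_matches(model: FragmentMatchModel, fragment_mzs: np.ndarray) -> int:
    """Number of theoretical fragments within tau of some picked peak."""
    if model.picked_mz.size == 0 or fragment_mzs.size == 0:
        return 0
    idx = np.searchsorted(model.picked_mz, fragment_mzs)
    matched = np.zeros(fragment_mzs.shape, dtype=bool)
    for side in (idx - 1, np.minimum(idx, model.picked_mz.size - 1)):
        side = np.clip(side, 0, model.picked_mz.size - 1)
        peaks = model.picked_mz[side]
        matched |= np.abs(fragment_mzs - peaks) <= model.half_widths(peaks)
    return int(matched.sum())


def binomial_tail_neglog(n: int, k: int, p: float) -> float:
    """``-ln P(X >= k)`` for X ~ Binomial(n, p), via a log-space tail sum."""
    if k <= 0 or n <= 0:
        return 0.0
    if p >= 1.0:
        return 0.0
    if p <= 0.0:
        return float("inf")
    j = np.arange(k, n + 1)
    log_terms = (
        gammaln(n + 1)
        - gammaln(j + 1)
        - gammaln(n - j + 1)
        + j * np.log(p)
        + (n - j) * np.log1p(-p)
    )
    return float(-logsumexp(log_terms))


def fragment_pvalue_score(
    spectrum: CentroidSpectrum,
    fragment_mzs: np.ndarray,
    config: SearchConfig = DEFAULT_CONFIG,
    model: Optional[FragmentMatchModel] = None,
) -> float:
    """``w_f = -ln P(matches >= observed | chance)`` for one candidate.

    Degenerate spectra (< 2 picked peaks) are uninformative: p = 1, score 0.
    """
    if model is None:
        model = build_fragment_match_model(spectrum, config)
    n_v = int(np.asarray(fragment_mzs).size)
    if n_v == 0:
        return 0.0
    n_uv = count_fragment_matches(model, np.asarray(fragment_mzs, dtype=float))
    return binomial_tail_neglog(n_v, n_uv, model.p)


# ---------------------------------------------------------------------------
# Feature 4: retention time difference
# ---------------------------------------------------------------------------

@dataclass
class RTContext:
    """Sorted observed (scan-cycle) and predicted RT multisets for a run."""

    observed: np.ndarray
    predicted: np.ndarray

    @classmethod
    def build(cls, run: DIARun, rt_map: Dict) -> "RTContext":
        observed = np.sort(
            [s.cycle_index for s in run.spectra if s.ms_level == 2]
        ).astype(float)
        predicted = np.sort(
            [v for v in rt_map.values() if v is not None]
        ).astype(float)
        return cls(observed, predicted)

    def norm_observed(self, t: float) -> float:
        n = self.observed.size
        return float(np.searchsorted(self.observed, t, side="right")) / n

    def norm_predicted(self, t: float) -> float:
        n = self.predicted.size
        return float(np.searchsorted(self.predicted, t, side="right")) / n


def rt_diff_score(
    observed_cycle: float,
    predicted_rt: Optional[float],
    context: RTContext,
    fallback: float = DEFAULT_CONFIG.rt_fallback,
) -> float:
    """``w_r = -|NormRT_u - NormRT_v|`` with rank-normalized RTs.

    ``predicted_rt=None`` (unpredictable peptide) yields the fallback value.
    """
    if predicted_rt is None or context.predicted.size == 0 or context.observed.size == 0:
        return fallback
    return -abs(
        context.norm_observed(observed_cycle) - context.norm_predicted(predicted_rt)
    )


# ---------------------------------------------------------------------------
# Feature 5: precursor/fragment coelution
# ---------------------------------------------------------------------------

def _elution_profile(
    spectra: Sequence[Optional[CentroidSpectrum]],
    queries: np.ndarray,
    tol_ppm: float,
) -> np.ndarray:
    """Per-query intensity profile across the given scans (rows = queries)."""
    out = np.zeros((queries.size, len(spectra)))
    for t, spec in enumerate(spectra):
        if spec is None:
            continue
        out[:, t] = max_intensity_batch(spec.mz, spec.intensity, queries, tol_ppm)
    return out


def coelution_score(
    run: DIARun,
    edge: Edge,
    config: SearchConfig = DEFAULT_CONFIG,
) -> float:
    """Mean of the top-3 normalized dot products between the precursor's
    MS1 elution profile and each fragment's same-window MS2 profile.

    Profiles span cycles ``t_u - delta_t .. t_u + delta_t`` (out-of-run
    cycles contribute zero); a zero-norm profile contributes a dot of 0.
    """
    dt = config.coelution_delta_t
    cycles = range(edge.cycle - dt, edge.cycle + dt + 1)
    ms1_scans = [run.ms1_of_cycle(c) for c in cycles]
    ms2_scans = [run.ms2_of(c, edge.window_index) for c in cycles]

    prec = _elution_profile(
        ms1_scans, np.array([edge.precursor.mz]), config.precursor_tolerance_ppm
    )[0]
    prec_norm = np.linalg.norm(prec)
    frag = _elution_profile(
        ms2_scans, np.asarray(edge.fragment_mzs), config.fragment_tolerance_ppm
    )
    frag_norms = np.linalg.norm(frag, axis=1)

    if prec_norm == 0:
        dots = np.zeros(frag.shape[0])
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            dots = frag @ (prec / prec_norm)
            dots = np.where(frag_norms > 0, dots / np.where(frag_norms > 0, frag_norms, 1.0), 0.0)
    if dots.size == 0:
        return 0.0
    top = np.sort(dots)[::-1][: min(3, dots.size)]
    return float(top.mean())


# ---------------------------------------------------------------------------
# Bulk attachment
# ---------------------------------------------------------------------------

def attach_features(
    graph: BipartiteGraph,
    run: DIARun,
    rt_map: Dict,
    config: SearchConfig = DEFAULT_CONFIG,
) -> BipartiteGraph:
    """Compute ``w_p``, ``w_f``, ``w_r`` and ``w_e`` for every retained edge."""
    context = RTContext.build(run, rt_map)
    match_models: Dict[int, FragmentMatchModel] = {}
    ms1_cache: Dict[int, Optional[CentroidSpectrum]] = {}

    for edge in graph.edges:
        if edge.spectrum_pos not in match_models:
            match_models[edge.spectrum_pos] = build_fragment_match_model(
                run.spectra[edge.spectrum_pos], config
            )
        if edge.cycle not in ms1_cache:
            ms1_cache[edge.cycle] = run.ms1_of_cycle(edge.cycle)

        edge.w_p = precursor_rank_score(
            ms1_cache[edge.cycle],
            edge.precursor.mz,
            edge.charge,
            config.precursor_tolerance_ppm,
            config.isotope_spacing,
        )
        edge.w_f = fragment_pvalue_score(
            run.spectra[edge.spectrum_pos],
            edge.fragment_mzs,
            config,
            model=match_models[edge.spectrum_pos],
        )
        edge.w_r = rt_diff_score(
            edge.cycle,
            rt_map.get(edge.precursor.peptide.key()),
            context,
            config.rt_fallback,
        )
        edge.w_e = coelution_score(run, edge, config)
    return graph
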