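"""Bipartite spectrum-to-precursor graph construction and primary scoring.

Every MS2 spectrum is scored against every database precursor whose
theoretical m/z falls inside the spectrum's isolation window, using the
SEQUEST cross-correlation (XCorr) score in its fast formulation: the
observed spectrum is square-root transformed, binned, regionally
normalized, and background-subtracted so that a single dot product with the
unit-intensity theoretical fragment bins equals
``corr(0) - mean(corr(tau), tau = +/-1..+/-75)``.

Only the top ``k`` matches per (spectrum, charge) are retained as graph
edges, but the full candidate score distribution is kept so the Tailor
calibration can divide by its empirical 99th quantile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import SearchConfig, DEFAULT_CONFIG
from .dia_io import CentroidSpectrum, DIARun
from .peptide_db import FragmentSet, Precursor, theoretical_fragments


@dataclass
class BinnedSpectrum:
    """Preprocessed, background-subtracted intensity vector over m/z bins."""

    bins: np.ndarray
    bin_width: float
    bin_offset: float


def mz_to_bin(mz, bin_width: float, bin_offset: float):
    """Discretize m/z: ``bin = floor(mz / width + 1 - offset)`` (SEQUEST)."""
    return (np.asarray(mz) / bin_width + 1.0 - bin_offset).astype(np.int64)


def preprocess_for_xcorr(
    spectrum: CentroidSpectrum,
    config: SearchConfig = DEFAULT_CONFIG,
    n_bins: Optional[int] = None,
) -> BinnedSpectrum:
    """SEQUEST-style preprocessing of one centroided spectrum.

    Square-root intensities, max-per-bin discretization, division of the
    occupied bin range into ``xcorr_regions`` equal regions each normalized
    to a maximum of ``xcorr_norm_cap``, then fast-XCorr background
    subtraction: each bin minus the mean of its neighbours at offsets
    +/-1..+/-``xcorr_flank``.  An empty spectrum yields an all-zero vector.
    """
    if spectrum.mz.size == 0:
        return BinnedSpectrum(
            np.zeros(n_bins or 1), config.bin_width, config.bin_offset
        )
    bins = mz_to_bin(spectrum.mz, config.bin_width, config.bin_offset)
    # extend past the last occupied bin so background subtraction is exact
    # for theoretical fragments that land just beyond the observed range
    size = int(bins.max()) + 1 + config.xcorr_flank
    if n_bins is not None:
        size = max(size, n_bins)
    vec = np.zeros(size)
    np.maximum.at(vec, bins, np.sqrt(spectrum.intensity))

    # Regional normalization over the occupied range [0, max_bin].
    top = int(bins.max()) + 1
    edges = np.linspace(0, top, config.xcorr_regions + 1).astype(int)
    for lo, hi in zip(edges[:-1], edges[1:]):
        peak = vec[lo:hi].max() if hi > lo else 0.0
        if peak > 0:
            vec[lo:hi] *= config.xcorr_norm_cap / peak

    return BinnedSpectrum(
        _subtract_background(vec, config.xcorr_flank),
        config.bin_width,
        config.bin_offset,
    )


def _subtract_background(vec: np.ndarray, flank: int) -> np.ndarray:
    """y'[i] = y[i] - (sum_{|tau|<=flank} y[i+tau] - y[i]) / (2*flank)."""
    padded = np.concatenate([np.zeros(flank), vec, np.zeros(flank)])
    csum = np.concatenate([[0.0], np.cumsum(padded)])
    n = vec.size
    window = csum[2 * flank + 1: 2 * flank + 1 + n] - csum[:n]
    return vec - (window - vec) / (2 * flank)


def theoretical_bins(
    fragment_mzs: np.ndarray, bin_width: float, bin_offset: float
) -> np.ndarray:
    """Unique bins of the unit-intensity theoretical fragment spectrum."""
    return np.unique(mz_to_bin(fragment_mzs, bin_width, bin_offset))


def xcorr_score(binned: BinnedSpectrum, fragments) -> float:
    """XCorr = 0.005 * dot(theoretical unit bins, processed observed vector)."""
    mzs = fragments.fragment_mzs if isinstance(fragments, FragmentSet) else fragments
    bins = theoretical_bins(np.asarray(mzs), binned.bin_width, binned.bin_offset)
    bins = bins[(bins >= 0) & (bins < binned.bins.size)]
    return 0.005 * float(binned.bins[bins].sum())


# ---------------------------------------------------------------------------
# Precursor index and graph
# ---------------------------------------------------------------------------

@dataclass
class _ChargeIndex:
    precursors: List[Precursor]
    mz: np.ndarray                   # sorted precursor m/z
    fragment_mzs: List[np.ndarray]   # aligned with precursors
    flat_bins: np.ndarray            # concatenated unique theoretical bins
    offsets: np.ndarray              # len(precursors)+1 prefix offsets


class PrecursorIndex:
    """Per-charge m/z-sorted view of the database with precomputed
    theoretical fragments and XCorr bins."""

    def __init__(self, precursors: Sequence[Precursor], config: SearchConfig):
        self.config = config
        self.by_charge: Dict[int, _ChargeIndex] = {}
        self.max_bin = 1
        groups: Dict[int, List[Precursor]] = {}
        for p in precursors:
            groups.setdefault(p.charge, []).append(p)
        for charge, plist in groups.items():
            plist.sort(key=lambda p: (p.mz, p.peptide.sequence, p.is_decoy))
            frag_arrays, bin_lists, offsets = [], [], [0]
            for p in plist:
                frags = theoretical_fragments(p).fragment_mzs
                frag_arrays.append(frags)
                bins = theoretical_bins(frags, config.bin_width, config.bin_offset)
                bin_lists.append(bins)
                offsets.append(offsets[-1] + bins.size)
            flat = np.concatenate(bin_lists) if bin_lists else np.empty(0, np.int64)
            if flat.size:
                self.max_bin = max(self.max_bin, int(flat.max()))
            self.by_charge[charge] = _ChargeIndex(
                plist,
                np.array([p.mz for p in plist]),
                frag_arrays,
                flat,
                np.array(offsets),
            )


@dataclass
class Edge:
    """A candidate match between an MS2 spectrum and a precursor.

    Feature slots stay ``None`` until the corresponding stage computes them.
    """

    spectrum_pos: int
    scan_id: str
    cycle: int
    window_index: int
    precursor: Precursor
    fragment_mzs: np.ndarray
    xcorr: float
    tailor: Optional[float] = None
    delta_cn: Optional[float] = None
    delta_lcn: Optional[float] = None
    w_p: Optional[float] = None
    w_f: Optional[float] = None
    w_r: Optional[float] = None
    w_e: Optional[float] = None
    aggregate: Optional[float] = None

    @property
    def charge(self) -> int:
        return self.precursor.charge


@dataclass
class BipartiteGraph:
    """Retained edges plus the pre-truncation candidate score distributions."""

    edges: List[Edge]
    groups: Dict[Tuple[int, int], List[int]]          # (spectrum_pos, charge) -> edge idx
    candidate_scores: Dict[Tuple[int, int], np.ndarray]  # sorted descending, length N
    flags: List[str] = field(default_factory=list)

    def group_edges(self, key) -> List[Edge]:
        return [self.edges[i] for i in self.groups[key]]


def build_graph(
    run: DIARun,
    precursors,
    config: SearchConfig = DEFAULT_CONFIG,
    k: Optional[int] = None,
) -> BipartiteGraph:
    """Score all in-window precursors against every MS2 spectrum and keep
    the top ``k`` edges per (spectrum, charge) by XCorr.

    The isolation window is treated as a closed interval, so a precursor
    exactly on a boundary matches both adjacent windows.  ``precursors``
    may be a list of :class:`Precursor` or a prebuilt :class:`PrecursorIndex`.
    """
    k = config.top_k if k is None else k
    if k < 1:
        raise ValueError("k must be >= 1")
    index = (
        precursors
        if isinstance(precursors, PrecursorIndex)
        else PrecursorIndex(precursors, config)
    )

    edges: List[Edge] = []
    groups: Dict[Tuple[int, int], List[int]] = {}
    candidate_scores: Dict[Tuple[int, int], np.ndarray] = {}

    for pos, spec in enumerate(run.spectra):
        if spec.ms_level != 2:
            continue
        lo, hi = spec.isolation_window
        if config.precursor_window_radius is not None:
            center = 0.5 * (lo + hi)
            lo = center - config.precursor_window_radius
            hi = center + config.precursor_window_radius
        window_index = _find_window_index(run, spec)
        binned = preprocess_for_xcorr(spec, config, n_bins=index.max_bin + 1)
        processed = binned.bins
        if processed.size < index.max_bin + 1:
            processed = np.concatenate(
                [processed, np.zeros(index.max_bin + 1 - processed.size)]
            )
        for charge in config.charges:
            ci = index.by_charge.get(charge)
            if ci is None:
                continue
            i0 = int(np.searchsorted(ci.mz, lo, side="left"))
            i1 = int(np.searchsorted(ci.mz, hi, side="right"))
            if i1 <= i0:
                continue
            flat = ci.flat_bins[ci.offsets[i0]: ci.offsets[i1]]
            starts = (ci.offsets[i0:i1] - ci.offsets[i0]).astype(np.intp)
            scores = 0.005 * np.add.reduceat(processed[flat], starts)
            order = sorted(
                range(scores.size),
                key=lambda j: (
                    -scores[j],
                    ci.precursors[i0 + j].peptide.sequence,
                    ci.precursors[i0 + j].is_decoy,
                ),
            )
            key = (pos, charge)
            candidate_scores[key] = np.sort(scores)[::-1].copy()
            idx_list = []
            for j in order[:k]:
                p = ci.precursors[i0 + j]
                idx_list.append(len(edges))
                edges.append(
                    Edge(
                        spectrum_pos=pos,
                        scan_id=spec.scan_id,
                        cycle=spec.cycle_index,
                        window_index=window_index,
                        precursor=p,
                        fragment_mzs=ci.fragment_mzs[i0 + j],
                        xcorr=float(scores[j]),
                    )
                )
            groups[key] = idx_list

    graph = BipartiteGraph(edges, groups, candidate_scores)
    if not edges:
        warnings.warn("no precursor fell in any isolation window; empty graph")
    return graph


def _find_window_index(run: DIARun, spec: CentroidSpectrum) -> int:
    key = (round(spec.isolation_window[0], 6), round(spec.isolation_window[1], 6))
    for i, w in enumerate(run.windows):
        if (round(w[0], 6), round(w[1], 6)) == key:
            return i
    raise ValueError(f"spectrum {spec.scan_id} window not registered in run")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def tailor_calibrate(graph: BipartiteGraph) -> BipartiteGraph:
    """Divide each edge's XCorr by the empirical 99th quantile of its
    (spectrum, charge) candidate score distribution.

    With N candidates sorted decreasingly, the divisor is the score at
    1-based position ``[N/100]`` (round half away from zero, floored at 1).
    A non-positive divisor yields ``tailor = 0`` and a flag.
    """
    for key, idx_list in graph.groups.items():
        scores = graph.candidate_scores[key]
        n = scores.size
        pos = min(max(_round_half_away(n / 100.0), 1), n)
        divisor = float(scores[pos - 1])
        for i in idx_list:
            if divisor <= 0:
                graph.edges[i].tailor = 0.0
            else:
                graph.edges[i].tailor = graph.edges[i].xcorr / divisor
        if divisor <= 0 and idx_list:
            graph.flags.append(f"non-positive Tailor divisor for group {key}")
    return graph


def rank_gap_features(graph: BipartiteGraph) -> BipartiteGraph:
    """Score-gap features of the retained, rank-ordered edges.

    For the edge at rank i with XCorr s_i: ``delta_cn = (s_i - s_{i+1}) /
    max(s_i, 1)`` against the next retained edge (0 for the last) and
    ``delta_lcn`` the same against the last retained edge.
    """
    for key, idx_list in graph.groups.items():
        if not idx_list:
            continue
        scores = [graph.edges[i].xcorr for i in idx_list]
        s_last = scores[-1]
        for rank, i in enumerate(idx_list):
            s_i = scores[rank]
            denom = max(s_i, 1.0)
            s_next = scores[rank + 1] if rank + 1 < len(scores) else s_i
            graph.edges[i].delta_cn = (
                (s_i - s_next) / denom if rank + 1 < len(scores) else 0.0
            )
            graph.edges[i].delta_lcn = (s_i - s_last) / denom
    return graph
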