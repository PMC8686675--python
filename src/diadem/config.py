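"""Run-wide configuration for the DIA search pipeline.

All tunable knobs of the search live here so that a whole analysis is
reproducible from a single :class:`SearchConfig` value.  Defaults follow the
published operating point of the method: top ``k = 5`` matches per spectrum
and charge, charge states 1-5, a +/-2-cycle chromatographic context for
coelution, a 10 x 10 peak-picking grid for the fragment-matching P-value,
1st/99th-quantile feature rescaling, and a retention-time fallback score of
-0.5 for peptides whose retention time cannot be predicted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

#: Grid of candidate values for each of the four aggregate-score weights.
ALPHA_GRID: Tuple[float, ...] = (0.0, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6, 3.2, 6.4, 12.8)

PROTON_MASS = 1.007276466
WATER_MASS = 18.0105646
#: 13C - 12C mass difference, used for isotope spacing of precursor queries.
ISOTOPE_SPACING = 1.00335


@dataclass(frozen=True)
class SearchConfig:
    """Settings for graph construction, edge features, filtering and rescoring.

    Tolerances are in parts-per-million unless stated otherwise.  The XCorr
    bin width defaults to the low-resolution fragment convention
    (1.0005079 Th); use 0.02 Th for high-resolution fragment spectra.
    """

    # --- bipartite graph construction ---
    top_k: int = 5
    charges: Tuple[int, ...] = (1, 2, 3, 4, 5)
    #: Override the isolation window with an explicit +/- radius (Th) around
    #: the window centre; ``None`` uses the window bounds from the mzML.
    precursor_window_radius: Optional[float] = None

    # --- XCorr preprocessing ---
    bin_width: float = 1.0005079
    bin_offset: float = 0.4
    xcorr_regions: int = 10
    xcorr_norm_cap: float = 50.0
    xcorr_flank: int = 75

    # --- edge features ---
    precursor_tolerance_ppm: float = 10.0
    fragment_tolerance_ppm: float = 10.0
    coelution_delta_t: int = 2
    n_segments: int = 10
    peaks_per_segment: int = 10
    isotope_spacing: float = ISOTOPE_SPACING
    rt_fallback: float = -0.5

    # --- noise reduction (single-scan peak removal) ---
    noise_reduction: bool = False
    #: ``None`` reuses ``fragment_tolerance_ppm``.
    noise_tolerance_ppm: Optional[float] = None

    # --- aggregate score / filtering ---
    scaler_quantiles: Tuple[float, float] = (0.01, 0.99)
    alpha_p: float = 0.8
    alpha_f: float = 0.1
    alpha_r: float = 0.8
    alpha_e: float = 0.8
    alpha_grid: Tuple[float, ...] = ALPHA_GRID
    #: Feature mask for ablation runs: features absent from the mask are
    #: dropped from the aggregate score and from rescoring.
    feature_mask: Tuple[str, ...] = ("tailor", "precursor", "fragment", "rt", "coelution")

    # --- semi-supervised rescoring ---
    rerank_folds: int = 3
    rerank_iterations: int = 10
    rerank_train_q: float = 0.01
    rerank_c_grid: Tuple[float, ...] = (0.1, 1.0, 10.0)

    def with_(self, **kwargs) -> "SearchConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @property
    def effective_noise_tolerance_ppm(self) -> float:
        if self.noise_tolerance_ppm is not None:
            return self.noise_tolerance_ppm
        return self.fragment_tolerance_ppm


@dataclass(frozen=True)
class DigestConfig:
    """In-silico digestion settings.

    Trypsin cleaves C-terminal to K/R; by default cleavage before proline is
    allowed (set ``proline_rule=True`` to suppress it).  Cysteines always
    carry carbamidomethyl (+57.02146 Da); up to ``max_variable_mods``
    methionines may be oxidized (+15.99491 Da).
    """

    missed_cleavages: int = 2
    min_length: int = 7
    max_length: int = 50
    min_mass: float = 200.0
    max_mass: float = 6000.0
    max_variable_mods: int = 3
    proline_rule: bool = False
    oxidize_methionine: bool = True
    carbamidomethyl_cysteine: bool = True


DEFAULT_CONFIG = SearchConfig()
DEFAULT_DIGEST = DigestConfig()
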