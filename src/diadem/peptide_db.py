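"""Precursor database construction from a protein FASTA.

Covers in-silico tryptic digestion with variable modifications, shuffled
decoy generation with explicit target/decoy pairing, charge-state
enumeration, theoretical b/y fragment ions, and retention-time prediction.

Masses are monoisotopic throughout; residue masses come from the standard
table (pyteomics), water is 18.0105646 Da and the proton 1.007276466 Da.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from pyteomics import fasta as _pyteomics_fasta
from pyteomics import mass as _pyteomics_mass

from .config import DigestConfig, PROTON_MASS, WATER_MASS, DEFAULT_DIGEST

RESIDUE_MASS: Dict[str, float] = dict(_pyteomics_mass.std_aa_mass)
CARBAMIDOMETHYL = 57.02146
OXIDATION = 15.99491

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class Peptide:
    """A (possibly modified) peptide.

    ``modifications`` is a sorted tuple of ``(position, mass_delta)`` with
    0-based positions; it includes static carbamidomethyl on every cysteine
    as well as any variable modifications.
    """

    sequence: str
    modifications: Tuple[Tuple[int, float], ...] = ()

    def __post_init__(self):
        object.__setattr__(
            self, "modifications", tuple(sorted(self.modifications))
        )

    @property
    def monoisotopic_mass(self) -> float:
        mass = WATER_MASS + sum(RESIDUE_MASS[a] for a in self.sequence)
        mass += sum(delta for _, delta in self.modifications)
        return mass

    def variable_modifications(self) -> Tuple[Tuple[int, float], ...]:
        """Modifications other than static carbamidomethyl on cysteine."""
        return tuple(
            (pos, delta)
            for pos, delta in self.modifications
            if not (self.sequence[pos] == "C" and abs(delta - CARBAMIDOMETHYL) < 1e-6)
        )

    def modification_string(self) -> str:
        """Inline representation of variable mods, e.g. ``PEPTM[+15.9949]IDEK``."""
        variable = dict(self.variable_modifications())
        out = []
        for i, aa in enumerate(self.sequence):
            out.append(aa)
            if i in variable:
                out.append(f"[{variable[i]:+.4f}]")
        return "".join(out)

    def key(self) -> Tuple[str, Tuple[Tuple[int, float], ...]]:
        return (self.sequence, self.modifications)


@dataclass(frozen=True)
class Precursor:
    """A charged peptide with theoretical m/z and target/decoy identity.

    ``pair_id`` is shared between a target peptide and its decoy across all
    charge states, so the later target-decoy competition happens once per
    (peptide, modification set) pair.
    """

    peptide: Peptide
    charge: int
    is_decoy: bool
    pair_id: int

    @property
    def mz(self) -> float:
        return (self.peptide.monoisotopic_mass + self.charge * PROTON_MASS) / self.charge


@dataclass(frozen=True)
class PeptidePair:
    """A target peptide and its sequence-shuffled decoy."""

    target: Peptide
    decoy: Peptide
    pair_id: int
    self_identical: bool = False


@dataclass
class FragmentSet:
    """Sorted b/y fragment m/z values of a precursor."""

    precursor: Precursor
    fragment_mzs: np.ndarray


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------

def cleavage_sites(sequence: str, proline_rule: bool = False) -> List[int]:
    """Positions after which trypsin cleaves (C-terminal to K/R)."""
    sites = []
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR":
            if proline_rule and sequence[i + 1] == "P":
                continue
            sites.append(i + 1)
    return sites


def digest_protein(sequence: str, params: DigestConfig) -> List[str]:
    """Tryptic peptides of one protein with up to the allowed missed cleavages.

    Length/mass bounds are *not* applied here; see :func:`digest_fasta`.
    """
    bounds = [0] + cleavage_sites(sequence, params.proline_rule) + [len(sequence)]
    peptides = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + params.missed_cleavages, len(bounds))):
            peptides.append(sequence[bounds[i]: bounds[j]])
    return peptides


def _modification_variants(sequence: str, params: DigestConfig) -> List[Peptide]:
    static = tuple(
        (i, CARBAMIDOMETHYL)
        for i, aa in enumerate(sequence)
        if aa == "C" and params.carbamidomethyl_cysteine
    )
    variants = [Peptide(sequence, static)]
    if params.oxidize_methionine:
        met_positions = [i for i, aa in enumerate(sequence) if aa == "M"]
        for r in range(1, min(params.max_variable_mods, len(met_positions)) + 1):
            for combo in itertools.combinations(met_positions, r):
                mods = static + tuple((i, OXIDATION) for i in combo)
                variants.append(Peptide(sequence, mods))
    return variants


def digest_fasta(
    fasta_path=None,
    params: DigestConfig = DEFAULT_DIGEST,
    proteins: Optional[Sequence[str]] = None,
) -> List[Peptide]:
    """Digest a FASTA file (or explicit protein sequences) into unique peptides.

    Peptides are deduplicated across proteins; all modification variants
    (static cys carbamidomethyl, up to ``max_variable_mods`` oxidized
    methionines) are enumerated.  Length and mass bounds from ``params``
    apply to the unmodified backbone / modified mass respectively.
    """
    if proteins is None:
        if fasta_path is None:
            raise ValueError("either fasta_path or proteins is required")
        proteins = []
        with _pyteomics_fasta.read(str(fasta_path)) as reader:
            for i, (descr, seq) in enumerate(reader):
                seq = seq.strip().upper().rstrip("*")
                if not seq or any(aa not in RESIDUE_MASS for aa in seq):
                    raise ValueError(f"malformed FASTA record {descr!r}")
                proteins.append(seq)

    seen: Set[str] = set()
    backbones: List[str] = []
    for protein in proteins:
        for pep in digest_protein(protein, params):
            if params.min_length <= len(pep) <= params.max_length and pep not in seen:
                seen.add(pep)
                backbones.append(pep)

    out: List[Peptide] = []
    for backbone in backbones:
        for variant in _modification_variants(backbone, params):
            if params.min_mass <= variant.monoisotopic_mass <= params.max_mass:
                out.append(variant)
    return out


# ---------------------------------------------------------------------------
# Decoys
# ---------------------------------------------------------------------------

def _reposition_mods(
    peptide: Peptide, permutation: Sequence[int], new_sequence: str
) -> Tuple[Tuple[int, float], ...]:
    # permutation[i] = origin index in the target sequence for new position i
    origin_to_new = {orig: new for new, orig in enumerate(permutation)}
    return tuple(
        sorted((origin_to_new[pos], delta) for pos, delta in peptide.modifications)
    )


def generate_decoys(
    peptides: Sequence[Peptide],
    seed: int,
    max_retries: int = 20,
    forbidden: Optional[Set[str]] = None,
) -> List[PeptidePair]:
    """One shuffled decoy per target peptide, linked by ``pair_id``.

    Internal residues are shuffled with the first and last residues fixed
    (preserving mass and tryptic termini).  A shuffle colliding with any
    target backbone is re-drawn up to ``max_retries`` times, then falls back
    to reversing the internal residues.  Modifications travel with their
    residues.  Deterministic for a given seed.
    """
    rng = random.Random(seed)
    target_seqs = {p.sequence for p in peptides}
    if forbidden:
        target_seqs |= set(forbidden)
    pairs: List[PeptidePair] = []
    for pair_id, target in enumerate(peptides):
        n = len(target.sequence)
        if n <= 3:
            pairs.append(PeptidePair(target, target, pair_id, self_identical=True))
            continue
        internal = list(range(1, n - 1))
        permutation = None
        for _ in range(max_retries):
            cand = internal[:]
            rng.shuffle(cand)
            perm = [0] + cand + [n - 1]
            seq = "".join(target.sequence[i] for i in perm)
            if seq not in target_seqs:
                permutation = perm
                break
        if permutation is None:
            permutation = [0] + internal[::-1] + [n - 1]
        decoy_seq = "".join(target.sequence[i] for i in permutation)
        decoy = Peptide(decoy_seq, _reposition_mods(target, permutation, decoy_seq))
        pairs.append(
            PeptidePair(
                target, decoy, pair_id, self_identical=decoy_seq == target.sequence
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# Precursors and fragments
# ---------------------------------------------------------------------------

def enumerate_precursors(
    pairs: Sequence[PeptidePair],
    charges: Iterable[int] = (1, 2, 3, 4, 5),
) -> List[Precursor]:
    """One target and one decoy :class:`Precursor` per (pair, charge)."""
    charges = sorted(set(charges))
    if not all(1 <= c <= 5 for c in charges):
        raise ValueError("charges must be within 1..5")
    out = []
    for pair in pairs:
        for c in charges:
            out.append(Precursor(pair.target, c, False, pair.pair_id))
            out.append(Precursor(pair.decoy, c, True, pair.pair_id))
    return out


def theoretical_fragments(precursor: Precursor) -> FragmentSet:
    """b/y ions at 1+ (always) and 2+ (when precursor charge >= 3)."""
    pep = precursor.peptide
    n = len(pep.sequence)
    residue = np.array([RESIDUE_MASS[a] for a in pep.sequence])
    deltas = np.zeros(n)
    for pos, delta in pep.modifications:
        deltas[pos] += delta
    residue = residue + deltas
    prefix = np.cumsum(residue)  # prefix[i] = neutral mass of b_{i+1} fragment chain
    total = prefix[-1]
    b_neutral = prefix[:-1]
    y_neutral = total - prefix[:-1] + WATER_MASS
    frag_charges = [1] if precursor.charge < 3 else [1, 2]
    mzs = []
    for z in frag_charges:
        mzs.append((b_neutral + z * PROTON_MASS) / z)
        mzs.append((y_neutral + z * PROTON_MASS) / z)
    arr = np.sort(np.concatenate(mzs)) if mzs else np.empty(0)
    return FragmentSet(precursor, arr)


# ---------------------------------------------------------------------------
# Retention time prediction
# ---------------------------------------------------------------------------

#: Approximate reversed-phase retention coefficients (hydrophobicity scale,
#: Krokhin-style).  Only the induced ordering matters downstream: the RT
#: feature compares normalized ranks, not raw times.
RT_COEFFICIENTS: Dict[str, float] = {
    "W": 11.0, "F": 10.5, "L": 9.6, "I": 8.4, "M": 5.8, "V": 5.0,
    "Y": 4.0, "A": 0.8, "T": 0.4, "P": 0.2, "E": 0.0, "D": -0.5,
    "C": -0.8, "S": -0.8, "Q": -0.9, "G": -0.9, "N": -1.2, "R": -1.3,
    "H": -1.3, "K": -1.9,
}
#: Oxidation makes methionine markedly less hydrophobic.
RT_OXIDIZED_MET = 2.0


class RTPredictor:
    """Contract: a deterministic map peptide -> predicted retention time,
    plus a predicate saying whether the peptide is predictable at all."""

    def predictable(self, peptide: Peptide) -> bool:  # pragma: no cover - interface
        raise NotImplementedError

    def predict(self, peptide: Peptide) -> float:  # pragma: no cover - interface
        raise NotImplementedError


class HydrophobicityRTPredictor(RTPredictor):
    """Residue-coefficient hydrophobicity sum.

    Supports unmodified peptides, static cys carbamidomethyl and methionine
    oxidation; any other modification makes the peptide unpredictable (the
    RT feature then takes its fallback value).
    """

    def predictable(self, peptide: Peptide) -> bool:
        for pos, delta in peptide.variable_modifications():
            if not (
                peptide.sequence[pos] == "M" and abs(delta - OXIDATION) < 1e-6
            ):
                return False
        return True

    def predict(self, peptide: Peptide) -> float:
        oxidized = {
            pos
            for pos, delta in peptide.variable_modifications()
            if peptide.sequence[pos] == "M" and abs(delta - OXIDATION) < 1e-6
        }
        total = 0.0
        for i, aa in enumerate(peptide.sequence):
            total += RT_OXIDIZED_MET if i in oxidized else RT_COEFFICIENTS[aa]
        return total


class FileRTPredictor(RTPredictor):
    """Predictions read from a two-column TSV: modification-string <TAB> rt.

    A peptide missing from the table is flagged unpredictable rather than
    raising, so the RT feature can fall back gracefully.
    """

    def __init__(self, path):
        self.table: Dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, value = line.split("\t")[:2]
                self.table[key] = float(value)

    def predictable(self, peptide: Peptide) -> bool:
        return peptide.modification_string() in self.table

    def predict(self, peptide: Peptide) -> float:
        return self.table[peptide.modification_string()]


def predict_rt(
    predictor: RTPredictor, peptides: Sequence[Peptide]
) -> Dict[Tuple[str, Tuple[Tuple[int, float], ...]], Optional[float]]:
    """Predicted RT per peptide key; ``None`` marks unpredictable peptides."""
    out = {}
    for pep in peptides:
        out[pep.key()] = predictor.predict(pep) if predictor.predictable(pep) else None
    return out
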