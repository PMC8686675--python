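"""Synthetic DIA runs with known ground truth.

The generator emulates the structure the search exploits: repeated scan
cycles of one MS1 survey scan plus a sweep of wide isolation windows,
co-fragmented peptides inside each window, M/M+1/M+2 isotope envelopes with
averagine-style ratios, Gaussian elution profiles across cycles, ppm-level
m/z jitter, and uniform noise peaks.  A configurable fraction of present
peptides is "MS1-suppressed": their fragments appear but their survey-scan
signal does not, mimicking precursors below the intrascan dynamic range.

It does not attempt realistic chimeric noise, charge-envelope overlap or
instrument peak shapes; passing tests on these runs demonstrates the
machinery and its calibration, not performance on real chromatography.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .config import DigestConfig, PROTON_MASS
from .dia_io import CentroidSpectrum, DIARun, build_run, write_mzml
from .peptide_db import (
    HydrophobicityRTPredictor,
    Peptide,
    Precursor,
    digest_fasta,
    theoretical_fragments,
)

#: Roughly physiological amino-acid frequencies with K/R enriched so random
#: proteins digest into plenty of tryptic peptides.
_AA_FREQ = {
    "A": 0.074, "C": 0.015, "D": 0.054, "E": 0.062, "F": 0.040,
    "G": 0.068, "H": 0.022, "I": 0.058, "K": 0.072, "L": 0.090,
    "M": 0.022, "N": 0.044, "P": 0.045, "Q": 0.038, "R": 0.062,
    "S": 0.068, "T": 0.054, "V": 0.064, "W": 0.011, "Y": 0.031,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of one simulated acquisition.

    Defaults describe a small but structurally faithful run: 24 fixed
    25-m/z windows from 400 Th, 40 scan cycles, log-normal abundances,
    Gaussian chromatographic peaks of sigma 1.5 cycles, apex-assignment
    noise of 3% of the gradient, 5 ppm m/z jitter and uniform noise peaks.
    """

    n_proteins: int = 60
    protein_length: int = 300
    n_peptides: Optional[int] = 2000     # database size cap after digestion
    window_count: int = 24
    window_width: float = 25.0
    window_start: float = 400.0
    n_cycles: int = 40
    peak_width_cycles: float = 1.5
    fraction_present: float = 0.15
    present_charges: Tuple[int, ...] = (2, 3)
    abundance_mu: float = 9.0            # log-intensity scale
    abundance_sigma: float = 1.0
    ms1_noise_peaks: int = 100
    ms2_noise_peaks: int = 150
    noise_intensity_mu: float = 5.5
    noise_intensity_sigma: float = 1.0
    mz_jitter_ppm: float = 5.0
    ms1_suppressed_fraction: float = 0.0
    rt_noise_fraction: float = 0.03      # apex sigma as fraction of the gradient
    min_elution_factor: float = 0.01
    seed: int = 0

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    @property
    def windows(self) -> List[Tuple[float, float]]:
        return [
            (
                self.window_start + i * self.window_width,
                self.window_start + (i + 1) * self.window_width,
            )
            for i in range(self.window_count)
        ]


@dataclass
class GroundTruthEntry:
    peptide: Peptide
    charge: int
    mz: float
    apex_cycle: float
    abundance: float
    ms1_suppressed: bool


@dataclass
class SyntheticGroundTruth:
    """Peptides truly present in a simulated run."""

    entries: List[GroundTruthEntry]

    def present_keys(self) -> Set:
        return {e.peptide.key() for e in self.entries}

    def suppressed_keys(self) -> Set:
        return {e.peptide.key() for e in self.entries if e.ms1_suppressed}

    def classify(self, peptide: Peptide) -> str:
        """``present``, ``related`` or ``absent``.

        ``related`` marks evidence-sharing homologs of present peptides —
        the same backbone with different modifications, or a missed-cleavage
        sub/super-peptide — whose fragments genuinely occur in the run, so a
        peptide-level ground truth cannot call them true or false.
        """
        if peptide.key() in self.present_keys():
            return "present"
        backbones = {e.peptide.sequence for e in self.entries}
        if peptide.sequence in backbones:
            return "related"
        for b in backbones:
            if peptide.sequence in b or b in peptide.sequence:
                return "related"
        return "absent"


def empirical_fdp(
    peptides: Sequence[Peptide], truth: SyntheticGroundTruth
) -> Tuple[int, int, float]:
    """(n_true, n_false, FDP) of a detected peptide list against the truth.

    ``related`` homologs (see :meth:`SyntheticGroundTruth.classify`) are
    excluded from both numerator and denominator.
    """
    n_true = n_false = 0
    for pep in peptides:
        cls = truth.classify(pep)
        if cls == "present":
            n_true += 1
        elif cls == "absent":
            n_false += 1
    return n_true, n_false, n_false / max(n_true + n_false, 1)


def simulate_fasta(config: SimulationConfig) -> str:
    """Random protein FASTA text, deterministic under the config seed."""
    rng = np.random.default_rng(config.seed)
    letters = np.array(list(_AA_FREQ))
    probs = np.array(list(_AA_FREQ.values()))
    probs = probs / probs.sum()
    records = []
    for i in range(config.n_proteins):
        seq = "".join(rng.choice(letters, size=config.protein_length, p=probs))
        records.append(f">synthetic_protein_{i:04d}\n{seq}")
    return "\n".join(records) + ("\n" if records else "")


def _fasta_proteins(fasta_text: str) -> List[str]:
    proteins, current = [], []
    for line in fasta_text.splitlines():
        if line.startswith(">"):
            if current:
                proteins.append("".join(current))
                current = []
        elif line.strip():
            current.append(line.strip())
    if current:
        proteins.append("".join(current))
    return proteins


def database_from_fasta(
    fasta_text: str,
    config: SimulationConfig,
    digest: DigestConfig = DigestConfig(),
) -> List[Peptide]:
    """Digest the FASTA and cap the database at ``n_peptides`` (seeded sample)."""
    peptides = digest_fasta(proteins=_fasta_proteins(fasta_text), params=digest)
    if config.n_peptides is not None and len(peptides) > config.n_peptides:
        rng = np.random.default_rng(config.seed + 7)
        idx = np.sort(rng.choice(len(peptides), size=config.n_peptides, replace=False))
        peptides = [peptides[i] for i in idx]
    return peptides


def _merge_duplicate_mz(mz: np.ndarray, inten: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    if mz.size < 2:
        return mz, inten
    keep_mz, keep_int = [mz[0]], [inten[0]]
    for m, i in zip(mz[1:], inten[1:]):
        if m == keep_mz[-1]:
            keep_int[-1] += i
        else:
            keep_mz.append(m)
            keep_int.append(i)
    return np.array(keep_mz), np.array(keep_int)


def simulate_run(
    fasta_text: str,
    config: SimulationConfig,
    database: Optional[Sequence[Peptide]] = None,
) -> Tuple[DIARun, SyntheticGroundTruth]:
    """Generate a DIA run from the FASTA's digest.

    A seeded subset of database peptides is "present": each gets a charge
    state, a log-normal abundance, an apex cycle derived from the default
    hydrophobicity retention predictor plus Gaussian noise (so the RT
    feature is informative but imperfect), and per-fragment efficiencies.
    Per cycle, one MS1 scan carries the isotope envelopes of unsuppressed
    present precursors scaled by the Gaussian elution factor, and each
    window's MS2 scan carries the fragments of in-window present precursors
    plus uniform noise peaks.
    """
    rng = np.random.default_rng(config.seed + 1)
    if database is None:
        database = database_from_fasta(fasta_text, config)
    database = list(database)

    mz_lo = config.window_start
    mz_hi = config.window_start + config.window_count * config.window_width

    # retention model over the whole database: rank -> position in gradient
    predictor = HydrophobicityRTPredictor()
    rts = {p.key(): predictor.predict(p) for p in database if predictor.predictable(p)}
    rt_values = np.sort(list(rts.values())) if rts else np.array([0.0])

    n_present = int(round(config.fraction_present * len(database)))
    charge_probs = np.full(len(config.present_charges), 1.0 / len(config.present_charges))
    order = rng.permutation(len(database))
    entries: List[GroundTruthEntry] = []
    for i in order:
        if len(entries) >= n_present:
            break
        pep = database[i]
        charge = int(rng.choice(config.present_charges, p=charge_probs))
        mz = (pep.monoisotopic_mass + charge * PROTON_MASS) / charge
        if not (mz_lo <= mz <= mz_hi):
            alt = [c for c in config.present_charges if c != charge]
            mz = None
            for c in alt:
                m = (pep.monoisotopic_mass + c * PROTON_MASS) / c
                if mz_lo <= m <= mz_hi:
                    charge, mz = c, m
                    break
            if mz is None:
                continue
        rt = rts.get(pep.key())
        frac = (
            np.searchsorted(rt_values, rt, side="right") / rt_values.size
            if rt is not None
            else rng.uniform()
        )
        apex = (0.05 + 0.9 * frac) * config.n_cycles + rng.normal(
            0.0, config.rt_noise_fraction * config.n_cycles
        )
        entries.append(
            GroundTruthEntry(
                peptide=pep,
                charge=charge,
                mz=mz,
                apex_cycle=float(np.clip(apex, 0, config.n_cycles - 1)),
                abundance=float(rng.lognormal(config.abundance_mu, config.abundance_sigma)),
                ms1_suppressed=bool(rng.uniform() < config.ms1_suppressed_fraction),
            )
        )

    # per-entry fragment m/z and efficiencies, and isotope envelope ratios
    frag_mzs, frag_eff, iso_ratio = [], [], []
    for e in entries:
        frags = theoretical_fragments(
            Precursor(e.peptide, e.charge, False, -1)
        ).fragment_mzs
        frag_mzs.append(frags)
        frag_eff.append(rng.uniform(0.05, 1.0, size=frags.size))
        r1 = min(e.peptide.monoisotopic_mass / 1800.0, 1.5)
        iso_ratio.append((1.0, r1, r1 * r1 / 2.0))

    windows = config.windows
    spectra: List[CentroidSpectrum] = []
    scan_counter = 0

    def jitter(values: np.ndarray) -> np.ndarray:
        if config.mz_jitter_ppm <= 0 or values.size == 0:
            return values
        return values * (
            1.0 + rng.normal(0.0, config.mz_jitter_ppm * 1e-6, size=values.size)
        )

    def noise_peaks(n: int, lo: float, hi: float) -> Tuple[np.ndarray, np.ndarray]:
        if n <= 0:
            return np.empty(0), np.empty(0)
        return (
            rng.uniform(lo, hi, size=n),
            rng.lognormal(
                config.noise_intensity_mu, config.noise_intensity_sigma, size=n
            ),
        )

    for cycle in range(config.n_cycles):
        elution = np.array(
            [
                np.exp(
                    -((cycle - e.apex_cycle) ** 2)
                    / (2.0 * config.peak_width_cycles ** 2)
                )
                for e in entries
            ]
        )
        active = elution >= config.min_elution_factor

        # --- MS1 survey scan ---
        mzs, ints = [], []
        for i, e in enumerate(entries):
            if not active[i] or e.ms1_suppressed:
                continue
            base = e.abundance * elution[i]
            for j, ratio in enumerate(iso_ratio[i]):
                mzs.append(e.mz + j * 1.00335 / e.charge)
                ints.append(base * ratio)
        nmz, nint = noise_peaks(config.ms1_noise_peaks, mz_lo - 50, mz_hi + 50)
        mz_arr = jitter(np.array(mzs)) if mzs else np.empty(0)
        all_mz = np.concatenate([mz_arr, nmz])
        all_int = np.concatenate([np.array(ints), nint])
        all_mz, all_int = _merge_duplicate_mz(all_mz, all_int)
        scan_counter += 1
        spectra.append(
            CentroidSpectrum(
                scan_id=f"scan={scan_counter}",
                ms_level=1,
                cycle_index=cycle,
                mz=all_mz,
                intensity=all_int,
            )
        )

        # --- MS2 scans, one per window ---
        for w_lo, w_hi in windows:
            mzs, ints = [], []
            for i, e in enumerate(entries):
                if not active[i] or not (w_lo <= e.mz <= w_hi):
                    continue
                base = e.abundance * elution[i]
                mzs.append(frag_mzs[i])
                ints.append(base * frag_eff[i])
            nmz, nint = noise_peaks(config.ms2_noise_peaks, 100.0, 1800.0)
            sig_mz = jitter(np.concatenate(mzs)) if mzs else np.empty(0)
            sig_int = np.concatenate(ints) if ints else np.empty(0)
            all_mz = np.concatenate([sig_mz, nmz])
            all_int = np.concatenate([sig_int, nint])
            all_mz, all_int = _merge_duplicate_mz(all_mz, all_int)
            scan_counter += 1
            spectra.append(
                CentroidSpectrum(
                    scan_id=f"scan={scan_counter}",
                    ms_level=2,
                    cycle_index=cycle,
                    mz=all_mz,
                    intensity=all_int,
                    isolation_window=(w_lo, w_hi),
                )
            )

    return build_run(spectra), SyntheticGroundTruth(entries)


def write_ground_truth(truth: SyntheticGroundTruth, path) -> None:
    """Tab-separated ground truth: one row per present precursor."""
    with open(path, "w") as fh:
        fh.write("sequence\tmodifications\tcharge\tmz\tapex_cycle\tabundance\tms1_suppressed\n")
        for e in truth.entries:
            fh.write(
                f"{e.peptide.sequence}\t{e.peptide.modification_string()}\t"
                f"{e.charge}\t{e.mz:.6f}\t{e.apex_cycle:.3f}\t"
                f"{e.abundance:.3f}\t{int(e.ms1_suppressed)}\n"
            )


def simulate_to_files(directory, config: SimulationConfig) -> Dict[str, str]:
    """Write a complete simulated dataset (mzML + FASTA + truth TSV)."""
    import os

    os.makedirs(directory, exist_ok=True)
    fasta_text = simulate_fasta(config)
    run, truth = simulate_run(fasta_text, config)
    paths = {
        "fasta": os.path.join(directory, "database.fasta"),
        "mzml": os.path.join(directory, "run.mzML"),
        "truth": os.path.join(directory, "ground_truth.tsv"),
    }
    with open(paths["fasta"], "w") as fh:
        fh.write(fasta_text)
    write_mzml(run, paths["mzml"])
    write_ground_truth(truth, paths["truth"])
    return paths
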