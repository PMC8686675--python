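"""Reading, modelling and writing DIA runs and search results.

A DIA run is a sequence of scan *cycles*: one MS1 survey scan followed by one
MS2 scan per isolation window, where each window co-isolates and co-fragments
every precursor whose m/z falls inside it.  This module parses centroided
mzML into that cycle structure, optionally removes single-scan noise peaks,
and writes detection results as TSV or pepXML.  A minimal mzML writer is
included so simulated runs can be exchanged with other DIA tools.
"""

from __future__ import annotations

import base64
import zlib
from dataclasses import dataclass
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lxml import etree


class Peak(NamedTuple):
    """A single centroided peak: m/z in Thomson, non-negative intensity."""

    mz: float
    intensity: float


@dataclass
class CentroidSpectrum:
    """One centroided scan.

    ``mz`` is strictly sorted ascending.  MS2 spectra carry the closed
    isolation window ``(low, high)`` of the precursors they co-fragment;
    MS1 spectra have ``isolation_window=None``.  ``cycle_index`` counts the
    MS1 scans seen so far (0-based), so all MS2 scans between survey scan i
    and i+1 share cycle i.
    """

    scan_id: str
    ms_level: int
    cycle_index: int
    mz: np.ndarray
    intensity: np.ndarray
    isolation_window: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size:
            if np.any(np.diff(self.mz) <= 0):
                order = np.argsort(self.mz, kind="stable")
                self.mz = self.mz[order]
                self.intensity = self.intensity[order]
            if np.any(np.diff(self.mz) <= 0):
                raise ValueError(f"duplicate m/z values in scan {self.scan_id}")
        if self.ms_level == 2 and self.isolation_window is None:
            raise ValueError(f"MS2 scan {self.scan_id} lacks an isolation window")
        if self.ms_level == 1 and self.isolation_window is not None:
            raise ValueError(f"MS1 scan {self.scan_id} must not have an isolation window")

    @property
    def peaks(self) -> List[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]

    def max_intensity_within(self, query_mz: float, tol_ppm: float) -> float:
        """Maximum intensity of peaks within +/- tol_ppm of ``query_mz`` (0 if none)."""
        half = query_mz * tol_ppm * 1e-6
        lo = np.searchsorted(self.mz, query_mz - half, side="left")
        hi = np.searchsorted(self.mz, query_mz + half, side="right")
        if hi <= lo:
            return 0.0
        return float(self.intensity[lo:hi].max())


@dataclass
class DIARun:
    """A DIA run organised into cycles and isolation windows.

    ``windows`` lists the distinct isolation windows; ``cycles[i]`` maps a
    window index to the position (in ``spectra``) of that cycle's MS2 scan,
    and ``ms1_scans[i]`` is the position of cycle i's survey scan (or None).
    """

    spectra: List[CentroidSpectrum]
    windows: List[Tuple[float, float]]
    cycles: List[Dict[int, int]]
    ms1_scans: List[Optional[int]]

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def ms1_of_cycle(self, cycle: int) -> Optional[CentroidSpectrum]:
        if 0 <= cycle < len(self.ms1_scans) and self.ms1_scans[cycle] is not None:
            return self.spectra[self.ms1_scans[cycle]]
        return None

    def ms2_of(self, cycle: int, window_index: int) -> Optional[CentroidSpectrum]:
        if 0 <= cycle < len(self.cycles):
            idx = self.cycles[cycle].get(window_index)
            if idx is not None:
                return self.spectra[idx]
        return None

    def ms2_spectra(self) -> List[CentroidSpectrum]:
        return [s for s in self.spectra if s.ms_level == 2]


def _window_key(window: Tuple[float, float]) -> Tuple[float, float]:
    return (round(window[0], 6), round(window[1], 6))


def build_run(spectra: Sequence[CentroidSpectrum]) -> DIARun:
    """Assemble a :class:`DIARun` from cycle-indexed spectra.

    Windows are collected in order of first appearance and sorted by lower
    bound; within a cycle a window may appear at most once.
    """
    seen: Dict[Tuple[float, float], Tuple[float, float]] = {}
    for s in spectra:
        if s.ms_level == 2:
            seen.setdefault(_window_key(s.isolation_window), s.isolation_window)
    windows = sorted(seen.values(), key=lambda w: (w[0], w[1]))
    w_index = {_window_key(w): i for i, w in enumerate(windows)}

    n_cycles = 1 + max((s.cycle_index for s in spectra), default=-1)
    cycles: List[Dict[int, int]] = [dict() for _ in range(n_cycles)]
    ms1_scans: List[Optional[int]] = [None] * n_cycles
    for pos, s in enumerate(spectra):
        if s.ms_level == 1:
            if ms1_scans[s.cycle_index] is not None:
                raise ValueError(f"cycle {s.cycle_index} has two MS1 scans")
            ms1_scans[s.cycle_index] = pos
        else:
            wi = w_index[_window_key(s.isolation_window)]
            if wi in cycles[s.cycle_index]:
                raise ValueError(
                    f"cycle {s.cycle_index} contains window {s.isolation_window} twice"
                )
            cycles[s.cycle_index][wi] = pos
    return DIARun(list(spectra), windows, cycles, ms1_scans)


def read_dia_run(
    path,
    window_spec: Optional[Sequence[Tuple[float, float]]] = None,
) -> DIARun:
    """Read a centroided mzML file into a :class:`DIARun`.

    Cycle indices are assigned by counting MS1 scans.  MS2 scans must carry
    isolation-window metadata (target m/z plus lower/upper offsets); if they
    do not, ``window_spec`` must supply an explicit window list, which is
    then assigned round-robin to the MS2 scans within each cycle.

    Raises ``ValueError`` for profile-mode spectra (centroid upstream) and
    for MS2 scans with neither window metadata nor a ``window_spec``.
    """
    spectra: List[CentroidSpectrum] = []
    ms1_seen = 0
    ms2_in_cycle = 0
    for entry in _iter_mzml_spectra(path):
        if entry["profile"]:
            raise ValueError(
                f"scan {entry['id']} is profile-mode; centroid the data first"
            )
        if entry["ms_level"] == 1:
            ms1_seen += 1
            ms2_in_cycle = 0
            spectra.append(
                CentroidSpectrum(
                    scan_id=entry["id"],
                    ms_level=1,
                    cycle_index=max(ms1_seen - 1, 0),
                    mz=entry["mz"],
                    intensity=entry["intensity"],
                )
            )
            continue
        window = entry["isolation_window"]
        if window is None:
            if window_spec is None:
                raise ValueError(
                    f"MS2 scan {entry['id']} lacks isolation-window metadata "
                    "and no window_spec was supplied"
                )
            window = tuple(window_spec[ms2_in_cycle % len(window_spec)])
        ms2_in_cycle += 1
        spectra.append(
            CentroidSpectrum(
                scan_id=entry["id"],
                ms_level=2,
                cycle_index=max(ms1_seen - 1, 0),
                mz=entry["mz"],
                intensity=entry["intensity"],
                isolation_window=window,
            )
        )
    return build_run(spectra)


def _local(tag) -> str:
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def _decode_binary_array(array_el) -> Tuple[Optional[str], Optional[np.ndarray]]:
    """Decode one <binaryDataArray>: returns (kind, values) where kind is
    'mz' or 'intensity'."""
    kind = None
    dtype = "<f8"
    compressed = False
    text = ""
    for child in array_el.iter():
        tag = _local(child.tag)
        if tag == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
            elif acc == "MS:1000521":
                dtype = "<f4"
            elif acc == "MS:1000523":
                dtype = "<f8"
            elif acc == "MS:1000574":
                compressed = True
        elif tag == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _iter_mzml_spectra(path):
    """Stream mzML <spectrum> elements into plain dicts.

    Handles the subset of the standard a DIA search needs: ms level,
    centroid/profile flags, the MS2 isolation window and the m/z and
    intensity binary arrays (32/64-bit float, zlib or uncompressed).
    """
    for _, el in etree.iterparse(str(path), events=("end",), tag="*"):
        if _local(el.tag) != "spectrum":
            continue
        entry = {
            "id": el.get("id", ""),
            "ms_level": 1,
            "profile": False,
            "isolation_window": None,
            "mz": np.empty(0),
            "intensity": np.empty(0),
        }
        target = lo_off = hi_off = None
        for child in el.iter():
            tag = _local(child.tag)
            if tag == "cvParam":
                acc = child.get("accession", "")
                parent = _local(child.getparent().tag)
                if acc == "MS:1000511" and parent == "spectrum":
                    entry["ms_level"] = int(child.get("value"))
                elif acc == "MS:1000128" and parent == "spectrum":
                    entry["profile"] = True
                elif acc == "MS:1000827":
                    target = float(child.get("value"))
                elif acc == "MS:1000828":
                    lo_off = float(child.get("value"))
                elif acc == "MS:1000829":
                    hi_off = float(child.get("value"))
            elif tag == "binaryDataArray":
                kind, values = _decode_binary_array(child)
                if kind is not None:
                    entry[kind] = values
        if target is not None and lo_off is not None and hi_off is not None:
            entry["isolation_window"] = (target - lo_off, target + hi_off)
        yield entry
        el.clear()


# ---------------------------------------------------------------------------
# Single-scan noise reduction
# ---------------------------------------------------------------------------

def _has_match(query_mz: np.ndarray, ref_mz: np.ndarray, tol_ppm: float) -> np.ndarray:
    """For each query m/z, is there a reference peak within the symmetric
    ppm tolerance |dmz| <= tol * 1e-6 * max(mz_q, mz_r)?

    The symmetric criterion makes "A corroborates B" equivalent to
    "B corroborates A", which in turn makes noise reduction idempotent.
    """
    if ref_mz.size == 0 or query_mz.size == 0:
        return np.zeros(query_mz.shape, dtype=bool)
    out = np.zeros(query_mz.shape, dtype=bool)
    idx = np.searchsorted(ref_mz, query_mz)
    for side in (idx - 1, np.minimum(idx, ref_mz.size - 1)):
        side = np.clip(side, 0, ref_mz.size - 1)
        ref = ref_mz[side]
        tol = tol_ppm * 1e-6 * np.maximum(query_mz, ref)
        out |= np.abs(query_mz - ref) <= tol
    return out


def denoise_run(run: DIARun, tolerance_ppm: float) -> DIARun:
    """Remove MS2 peaks that occur in a single scan cycle.

    A peak in the MS2 scan of window w, cycle c is retained iff the MS2 scan
    of the *same window* in cycle c-1 or c+1 contains a peak within the ppm
    tolerance.  First/last cycles use their single neighbour; MS1 scans are
    never modified.  A run with fewer than two cycles is returned unchanged.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    if run.n_cycles < 2:
        return run

    new_spectra = list(run.spectra)
    for wi in range(len(run.windows)):
        per_cycle = [run.cycles[c].get(wi) for c in range(run.n_cycles)]
        for c, pos in enumerate(per_cycle):
            if pos is None:
                continue
            spec = run.spectra[pos]
            keep = np.zeros(spec.mz.shape, dtype=bool)
            for nb in (c - 1, c + 1):
                if 0 <= nb < run.n_cycles and per_cycle[nb] is not None:
                    nb_spec = run.spectra[per_cycle[nb]]
                    keep |= _has_match(spec.mz, nb_spec.mz, tolerance_ppm)
            new_spectra[pos] = CentroidSpectrum(
                scan_id=spec.scan_id,
                ms_level=2,
                cycle_index=spec.cycle_index,
                mz=spec.mz[keep],
                intensity=spec.intensity[keep],
                isolation_window=spec.isolation_window,
            )
    return build_run(new_spectra)


# ---------------------------------------------------------------------------
# Result writing
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "sequence",
    "modifications",
    "charge",
    "precursor_mz",
    "scan",
    "charge_feature",
    "delta_cn",
    "delta_lcn",
    "tailor",
    "precursor_rank",
    "fragment_pvalue",
    "rt_diff",
    "coelution",
    "score",
    "q_value",
    "label",
]


def results_frame(peptides: Sequence) -> pd.DataFrame:
    """Tabulate :class:`~diadem.rerank_fdr.ScoredPeptide` records."""
    rows = []
    for p in peptides:
        feats = p.features or {}
        rows.append(
            {
                "sequence": p.precursor.peptide.sequence,
                "modifications": p.precursor.peptide.modification_string(),
                "charge": p.precursor.charge,
                "precursor_mz": p.precursor.mz,
                "scan": p.scan_id,
                "charge_feature": feats.get("charge", float("nan")),
                "delta_cn": feats.get("delta_cn", float("nan")),
                "delta_lcn": feats.get("delta_lcn", float("nan")),
                "tailor": feats.get("tailor", float("nan")),
                "precursor_rank": feats.get("precursor", float("nan")),
                "fragment_pvalue": feats.get("fragment", float("nan")),
                "rt_diff": feats.get("rt", float("nan")),
                "coelution": feats.get("coelution", float("nan")),
                "score": p.score,
                "q_value": p.q_value,
                "label": "decoy" if p.precursor.is_decoy else "target",
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(peptides: Sequence, path, format: str = "tsv") -> None:
    """Write scored peptides as ``tsv`` (all feature columns) or ``pepxml``."""
    if format == "tsv":
        results_frame(peptides).to_csv(path, sep="\t", index=False)
    elif format == "pepxml":
        _write_pepxml(peptides, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


_PEPXML_NS = "http://regis-web.systemsbiology.net/pepXML"


def _write_pepxml(peptides: Sequence, path) -> None:
    from .config import PROTON_MASS

    root = etree.Element(
        f"{{{_PEPXML_NS}}}msms_pipeline_analysis",
        nsmap={None: _PEPXML_NS},
        summary_xml=str(path),
    )
    run = etree.SubElement(
        root,
        f"{{{_PEPXML_NS}}}msms_run_summary",
        base_name="dia_run",
        raw_data_type="mzML",
        raw_data=".mzML",
    )
    etree.SubElement(
        run,
        f"{{{_PEPXML_NS}}}search_summary",
        base_name="dia_run",
        search_engine="diadem",
        precursor_mass_type="monoisotopic",
        fragment_mass_type="monoisotopic",
    )
    for i, p in enumerate(peptides, start=1):
        neutral = p.precursor.mz * p.precursor.charge - p.precursor.charge * PROTON_MASS
        query = etree.SubElement(
            run,
            f"{{{_PEPXML_NS}}}spectrum_query",
            spectrum=str(p.scan_id),
            start_scan=str(i),
            end_scan=str(i),
            precursor_neutral_mass=f"{neutral:.6f}",
            assumed_charge=str(p.precursor.charge),
            index=str(i),
        )
        result = etree.SubElement(query, f"{{{_PEPXML_NS}}}search_result")
        hit = etree.SubElement(
            result,
            f"{{{_PEPXML_NS}}}search_hit",
            hit_rank="1",
            peptide=p.precursor.peptide.sequence,
            protein="unknown",
            num_tot_proteins="1",
            calc_neutral_pep_mass=f"{p.precursor.peptide.monoisotopic_mass:.6f}",
            massdiff="0.0",
            is_rejected="0",
        )
        for name, value in (("score", p.score), ("q_value", p.q_value)):
            etree.SubElement(
                hit, f"{{{_PEPXML_NS}}}search_score", name=name, value=f"{value:.6g}"
            )
        for name, value in (p.features or {}).items():
            etree.SubElement(
                hit, f"{{{_PEPXML_NS}}}search_score", name=name, value=f"{value:.6g}"
            )
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


# ---------------------------------------------------------------------------
# Minimal mzML writer (enough for round-tripping centroided DIA runs)
# ---------------------------------------------------------------------------

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _encode_array(values: np.ndarray) -> str:
    return base64.b64encode(np.asarray(values, dtype="<f8").tobytes()).decode("ascii")


def _cv(parent, accession: str, name: str, value: str = "", **extra) -> None:
    etree.SubElement(
        parent,
        f"{{{_MZML_NS}}}cvParam",
        cvRef="MS",
        accession=accession,
        name=name,
        value=value,
        **extra,
    )


def write_mzml(run: DIARun, path, include_isolation_windows: bool = True) -> None:
    """Write a :class:`DIARun` as centroided mzML (64-bit, uncompressed).

    ``include_isolation_windows=False`` omits the MS2 precursor metadata,
    producing files that need an explicit ``window_spec`` to read back.
    """
    root = etree.Element(
        f"{{{_MZML_NS}}}mzML", nsmap={None: _MZML_NS}, version="1.1.0"
    )
    cv_list = etree.SubElement(root, f"{{{_MZML_NS}}}cvList", count="1")
    etree.SubElement(
        cv_list,
        f"{{{_MZML_NS}}}cv",
        id="MS",
        fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    run_el = etree.SubElement(root, f"{{{_MZML_NS}}}run", id="run")
    spec_list = etree.SubElement(
        run_el, f"{{{_MZML_NS}}}spectrumList", count=str(len(run.spectra))
    )
    for index, spec in enumerate(run.spectra):
        el = etree.SubElement(
            spec_list,
            f"{{{_MZML_NS}}}spectrum",
            index=str(index),
            id=spec.scan_id,
            defaultArrayLength=str(spec.mz.size),
        )
        _cv(el, "MS:1000511", "ms level", str(spec.ms_level))
        _cv(el, "MS:1000127", "centroid spectrum")
        if (
            spec.ms_level == 2
            and spec.isolation_window is not None
            and include_isolation_windows
        ):
            lo, hi = spec.isolation_window
            target = 0.5 * (lo + hi)
            plist = etree.SubElement(el, f"{{{_MZML_NS}}}precursorList", count="1")
            prec = etree.SubElement(plist, f"{{{_MZML_NS}}}precursor")
            iso = etree.SubElement(prec, f"{{{_MZML_NS}}}isolationWindow")
            _cv(iso, "MS:1000827", "isolation window target m/z", f"{target:.6f}")
            _cv(iso, "MS:1000828", "isolation window lower offset", f"{target - lo:.6f}")
            _cv(iso, "MS:1000829", "isolation window upper offset", f"{hi - target:.6f}")
            sel_list = etree.SubElement(
                prec, f"{{{_MZML_NS}}}selectedIonList", count="1"
            )
            sel = etree.SubElement(sel_list, f"{{{_MZML_NS}}}selectedIon")
            _cv(sel, "MS:1000744", "selected ion m/z", f"{target:.6f}")
            etree.SubElement(prec, f"{{{_MZML_NS}}}activation")
        arr_list = etree.SubElement(
            el, f"{{{_MZML_NS}}}binaryDataArrayList", count="2"
        )
        for accession, name, values in (
            ("MS:1000514", "m/z array", spec.mz),
            ("MS:1000515", "intensity array", spec.intensity),
        ):
            encoded = _encode_array(values)
            arr = etree.SubElement(
                arr_list,
                f"{{{_MZML_NS}}}binaryDataArray",
                encodedLength=str(len(encoded)),
            )
            _cv(arr, "MS:1000523", "64-bit float")
            _cv(arr, "MS:1000576", "no compression")
            _cv(arr, accession, name)
            binary = etree.SubElement(arr, f"{{{_MZML_NS}}}binary")
            binary.text = encoded
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )
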