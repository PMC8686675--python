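import numpy as np
import pytest

from diadem import (
    CentroidSpectrum,
    SimulationConfig,
    build_run,
    database_from_fasta,
    simulate_fasta,
    simulate_run,
)


def make_spectrum(mz, intensity, ms_level=2, cycle=0, window=None, scan_id="s"):
    if ms_level == 2 and window is None:
        window = (400.0, 425.0)
    return CentroidSpectrum(
        scan_id=scan_id,
        ms_level=ms_level,
        cycle_index=cycle,
        mz=np.asarray(mz, dtype=float),
        intensity=np.asarray(intensity, dtype=float),
        isolation_window=window if ms_level == 2 else None,
    )


def make_cycle_run(peaks_by_cycle_window, n_cycles, windows):
    """Build a run from {(cycle, window_index): (mz_list, int_list)}."""
    spectra = []
    sid = 0
    for c in range(n_cycles):
        sid += 1
        spectra.append(make_spectrum([], [], ms_level=1, cycle=c, scan_id=f"scan={sid}"))
        for wi, w in enumerate(windows):
            mzs, ints = peaks_by_cycle_window.get((c, wi), ([], []))
            sid += 1
            spectra.append(
                make_spectrum(mzs, ints, ms_level=2, cycle=c, window=w, scan_id=f"scan={sid}")
            )
    return build_run(spectra)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset shared by pipeline-level unit tests."""
    config = SimulationConfig(
        n_proteins=10,
        protein_length=250,
        n_peptides=200,
        window_count=8,
        n_cycles=16,
        fraction_present=0.25,
        seed=42,
    )
    fasta = simulate_fasta(config)
    database = database_from_fasta(fasta, config)
    run, truth = simulate_run(fasta, config, database=database)
    return {"config": config, "fasta": fasta, "database": database, "run": run, "truth": truth}
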