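"""Write a small synthetic DIA dataset (mzML + FASTA + ground truth).

The run cycles through one MS1 survey scan plus one MS2 scan per 25-m/z
isolation window; a known subset of database peptides is present with
log-normal abundances, Gaussian elution profiles and isotope envelopes.
"""

from diadem import SimulationConfig, simulate_to_files

config = SimulationConfig(
    n_proteins=20,
    n_peptides=500,
    window_count=12,
    n_cycles=24,
    fraction_present=0.2,
    ms1_suppressed_fraction=0.1,
    seed=1,
)
paths = simulate_to_files("scratch/example_dataset", config)

for kind, path in paths.items():
    print(f"{kind:>6}: {path}")
with open(paths["truth"]) as fh:
    lines = fh.read().splitlines()
print(f"\n{len(lines) - 1} peptides are truly present; the first few:")
for line in lines[:4]:
    print("   ", line)
# Each ground-truth row records the peptide, its charge and m/z, the scan
# cycle at which it elutes most strongly, its abundance, and whether its
# MS1 (survey-scan) signal was suppressed.
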