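"""Dissect the evidence features of one confident peptide-spectrum match.

Each retained edge of the bipartite graph carries: the Tailor-calibrated
XCorr (w_T), the precursor intensity log-rank (w_P <= 0, 0 is best), the
fragment-matching binomial P-value score (w_F >= 0, larger is better),
the retention-time difference (-1 <= w_R <= 0), and the precursor/fragment
coelution score (0 <= w_E <= 1).
"""

from diadem import (
    SimulationConfig,
    database_from_fasta,
    search_run,
    simulate_fasta,
    simulate_run,
)

config = SimulationConfig(
    n_peptides=400, fraction_present=0.25, window_count=10, n_cycles=24, seed=3
)
fasta = simulate_fasta(config)
database = database_from_fasta(fasta, config)
run, truth = simulate_run(fasta, config, database=database)
result = search_run(run, database, seed=0)

present = truth.present_keys()
best = next(
    p for p in result.peptides
    if not p.precursor.is_decoy and p.precursor.peptide.key() in present
)
print(f"peptide {best.precursor.peptide.modification_string()} "
      f"({best.precursor.charge}+), detected at q = {best.q_value:.4f}")
print(f"matched in spectrum {best.scan_id}\n")
names = {
    "tailor": "w_T  calibrated XCorr (1.0 = at the 99th pctile of candidates)",
    "precursor": "w_P  precursor isotope intensity log-rank (0 = all rank 1)",
    "fragment": "w_F  -ln P(matching this many fragments by chance)",
    "rt": "w_R  -|observed - predicted| normalized retention time",
    "coelution": "w_E  precursor/fragment elution-profile agreement",
    "charge": "     precursor charge state",
    "delta_cn": "     XCorr gap to the next-ranked candidate",
    "delta_lcn": "     XCorr gap to the last retained candidate",
}
for key, label in names.items():
    print(f"  {best.features[key]:>9.4f}   {label}")
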