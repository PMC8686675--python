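# diadem

**Library-free peptide detection in data-independent acquisition (DIA) mass
spectrometry data.**

In DIA, the instrument cycles through fixed, wide *m/z* isolation windows
(e.g. 25 Th) and co-fragments *every* precursor inside each window. The
resulting MS2 spectra are chimeric mixtures, which breaks the
one-peptide-per-spectrum assumption of conventional database search engines,
and the usual workaround — a spectral library of previously observed
patterns — is expensive to build and rarely transfers across laboratories.
`diadem` detects peptides in a single centroided DIA run using **only a
protein FASTA database**: no spectral library, no assumption that the
precursor is even visible in the MS1 survey scan.

## Method

The run and the database are connected in a bipartite graph
G = (U, V, E): U are the MS2 spectra, V the charged peptides ("precursors",
charges 1–5) from a tryptic digest with static carbamidomethyl-Cys, up to
three variable Met oxidations, and one shuffled decoy per target. An edge
(u, v) exists when the theoretical m/z of v falls inside the isolation
window of u; for each spectrum and charge only the top *k* = 5 edges by
SEQUEST XCorr are kept. Each edge then receives eight features:

| feature | meaning |
|---|---|
| `charge`, `delta_cn`, `delta_lcn` | charge state and XCorr rank-gap features |
| w<sup>T</sup> | XCorr divided by the 99th percentile of the spectrum's candidate score distribution (Tailor calibration) |
| w<sup>P</sup> = −Σ<sub>j∈{M,M+1,M+2}</sub> ln rank(I<sub>j</sub>) | log-rank of the precursor isotope intensities in the survey scan; a missing signal gets the worst finite rank, not −∞ |
| w<sup>F</sup> = −ln Σ<sub>j≥N<sub>uv</sub></sub> C(N<sub>v</sub>, j) p<sup>j</sup>(1−p)<sup>N<sub>v</sub>−j</sup> | binomial-tail probability of matching N<sub>uv</sub> of N<sub>v</sub> theoretical fragments by chance, with p estimated from the m/z coverage of the 10×10 most intense picked peaks |
| w<sup>R</sup> = −\|NormRT<sub>u</sub> − NormRT<sub>v</sub>\| | rank-normalized observed (scan cycle) vs. predicted retention time; −0.5 when the peptide is unpredictable |
| w<sup>E</sup> | mean of the top-3 normalized dot products between the precursor's MS1 elution profile and each fragment's MS2 profile over ±2 cycles |

Features are rescaled so their 1st/99th quantiles map to [0, 1] and combined
as w = w<sup>T</sup> + α<sup>P</sup>w<sup>P</sup> + α<sup>F</sup>w<sup>F</sup> +
α<sup>R</sup>w<sup>R</sup> + α<sup>E</sup>w<sup>E</sup>; per spectrum and
charge, edges scoring below the top-XCorr edge's aggregate are discarded.
Surviving edges are rescored by a semi-supervised linear max-margin
classifier (Percolator protocol: 3 cross-validation folds that keep each
target/decoy pair atomic, iteratively refined positives at q ≤ 0.01).
Finally, competition happens per target/decoy pair across charge states, and
q-values come from the decoy-counting estimate
FDR(τ) = min(1, #{decoys > τ} / max(1, #{targets > τ})).

A synthetic-data module generates complete DIA runs (cycles, windows,
isotope envelopes, Gaussian elution, noise, optional MS1-suppressed
peptides) with known ground truth, and an entrapment ("pseudo-target")
harness audits any pipeline's FDR estimates with disguised decoys.

## Worked example

```bash
python examples/02_search_a_run.py
```

```
database: 800 peptides, 160 truly present
accepted at q <= 0.01: 91 peptides (91 known true, 0 known false, FDP 0.000)

top detections (score is the rescored, rank-normalized value):
   GPGAAGPFNFLGLFIQLK           3+  score=1.0000  q=0.0000  target
   TLVLGLIISPYKAVVANGR          3+  score=1.0000  q=0.0000  target
   ACTM[+15.9949]YKGAGCDTNKAK   3+  score=1.0000  q=0.0000  target
   ...
```

The run contains 160 truly present peptides out of an 800-peptide database;
at a 1% peptide-level FDR the engine reports 91 peptides, all of which are
in the ground truth. `q` is the minimal FDR threshold at which a peptide is
accepted; `[+15.9949]` marks an oxidized methionine. The other examples
show dataset simulation (`01`), the anatomy of the eight edge features for
one confident match (`03`), and entrapment-based FDR auditing (`04`).

The same pipeline is available from the shell:

```bash
diadem simulate scratch/ds --seed 1 --fraction-present 0.2
diadem search scratch/ds/run.mzML scratch/ds/database.fasta -o results.tsv
```

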