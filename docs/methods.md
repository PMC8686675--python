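# Methods

This note records the model, the numerical conventions and the design
decisions behind `diadem`, at the level of detail a maintainer or reviewer
needs to reproduce or challenge them.

## The detection model

A DIA run is modelled as a sequence of scan cycles, each one MS1 survey
scan followed by one MS2 scan per isolation window; every MS2 spectrum is
associated with the most recent preceding MS1 scan, and the scan cycle
index serves as the observed retention-time axis. Isolation windows are
treated as *closed* intervals, so a precursor sitting exactly on a boundary
is a candidate for both adjacent windows.

Candidate generation scores every in-window precursor against every MS2
spectrum with SEQUEST XCorr in the fast formulation: square-root
intensities, discretized at bin width 1.0005079 Th with offset 0.4 (0.02 Th
is the high-resolution alternative), maximum intensity per bin, the
occupied bin range split into 10 equal regions each normalized to a peak of
50, then background subtraction of the mean over offsets ±1..±75. After
this transform a single dot product with the unit-intensity theoretical
b/y-ion bins equals corr(0) − mean(corr(τ)) over τ = ±1..±75; the processed
vector is extended 75 bins past the last occupied bin so the identity holds
exactly for fragments just beyond the observed range (verified against a
direct cross-correlation oracle to < 1e−9). Scores carry the conventional
0.005 scale. Only the top k = 5 candidates per (spectrum, charge) become
graph edges, but the full candidate score distribution is retained: the
Tailor calibration divides each XCorr by the score at 1-based position
[N/100] (round half away from zero, floored at 1) of the N sorted candidate
scores. With N < 100 the divisor is the top score, so calibrated scores of
that group are ≤ 1; a non-positive divisor yields 0 and a flag. N is
counted per charge state, following the per-charge candidate definition.

## Edge features

*Precursor intensity rank.* For the monoisotopic, M+1 and M+2 query m/z
(isotope spacing 1.00335/z by default; configurable to exactly 1/z), the
maximum MS1 intensity within tolerance is ranked by ≥-counting against all
peaks of the survey scan, and the feature is minus the sum of the three log
ranks. A query with no matching peak takes intensity 0 and hence the worst
rank — a finite penalty rather than a veto, which is what lets peptides
with no visible precursor survive to the classifier. Natural logarithms are
used throughout; any other base rescales features linearly and is absorbed
by the α weights and the classifier.

*Fragment-matching P-value.* The spectrum's m/z range is split into 10
equal segments (half-open, last closed) and the 10 most intense peaks per
segment are picked; the chance-match probability p is the measure of the
union of ±τ intervals around the picked peaks divided by the padded
observed range (overlaps merged, capped at 1). The feature is the negative
log binomial tail P(X ≥ N_matched) with N_theoretical trials, computed as a
log-space sum of gammaln terms (verified against term-by-term enumeration).
Degenerate spectra (< 2 picked peaks) and empty fragment sets score 0. The
picked peaks are used *only* for this feature.

*Retention time.* Observed RT is the scan-cycle rank of the spectrum among
all MS2 spectra; predicted RT is the rank of the peptide's prediction among
all precursor predictions (decoys predicted on their own sequence). The
default predictor is a residue-coefficient hydrophobicity sum with
approximate Krokhin-style coefficients; only the induced ordering matters,
since the feature compares normalized ranks. Peptides with modifications
the predictor does not support — anything beyond static
carbamidomethyl-Cys and Met oxidation — and peptides missing from a
file-backed prediction table are "unpredictable" and receive the fallback
−0.5.

*Coelution.* Precursor profiles are read from the MS1 scans of cycles
t ± 2 at the precursor m/z; fragment profiles from the same-window MS2
scans at each fragment m/z; per scan the maximum intensity within tolerance
is taken, missing cycles contribute 0, and a zero-norm profile contributes
a dot product of 0. The score is the mean of the three largest normalized
dot products (all of them when fewer than three fragments exist).

Default mass tolerances are 10 ppm (Orbitrap-style); 30 ppm suits
TripleTOF-style data. Single-scan noise reduction (drop an MS2 peak unless
the same-window MS2 scan of an adjacent cycle has a peak within tolerance)
is off by default and intended for noisy time-of-flight data; its peak
matching uses the symmetric criterion |Δm/z| ≤ ppm·10⁻⁶·max(m/z₁, m/z₂),
which makes corroboration mutual and the operation exactly idempotent.

## Filtering, rescoring, confidence estimates

The five evidence scores are rescaled by mapping their empirical 1st/99th
quantiles (linear-interpolation definition) onto [0, 1], without clamping;
the scaler is fit on all edges, targets and decoys alike, so the transform
is label-blind. The aggregate score puts unit weight on calibrated XCorr
and non-negative weights α on the other four; within each (spectrum,
charge) group edges below the top-XCorr edge's aggregate are discarded, so
that edge always survives and no group is emptied. The shipped default
weights (0.8, 0.1, 0.8, 0.8) were selected by the included grid search
(values {0, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6, 3.2, 6.4, 12.8} per weight,
objective = accepted peptides at 1% FDR) on simulated data; `feature_mask`
removes features from both the aggregate and the classifier for ablations.

Rescoring follows the Percolator protocol rather than wrapping a
particular solver: edges are hashed into 3 folds atomically by
target/decoy pair (a decoy never trains the model that scores its own
target); the initial direction is the single signed feature maximizing
targets at q ≤ 0.01; then for 10 iterations the positives are the target
edges currently at q ≤ 0.01, the negatives all decoy edges, and a
regularized linear max-margin classifier (liblinear primal, balanced class
weights) is refit. The regularization constant is chosen once per fold by
nested selection among {0.1, 1, 10} on the two training folds. Held-out
scores are rank-normalized within each fold before merging. A fold with no
positives at initialization falls back to ranking by calibrated XCorr and
is flagged.

Competition is at the precursor-pair level: a pair is one (peptide,
modification set) across all charge states, its decoy sharing the pair id;
the top-scoring edge of the pair wins, ties resolving toward the decoy.
q-values use FDR(τ) = min(1, D(>τ)/max(1, T(>τ))) with suffix
minimization; tied scores share counts, making the result independent of
input order (verified exactly against threshold enumeration). The estimate
deliberately carries no +1 correction on the decoy count.

Decoys are internal shuffles with the first and last residues fixed —
preserving mass, composition and tryptic termini — re-drawn up to 20 times
on collision with a target backbone, then falling back to internal
reversal; modifications travel with their residues. Peptides of length ≤ 3
have no shuffle and are flagged self-identical. The entrapment harness
generates an independent set of such shuffles, feeds them to the pipeline
disguised as targets, and recomputes q-values from the hidden labels.

## The synthetic generator

`synthetic_data` emulates exactly the structure the method exploits:
repeated cycles of one MS1 scan plus a sweep of fixed-width windows
(default 24 × 25 m/z from 400 Th, 40 cycles), co-fragmented peptides,
M/M+1/M+2 envelopes with averagine-style ratios (M+1/M ≈ mass/1800),
Gaussian elution (σ = 1.5 cycles), log-normal abundances, 5 ppm m/z
jitter, uniform noise peaks (100 per MS1, 150 per MS2 scan), and apex
cycles derived from the default retention predictor plus Gaussian noise
with σ = 3% of the gradient — informative but imperfect, like real RT
prediction. A configurable fraction of present peptides is
"MS1-suppressed": fragments appear, survey-scan signal does not.

What it does **not** model: chimeric structured noise, charge-envelope
overlap, profile peak shapes, intensity-dependent mass error, or dynamic
range anywhere near a real proteome. Passing tests on these runs
demonstrates correctness and calibration of the machinery, not detection
performance on real chromatography.

One evaluation subtlety: tryptic databases contain missed-cleavage
sub/super-peptides and modification variants that share most fragments
with a present peptide. Such "related" detections are genuinely supported
by the data but are neither true nor false at the peptide level, so the
empirical false-discovery proportion reported by `empirical_fdp` excludes
them from numerator and denominator — the same homology exclusion used in
entrapment benchmarks.

## Problem sizes and numerical conventions

The test suite and the acceptance script run everything at desk scale:
oracle checks on hundreds of random 20-peak spectra, null calibration over
20 simulated runs of 250-peptide databases with nothing present, and one
end-to-end acquisition with a 2000-peptide database, 300 peptides present
and 20% of those MS1-suppressed. Constants: proton 1.007276466 Da, water
18.0105646 Da, carbamidomethyl +57.02146 Da, oxidation +15.99491 Da,
standard monoisotopic residue masses. Ties in top-k retention break by
higher XCorr, then lexicographic peptide, then target before decoy, making
graph construction bit-deterministic; all stochastic stages (decoy
shuffling, fold assignment, simulation) are driven by explicit seeds.

## Known limitations

- The linear classifier is a faithful re-implementation of the rescoring
  *protocol*, not byte-identical to any particular Percolator release.
- XCorr omits flanking-peak credit and the exact p-value mode of some
  implementations; binning conventions are documented above.
- No protein inference, no quantification, mzML input only (vendor
  conversion is upstream), centroided data required.
- The retention-time predictor is intentionally simple; a file of external
  predictions (deep-learning or otherwise) can replace it via
  `FileRTPredictor`.
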