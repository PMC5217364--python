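# Methods

## Scope and model

`lfqpipe` quantifies proteins from label-free LC-MS/MS experiments using
MS1 elution-profile integration, and tests between-condition differences
with a resampling procedure. It deliberately stops short of running a
database search: its inputs are already-scored peptide-spectrum matches
(PSMs), an MS1 chromatogram per replicate, and the protein FASTA the
search used. Everything downstream — filtering, protein inference,
grouping, quantification, normalization and significance — is in scope.

The statistical model is intentionally minimal. No distributional form is
assumed for protein intensities; significance comes from a bounded-uniform
resampling null (below), and no multiple-testing correction is applied —
calls are made at a raw p ≤ α, which is how this class of workflow is
usually reported. Users who need FDR control across proteins should feed
the p-value column to their favorite correction.

## Identification filtering

* PSMs with E-value strictly greater than the threshold (default 0.05)
  are discarded; equality is retained.
* Proteins need ≥ 2 **distinct peptide sequences** (default). A protein
  matched by three spectra of one peptide is discarded. The rule is
  deliberately about sequences, not spectra: repeated sampling of one ion
  is weak evidence.
* Decoy handling is by accession prefix (`DECOY_` by default). The FDR is
  the ratio of decoy to target proteins passing identical filters,
  computed at the protein level because the filters themselves are
  protein-level; a PSM-level variant (`level="psm"`) counts supporting
  spectra instead.
* Coverage uses a mark-array: a boolean mask the length of the protein,
  marking every residue of every (possibly overlapping, possibly
  repeated) exact substring match of every peptide. Matching is exact and
  case-sensitive; isoleucine and leucine are *not* equated.

## Grouping

Proteins whose spectrum-id sets are *exactly equal* form a group — a
strict subset does not join (parsimony inference is explicitly out of
scope; the operation only removes evidence-identical redundancy, e.g.
orthologs in a multi-species database). If a group contains members of
the preferred species (default *Gossypium hirsutum*), all of them are
retained as isoforms; otherwise a single representative is kept. The
representative is the lexicographically smallest retained accession — a
convention chosen only to make output order-independent; no biological
meaning attaches to it. Groups and member lists are sorted, so the result
is invariant under permutation of the input.

## Quantification

* **Channel**: ion current within ± `halfwidth` (default 0.5 Th, i.e. a
  1-Da-wide window) of the PSM's precursor m/z, summed per scan.
* **Trace walk**: starting at the PSM's scan (always included), walk
  backward and forward, including each scan whose channel intensity is
  strictly above the replicate noise level; stop *excluding* the first
  scan at or below it, or after 250 scans per direction, or at the
  chromatogram edge. Distance is counted in scan indices, not retention
  time.
* **Noise level**: the 5th percentile (linear-interpolation convention) of
  all nonzero peak intensities of the replicate's chromatogram. This one
  scalar serves three roles: trace termination, substitution for missing
  proteins, and the lower bound of the resampling draw. It is a run-level
  constant; no per-scan noise series is estimated.
* **Deduplication**: PSMs of one protein in one replicate are clustered
  on ascending precursor m/z by chaining — a PSM joins the open class
  while within the tolerance (default 0.01 Th) of the previous m/z — and
  only the earliest-scan member of each class is integrated, so the same
  elution profile is never counted twice. Chaining (rather than a window
  around the first member) keeps class representatives more than one
  tolerance apart, which makes the operation idempotent.
* **Imputation**: a protein with no PSMs in a replicate — or whose summed
  trace area is zero, which can happen when the channel is empty at the
  identification's scan — gets the replicate's noise level and an entry
  in the imputation mask. Consequently every cell is strictly positive
  whenever the noise level is, and downstream ratios are always defined.
* Charge states are not reconciled; each PSM is quantified at its
  reported precursor m/z. Retention-time alignment, peak-shape fitting
  and isotope deconvolution are out of scope.

## Normalization and differential testing

* **Mode**: intensities are histogrammed on a log10 grid of width 0.1
  anchored at 0; the mode is 10^(center of the fullest bin), ties going to
  the lower bin. Binning is how a mode of continuous data is made
  well-defined; the width trades resolution against count stability. Each
  replicate is divided by its own mode, which cancels per-replicate gain
  factors exactly when they are powers of 10^0.1 and up to one bin
  otherwise.
* **Ratio**: mean(normalized A) / mean(normalized B).
* **Monte Carlo test**: each iteration draws one uniform value per
  replicate from [noise_min, intensity_max] and forms the random ratio of
  means. Counts of random ratios strictly above and strictly below the
  observed ratio (ties count as neither) give
  p = min(1, 2·(min(above, below)+1)/(N+1)): two-sided, with a +1 guard
  so p is never 0. The bounds are per protein — minimum replicate noise
  level to maximum observed cell of that protein's row — because the
  comparison is per-protein; a `bounds="global"` switch uses the bounds
  of the whole matrix instead. The default iteration count is 10^6 in the
  CLI; the test suite and acceptance script use 10^4, which resolves
  p-values to ~10^-4, ample for an α of 0.05.
* This null is deliberately conservative: random intensities spanning the
  full observed range produce ratio distributions far wider than real
  replicate noise, so unchanged proteins sit deep inside the null and the
  realized false-positive rate is well below α (the null-calibration
  check typically measures 0).
* Direction comes from the ratio alone; a ratio of exactly 1 cannot be
  directional and is classified unchanged (with a warning if nominally
  significant). Every protein in the matrix is tested; no
  detected-in-k-replicates filter is applied.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with defaults chosen as the study conditions of interest:

* two conditions × 3 replicates; protein abundances with configurable
  per-protein fold changes; lognormal replicate variability at 10% CV
  (unit-mean multipliers);
* random 20-letter protein sequences (150–300 residues), tryptic digestion
  after K/R with ≤ 2 missed cleavages and a 6–30-residue length filter,
  monoisotopic precursor m/z at charge 2 or 3 (standard proton-adduct
  convention), up to 5 quantified peptides per protein;
* Gaussian elution peaks (width 3–6 scans, apex away from the edges) whose
  apex is abundance × 20 000 counts — ~200× the noise floor at unit
  abundance, and ≥ 50× at the detection threshold of 5 000 counts;
* a uniform(50, 150) noise floor present in 50% of scans per channel
  (real survey scans are sparse; a floor in *every* scan would keep
  overlapping channels permanently above the noise level and run every
  trace to the extent limit), with sub-single-count signals dropped, as a
  detector would;
* target PSM E-values ~ Exponential(0.005) and decoy E-values
  ~ Exponential(10), so targets essentially always pass the 0.05 filter
  and each decoy row passes with probability 1 − e^(−0.005) ≈ 0.005; decoy
  matches are sparse (≤ 10 peptides, one random replicate each), like
  chance hits in a real decoy search;
* optional duplicate accessions sharing a source protein's spectra
  exactly, to exercise grouping;
* every random draw flows from a single top-level seed, and identical
  seeds reproduce byte-identical files.

What the generator does **not** emulate: retention-time drift between
replicates, chimeric/overlapping isotope envelopes, intensity-dependent
detection probability, charge-state envelopes, and modified peptides.
Passing tests therefore demonstrate the correctness and calibration of
the computation under clean chromatography, not robustness to those
instrument effects.

## Verification problem sizes

The oracle-equivalence sweeps use 500 randomized chromatograms (≤ 50
scans, ≤ 20 peaks/scan), 500 coverage instances and 200 grouping lists,
exact-match. Calibration uses 200 no-change proteins (matrix drawn
directly from the abundance model) at 10^4 iterations; recovery uses 50
five-fold proteins over a 150-protein unchanged background through the
full MS1 → trace → matrix → test path (the background keeps the
per-replicate mode anchored to unchanged proteins — a *global* fold
change is absorbed by mode normalization by design); FDR behavior uses
300 targets + 300 shuffled decoys. These sizes give stable statistics
while keeping a full verification run to a few seconds.

## Known limitations

* The mode estimator quantizes to 0.1 log10 units; two replicates whose
  true modes straddle a bin edge can normalize a shared factor of up to
  10^0.1 ≈ 1.26 into the ratios. Wider matrices (more proteins) make this
  progressively unlikely.
* The bounded-uniform null trades power for robustness; small true fold
  changes (≲ 2×) are often not callable at 3 + 3 replicates.
* Protein inference is evidence-identity grouping only; shared-peptide
  (razor) apportionment is not performed, so paralogs sharing *some*
  spectra are quantified independently, double-counting those traces.
* The MS1 reader accepts only the text MS1 dialect (S/I/H lines with
  m/z–intensity pairs); mzML input should be converted first.
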