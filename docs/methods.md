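# Methods

## Digest-product masses (`acylstall.chem`)

Analyte compositions are assembled by elemental-formula arithmetic:

    product = amino acid + adenosine (C10H13N5O4) − H2O + modification delta
              [+ HPO3 for Nuclease P1 digestion]

with modification deltas acetyl +C2H2O, formyl +CO, Fmoc +C15H10O2 on the
α-amino group.  The aminoacyl ester condensation loses one water; 2′- vs
3′-ester positional isomers are mass-identical and not distinguished.
Monoisotopic atomic masses: C 12.000000, H 1.0078250319, N 14.0030740052,
O 15.9949146221, P 30.97376151, S 31.97207069.  [M+H]⁺ uses the proton mass
1.0072765 Da (the electron stays behind), the standard MS convention; at the
2-decimal precision of reported m/z values the distinction from the H-atom
mass is invisible.  Values reported to two decimals are matched by
truncation (floor), the rounding dialect of the reference chromatography
software.  For the Glu-AMP / N-acetyl-Ser-AMP isobar the printed value
476.1057 corresponds to the *neutral* monoisotopic mass of the shared
formula C15H21N6O10P; the package reports both the neutral mass and the
[M+H]⁺ m/z (477.1130) and leaves the labeling convention to the caller.

Isobar grouping is the transitive closure of pairwise mass agreement within
a ppm tolerance (default 5 ppm) over the sorted mass list — deterministic
and adequate for the ≤ ~100-species lists this assay produces; borderline
chains merge, which is the conservative direction for assay design.

## LC/MS quantification (`acylstall.lcms`)

**Smoothing.** Savitzky–Golay, quartic, 31-point window by default (the
filter needs an odd window; 31 is the nearest odd width to the conventional
30-point setting).

**Peak model.** The exponentially modified Gaussian

    h(t) = A/(2τ) · exp(σ²/(2τ²) + (μ−t)/τ) · erfc((σ/τ + (μ−t)/σ)/√2)

integrates to A over the real line.  Evaluation is piecewise for numerical
stability: the erfcx form (a pure Gaussian factor) on the left flank/apex,
the direct exp·erfc form on the right tail where erfc → 2 and the
exponential decays.

**Fitting.** Nonlinear least squares (lmfit, Levenberg–Marquardt) over peak
parameters plus a constant-or-linear baseline.  Bounds: σ, τ ∈ [10⁻⁴, 5]
min; μ within the data window; A ≥ 0.  Initialisation derives from the
smoothed trace (highest local maxima; left peak = peak 1); because strongly
overlapped pairs can present a single maximum, several deterministic
starting points (symmetric splits of the dominant maximum) are tried and
the lowest-residual solution kept — the result is reproducible for a given
trace.  Two-peak fits constrain σ and τ to be shared across peaks by
default: the motivating use is the co-eluting Leu/Ile adenosine pair, a
pair of structural isomers with essentially identical chromatographic
shape, and without the constraint fits at separations near 1.5σ are weakly
identifiable.  Residuals are weighted by the reciprocal of the smoothed
signal (floored at 1% of its maximum), the maximum-likelihood weighting
when detector noise scales with intensity — the usual LC/MS regime and the
noise model of the synthetic generator.  Area standard errors come from the
least-squares covariance.  Degenerate inputs: a signal-free trace either
raises a fit error (no covariance) or returns an essentially-zero area
flagged as pinned at its bound; pinned shape parameters are reported in
`at_bounds`.

**Integration.** Trapezoidal area over a stated window, optionally above
the straight line through the window's endpoint intensities.  The area sd
is a noise-floor estimate: RMS residual of the raw trace to its smoothed
version in flanking windows (default 0.2 min — the reference integrator's
setting is unspecified; configurable) × √(n points) × Δt.

**Statistics.** RRF = S_Fmoc/S_Ac from an equimolar split-sample
calibration; acetylated fraction f = S_Ac/(S_Ac + S_Fmoc/RRF).  This
orientation is forced by the RRF definition together with the requirement
that an equimolar acetyl/Fmoc pool give f = 0.5; a calibration table using
the reciprocal convention is one flag away
(`rrf_orientation="acetyl_over_fmoc"`).  Uncertainties propagate to first
order (via the `uncertainties` package) treating inputs as independent —
conservative for ratios of separately measured areas; the delta-method sds
agree with 10⁶-draw Monte-Carlo within a few percent for input CVs ≤ 10%,
degrading gracefully as CVs grow and the ratio distributions skew.
Spike-in normalization divides all areas of a sample by its ¹⁵N-AMP
internal-standard area.

## Ribosome profiling (`acylstall.ribo`)

Footprints are summarised by the genomic position of their **3′ end**
(rightmost aligned base on +, leftmost on −), the better-defined boundary
of MNase-generated bacterial footprints; read lengths outside 15–40 nt are
discarded and "uniquely mapped" is approximated tool-agnostically as
primary alignments with MAPQ ≥ 10 (configurable).  Density = 3′-end counts
per position, strand-specific, normalised to reads per million uniquely
mapped footprints (RPM).

ORFs shorter than 170 bp, or with trimmed-region mean density below
1 RPM per codon, are discarded (retention requires both).  The first 15 and
last 7 codons are excluded from all means and scores because
initiation/termination-proximal density is systematically biased; the
per-ORF normaliser (and the density filter) use the trimmed region so those
biases cannot leak into the pause scores.  Pause score PS = density / ORF
trimmed-mean density; the trimmed-region mean of PS is exactly 1 per ORF.

**Offset calibration.** Terminating ribosomes hold the stop codon in the A
site, leaving a metagene peak a fixed distance downstream of the stop
codon's first nucleotide.  The stop-aligned metagene of ORF-mean-normalised
density is searched over candidate offsets (default −20…−6 nt); the peak
must exceed 2× the strongest non-adjacent competitor column — 3′-end
density is 3-nt phased, so the relevant null is "all in-frame columns
equally high", not a flat profile — otherwise calibration fails with an
instruction to pass `--offset` explicitly.  Ties resolve to the most-3′
offset.  The start-aligned metagene is retained as a diagnostic.  Default
offset when calibration is skipped: −11 nt, typical for 3′-aligned
bacterial footprints.

**MPS.** For a codon starting at transcript position c, footprints decoding
it in site S ∈ {A, P, E} have 3′ ends in [c + shift − offset, c + shift −
offset + 3) with shift 0/3/6 (the P- and E-site codons sit 3 and 6 nt
upstream of the A-site codon).  Per ORF, PS values over all such
nucleotides of all occurrences of a codon are averaged; these per-ORF means
are averaged unweighted across ORFs with ≥ 1 occurrence.  Windows must lie
fully inside the trimmed region: because 3′-end density is 3-nt phased,
partial windows at the trim boundaries would otherwise bias per-ORF means.
The amino-acid view pools codons by translation within each ORF before the
per-ORF average.  Cells with no contributing ORF are missing (NaN), never
zero.  Overlapping ORFs are scored independently from the shared track.  No
p-values are produced; MPS is a descriptive statistic.

**Decile profile.** Codons of each (full, untrimmed) ORF are split 5′→3′
into 10 contiguous bins (integer partition, earlier bins take the
remainder); footprint counts per bin plus a 0.5-read pseudocount are
normalised to fractions, and the per-bin geometric mean is taken across
ORFs.  The pseudocount keeps the geometric mean defined for empty bins with
minimal distortion.

Coordinates are 0-based half-open internally; GFF3 is read 1-based
inclusive, BED 0-based half-open; human-readable outputs are 1-based.

## Synthetic data (`acylstall.simulate`)

**Footprint libraries.** A single-contig toy genome carries non-overlapping
ORFs (ATG + body codons drawn from configurable usage weights + TAA) on
both strands with random intergenic spacers.  Defaults are the standard
study scale used throughout the tests: 100 ORFs × 200 codons, depth 10⁶
reads, uniform codon usage, offset −11, read lengths uniform on 24–32 nt,
log-normal expression weights across ORFs with CV 1.0 (so the density
filter has realistic work to do).  Reads are placed by sampling an ORF ∝
expression weight, a ribosome position ∝ per-codon dwell — multiplicative
stall factors apply when the codon occupies the A site; A-site positions
run from codon 1 (the start codon begins in the P site) through the stop
codon — and a 3′ end at (first A-site nucleotide − offset) with the length
drawn independently; the 3′ rule makes the downstream statistics
insensitive to read length by construction.  The stop codon receives a
dwell of 5.0 by default, modeling the termination pause that real
bacterial profiles show and that the stop-codon metagene calibration
requires; with it, simulated offsets in [−16, −8] are recovered exactly at
depths ≥ 2×10⁵.  Emitted SAM/BAM files are coordinate-sorted with
sequences taken from the genome.

What the generator does *not* model: sequence-dependent MNase bias,
sequencing errors, multi-mapping, rRNA/tRNA contamination, or P/E-site
stalls.  Passing tests therefore show that the pipeline's bookkeeping,
normalisation, calibration and ranking are correct under the stated
generative model — not that real libraries are free of those artifacts
(the common Ser/Gly profiling artifact, for instance, is outside the
model).

**LC/MS tables and traces.** Per amino acid, acetyl and Fmoc areas are
drawn as molar amount × response factor × log-normal multiplicative noise
of the stated CV (positivity plus signal-proportional scatter, the typical
area-measurement behaviour); the acetyl response is 1 by convention and the
Fmoc response is RRF× it.  Default noise CV 5% with 3 replicate samples,
mirroring triplicate experiments.  The RRF calibration is itself simulated
from an equimolar split sample with the same noise, and the exact-truth RRF
table is exposed separately for recovery tests against known response
factors.  Chromatogram rendering sums EMG peaks (σ 0.05 min, τ 0.12 min, a
moderately tailing ~3.5 s-wide peak on a 0.002 min grid) over a linear
baseline with multiplicative noise; a co-eluting pair sharing one trace
exercises the deconvolution path.  At separation 2σ the two-peak fit
recovers areas to ~1% under 1% noise; at 1.5σ the small peak of a 4:1 pair
has a Cramér–Rao lower bound of ~6% relative sd — separations below ~2σ
are intrinsically hard at this noise level no matter the estimator, and
results there should be read with their reported standard errors.

All randomness flows from one integer seed per spec through NumPy
generators; identical specs reproduce identical outputs byte for byte.

## Problem sizes

Tests and the acceptance script run the ribosome pipeline at the full
default scale (10⁶ reads; seconds on one core), calibration-recovery checks
at 2×10⁵ reads, Monte-Carlo uncertainty checks at 10⁶ draws, and
chromatogram fits on ~3×10³-point traces.
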