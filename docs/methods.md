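# Methods

This note records the model, the estimators, the numerical choices and the
known limitations of `dsbseq`, in the order data flows through the package.

## Synthetic reference

The reference emulates a two-locus inter-chromosomal recombination assay:

* **Recipient** (`chrIII`, 60 kb): a 24-nt HO recognition core at
  coordinate 35 000 (the cut coordinate is the core's centre), EcoRI sites
  engineered at −2500 and +4300 nt from the cut, and a resection-blocking
  element (Ty1-LTR analogue) annotated 32 kb to the left. The engineered
  EcoRI geometry makes the uncut locus fragment 6.8 kb and the left cut
  product 2.5 kb, the band sizes by which HO cutting is scored on a blot.
* **Donor** (`chrV`, 40 kb): a 1300-nt insert — two 638-nt homology arms
  copied from the recipient around a 24-nt uncleavable HO-inc core (one
  base changed at core index 11). The arms carry 23 single-nucleotide
  polymorphisms: 12 left / 11 right of the cut at 55-nt spacing, starting
  ±30 nt from the cut. Three donor alleles complete EcoRI sites
  (offsets −415, −85, +305) whose recipient context `GACTTC` does not cut.
* **Background** (`chrVIII`, 15 kb): an uninvolved chromosome for
  background-rate estimation, plus a 20-kb control region on the donor
  chromosome (15 000–35 000), clear of the insert.

Background sequence is i.i.d. uniform over {A,C,G,T} with every spurious
EcoRI motif scrubbed genome-wide (third base mutated, iterated to a fixed
point), so restriction maps contain exactly the designed sites and random
75-mers are unique with overwhelming probability. Arms are copied verbatim
from the recipient before substituting alleles, which guarantees the
*flanking-context invariant*: donor and recipient differ only at annotated
positions, so a 0-mismatch read carrying a donor allele cannot align to the
recipient chromosome and vice versa.

**Why 638-nt arms and 55-nt spacing.** The assay this emulates is described
with a 1.3-kb donor insert, "0.7-kb" arms, and 23 polymorphisms at "~60-nt"
spacing — constraints that cannot all hold exactly (23 sites at 60-nt
spacing span 1320 nt > 1300). We pin the exact quantities (1300-nt insert,
23 sites, 12/11 split) and let the approximate ones absorb the slack:
638 + 24 + 638 = 1300, and 12 left sites at 55-nt spacing fit a 638-nt arm
where 60-nt spacing would not. Both are configurable in `GenomeConfig`.

Coordinates are 0-based half-open everywhere in memory; only SAM/BedGraph
writers emit the 1-based forms their standards require.

## Population model

Per-cell latent variables are drawn once from the master seed (cut Bernoulli,
per-side gamma velocities, repair Bernoulli and normal repair time,
exponential tract half-lengths, degradation Bernoulli), so states queried at
different times describe one coherent trajectory and adding time points
never perturbs earlier draws.

* **Cutting**: probability `cut_efficiency` (default 0.98 — cutting is
  essentially complete within the first hour in this assay class).
* **Resection**: extent = v·(t − delay) per side, v ~ Gamma(shape 4,
  mean 4 kb/h). The gamma across cells produces the smooth sigmoid coverage
  decay of real profiles with two parameters; the deterministic limit
  (`velocity_shape=None`) gives sharp fronts for parameter-recovery tests.
  Left extents are capped at the blocking element, right extents at the
  chromosome end. The in-vivo velocity distribution is not known at
  per-cell resolution; these defaults are model choices that put the
  half-coverage front in the observed few-kb/h range.
* **Repair**: a fraction `repair_fraction` (default 0.8) repairs at
  T ~ Normal(6 h, 1 h). With `stop_resection_on_repair` (wild-type
  behaviour) resection halts at T; disabling it emulates a
  phosphatase-deficient mutant in which resection continues throughout.
  `cdc14_like_params()` bundles that scenario (26% repair, no stop, slower
  re-synthesis, partial ssDNA degradation).
* **Conversion tract**: boundaries gc_left ≤ −12 ≤ +12 ≤ gc_right; the
  12-nt minimum spans the HO core, which repair always replaces with the
  HO-inc sequence (this is what prevents re-cutting). Half-lengths beyond
  the core are exponential (means 400 nt left / 150 nt right), giving the
  left-biased conversion profile characteristic of the assay. Boundaries
  are continuous coordinates; quantisation to polymorphism positions
  happens only when substituting genotypes into reads.
* **Re-synthesis**: duplex restored from the break outward at
  `resynthesis_velocity` after T, so coverage near the break recovers
  before distal positions — matching the proximal-first recovery seen in
  blots and profiles.
* **Library**: fragments ~ Normal(300, 50) sampled uniformly over
  (cell, duplex position); a fragment never spans single-stranded DNA, and
  an unrepaired cut separates the two duplex pieces. Reads are error-free
  (under a 0-mismatch alignment contract, sequencing errors would only
  discard reads, so modelling them adds nothing but a depth rescaling).
  Mate 2 is reverse-complemented; qualities are constant Phred 40.

`expected_relative_coverage` — the fraction of cells in which a position is
double-stranded — is the analytic oracle for every T0-normalised profile.
The qPCR model scores an amplicon 1 if fully duplex, 0.5 if it overlaps
ssDNA (one template strand survives: the textbook 50% expectation), and 0
if that ssDNA is degraded; degradation can therefore only lower the signal.

## Mapping

An exact-match hash index over all length-75 reference substrings (forward
strand stored; reads looked up as themselves and as reverse complements)
implements end-to-end 0-mismatch alignment. Reads with non-ACGT symbols or
the wrong length never map (but are counted in totals). For coverage,
multi-mapped reads are dropped entirely rather than assigned one arbitrary
locus: deterministic, and identical on a repeat-free reference. Pairs are
*discordant* when both mates map uniquely to different chromosomes;
concordant when same-chromosome, opposite strands, insert within bounds.

## Coverage normalisation

RPGC scaling divides by the genome-wide mean; the T0 mask removes positions
whose scaled undamaged coverage is below 0.2 (per-base, configurable) from
every sample; ratios are computed per position and then averaged per
100-nt bin (masking is per-position, so ratio-then-bin is the faithful
order; the alternative differs at second order). The bin grid is anchored
at the cut so no bin mixes the two sides. Section profiles implement
C_N = (CIII_Tx/CIII_T0)/(CV_Tx/CV_T0) over 2-kb sections with the control
region on the donor chromosome; the control region normalises to 1 by
construction.

**Control correction of ratio profiles.** On this compact (115-kb)
reference, turning ~25% of the genome single-stranded inflates every
unaffected position under RPGC (the same read mass spreads over less
duplex). `break_profiles` therefore divides ratio profiles by the control
region's Tx/T0 ratio — the C_N denominator applied at 100-nt resolution —
restoring an absolute duplex-fraction scale. On a real genome, where the
broken chromosome is a small fraction of the total, this factor is ~1 and
plain T0 normalisation behaves identically.

## Resection and synthesis estimators

The resection front at level L is the *outermost* upward crossing of the
(3-bin-median-smoothed) profile scanning outward from the cut, linearly
interpolated between bin centres; ties break toward the break. Smoothing
suppresses spurious crossings from binomial noise; width 1 disables it.
Estimates limited by the blocking element or a chromosome end are returned
censored at that boundary and excluded from rate regressions, not imputed.
The long-range rate is the OLS slope of distance vs time over 1–4 h
(exactly Δs/Δt for two points). Maximum extent scans the same-sample scaled
coverage for 0.9 × the recipient chromosome's own unmasked mean — so
samples enriched in ssDNA have a lower effective threshold, which is the
intended behaviour of that estimator. Synthesis series read the bin at
x = 500 / 15 000 nt; S is the trend-line slope over 4–10 h, and the
initiation rate v = 0.5 kb / Δt with Δt = 0.5/m from the same line.

Edge behaviour worth knowing: because fragments cannot straddle
single-stranded DNA, positions within ~one insert of a cell's resection
front are depleted slightly beyond the duplex-fraction oracle. With
dispersed per-cell fronts this is second order; with deterministic
velocities it shifts every crossing by a constant ≈ +read length, which
cancels exactly in the rate regression.

## Gene-conversion quantification

With each locus normalised by its own T0 coverage and the control factor,
the donor-site ratio is Cd′ = 1 + q·r (q = probability a repaired cell's
tract covers the site, r = repaired fraction) and the recipient-site ratio
is (1−q)·r plus the uncut fraction — unrepaired cells hold the locus
single-stranded. The descriptive *donor share* Cd′/(Cd′+Cr′) is reported
per site (0.5 at baseline), but it is **not** invariant to r: recipient
depletion inflates it even with q = 0. The corrected estimator is instead
the donor excess divided by the correction factor,

    corrected q̂ = (Cd′ − 1) / F,   F = max over t>0 of the 0.5-kb recovery,

which equals q·r/r = q for any repair fraction. F is measured per side
(left sites with the left recovery) and the undamaged reference sample is
excluded from the maximum. Site coverage is the mean over a 75-nt window
centred on the site, since any overlapping 0-mismatch read is
allele-informative.

Known bias: a 75-nt read is a haplotype, so it migrates to the donor locus
only if *every* polymorphism it covers is converted. Near the break, where
short tracts end between adjacent sites, q̂ therefore underestimates the
single-site conversion probability by roughly the joint-conversion deficit
of the read window (≈10% of q for exponential tracts with 100–150-nt
scales, larger immediately at the break). This is a property of any
0-mismatch coverage readout, not of the simulator. The tract boundaries
themselves are better taken from discordant pairs, which are insensitive
to this.

## Discordant-pair boundary mapping

A fragment straddling a tract boundary yields one donor-haplotype mate
(maps only to the donor chromosome) and one recipient-haplotype mate:
a unique×unique inter-chromosomal pair bracketing the boundary. Pair
coordinates use each mate's leftmost aligned base (a midpoint convention is
available). Quadrants around (HO, HO-inc) separate left-side from
right-side conversion events and left from right boundaries; on-axis pairs
go right/top by the ≥ convention. Donor-mate coordinates are mapped into a
break-centred frame through the homology arms; each boundary is estimated
as the linearly interpolated sign change of (recipient − donor) smoothed
coverage at which both tracks are highest — the peak intersection. Pairs
whose donor mate falls outside the arms are excluded from the frame and
counted. The A–E region bands are defined only graphically in the assay's
literature, so `default_regions` derives them from the estimated peak
intersections (band edges one read length outside each boundary, a ±150-nt
proximal band around the cut) and any explicit (name, lo, hi) list
overrides them. The background rate counts recipient × uninvolved-
chromosome pairs per read analysed; error-free simulations give exactly 0.

## Problem sizes and determinism

Default analyses run on the 115-kb reference with 1000–2000 cells at
30–60× coverage; a full 11-time-point pipeline completes in well under two
minutes on one CPU, and the whole test suite in a couple of minutes. All
randomness flows from explicit integer seeds through per-purpose
`SeedSequence` substreams; identical configurations and seeds reproduce
byte-identical FASTA/FASTQ/report output.

## Limitations

* The simulator models neither checkpoint signalling, D-loop intermediates,
  chromatin, replication, sequencing error, GC-content bias nor
  fragment-length bias; passing tests demonstrate estimator correctness
  under the stated generative model, not robustness to those real-data
  artefacts (the T0 normalisation is, however, exactly the mechanism real
  analyses use to cancel position-specific library bias).
* Resection velocity and tract-length distributions are plausible model
  choices, not per-cell measurements.
* Alignment is strictly ungapped and mismatch-free by design; indel-bearing
  or error-bearing reads are simply lost, as in the assay's own contract.
* The A–E band construction is an explicit interpretation of a graphical
  definition and should be overridden when comparing against an externally defined
  partition.
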