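# Methods

## The screening problem

High-density peptide arrays display every combinatorial peptide over a
reduced amino-acid alphabet as replicated spots, incubate the chip with a
fluorescently labelled 12-mer RNA homo-oligonucleotide (poly-A, -U, -G or
-C), and read out per-spot fluorescence: brighter spots mean more bound
RNA. `protopep` implements the full downstream analysis of such screens —
from the genetic-code model that motivates the library alphabets, through
library design and photometric-table handling, to the fragment-level
interaction statistic — together with a synthetic-data generator so that
the whole pipeline is testable end to end without the experimental data.

## Protocode model and combinatorial fusion

The library alphabets come from a partition of the canonical amino acids
into four *protocodes*: dominant and recessive codes over the A/U base
pair (members K,F,N,I,Y and E,L,D,V,Q,H) and over the G/C base pair
(G,P,A,R and S,T,C,R), with Met and Trp excluded as late entrants.
Within each base pair the dominant and recessive codes compete for the
same eight two-base codons. Fusion into the standard genetic code (SGC)
is modelled with transition mutations (A↔G, U↔C): dominant members keep
their codons and gain the third-position transition mutants; recessive
members are re-assigned to free codons via first-position or
first-and-third-position transitions, chosen so that the reverse
complementarity of partner codons within a recessive code survives
(both partners take the first-and-third mutants of a complementary codon
pair). Placeholders X1/X1\*/X2 are deleted members: removing X1 turns
UAA/UAG into stops, Leu inherits X1\*'s UUA (and its mutant UUG), and
X2's mutants become the UGA stop and the Trp codon.

The complete codon table of the four protocodes is not printed anywhere
as text, so the bundled configuration (`data/protocodes.yaml`) is a
reconstruction from the documented anchor assignments (F at UUU, Y at
UAU, P at CCC with Ser competing, X1/X1\* at UAA/UUA, the "traveling"
Ser/Arg at GGC/GGG, X2 adjacent to Arg at CGG). The reconstruction is
strongly constrained: under the fusion rules above it tiles all 64 SGC
codons exactly once (stops and late entrants included), every dominant
fused set is a subset of the corresponding SGC codon set, and every
recessive member recovers precisely its SGC codons. A third-position
mutant that lands on a late-entrant codon (Ile's AUA → AUG) is recorded
as *ceded* rather than fused, mirroring the late entry of Met.

## The interaction score

For a contiguous peptide fragment m, I_m is the set of fluorescence
signals of all spots whose peptide contains m (a peptide counts once no
matter how often m occurs in it; an occurrence-weighted mode exists but
is not the default). The interaction score

    R_m = mean(I_m) / sd(I_m)

uses the sample (ddof = 1) standard deviation. R_m is scale-free:
multiplying all intensities by c > 0 changes nothing, while additive
offsets do change it. It rewards fragments whose carriers light up
*consistently* — a fragment carried by uniformly bright peptides
outranks one carried by a heterogeneous mixture, even at equal mean.

Fragments with fewer than `min_support` signals (default 3) or zero
standard deviation are reported separately and never ranked; the ratio
is undefined or degenerate for them. Scoring defaults to spot-level signals
(all replicate copies enter I_m); per-peptide aggregated signals
(default aggregator: median across copies) are available. Ranking ties
are broken longer-fragment-first, then lexicographically, so all tables
are deterministic.

Signature columns are cumulative: column n ranks all fragments of
lengths 3…n. Comparing consecutive columns shows the displacement of
short signatures by longer ones; `displacement_analysis` reports the
retained/displaced/entering fragments per transition and
`composition_trend` tracks residue content of the top of each column.

## Property scales

Sum properties are additive over residues with terminal adjustments.
Defaults: side-chain charge at pH 7.4 (K,R = +1; D,E = −1; H = 0;
termini = 0 because the peptides are N-acetylated and surface-linked),
Kyte–Doolittle hydrophobicity, Pace–Scholtz helix propensity (kcal/mol)
and average residue masses plus the acetyl mass. Published
property-vs-intensity analyses of these screens do not tabulate their
exact scales, so the scales are pluggable data files; the defaults are
the field-standard choices (for the AU alphabets the Pace–Scholtz sums of 6-mers centre
near 3 kcal/mol, consistent with the reported convergence).

## Synthetic screens

The generator is multiplicative on intensity (log-additive):

    I = baseline_channel × library_multiplier × Π effect_terms
        × exp(β · property) × exp(N(0, σ²))

Fluorescence is positive and right-skewed, which lognormal noise
captures; the default σ = 0.3 reproduces an sd/mean ratio of ≈ 0.3–0.45,
the magnitude seen in real channel summaries. Planted motif effects are
per-presence or per-occurrence (overlapping matches, optional saturation
cap). Everything is driven by one `numpy` Generator seed; the σ = 0 case
is exactly reproducible from the config in closed form
(`expected_intensity`).

A consequence of the purely multiplicative model worth stating: because
R_m is scale-free, a *homogeneous* multiplicative boost does not by
itself raise a fragment's R — what distinguishes a planted fragment is
that its carrier set is homogeneous while every other fragment's signal
set becomes a mixture of boosted and un-boosted peptides, which inflates
its sd and depresses its R. Per-occurrence effects without saturation
therefore *lower* the planted motif's own R (its carriers span several
multiplier levels). The presets exploit this deliberately:

* **GC preset** — full dominant (GPAR) and recessive (STCR) 7-mer
  sublibraries, 2 copies; baselines C = 1250, G = 560 (C ≈ 2.2 × G);
  dominant sublibrary × 2.5 in C and × 1.2 in G so the dominant/recessive
  intensity ranges separate; per-presence effects PPP × 4.0,
  PPPP × 1.15, PPPPP × 1.1 (nothing beyond run length 5, echoing the
  exhaustion of polyprolines at the 5-mer level — the run-length extras
  are kept small so the PPP carrier set stays near-homogeneous), and a
  × 6 bonus for the PPPAPPP context. The bonus size comes from a power
  argument: with σ = 0.3 and 2 copies the aggregated log-intensity gap
  between PPPAPPP (× 24 total) and the strongest competitor (× 5.06)
  is ≈ 1.6 ≈ 5 sd of the comparison noise, so the scan argmax is
  recoverable against all 21 variants in essentially every replicate.
* **AU preset** — dominant (KFNIY, 5⁶) and recessive (ELDVQH, 6⁶) 6-mer
  sublibraries subsampled to 23,403 peptides (the synthesized-library
  scale; how the real subset was chosen is unknown, so a uniform seeded
  subsample stands in), 3 copies; baselines A = 1150, U = 60 (A ≫ U);
  saturating per-occurrence effects F × 1.6 and Y × 1.5 (cap 2), so
  fragments fixing two F and two Y pin the peptide multiplier and become
  the homogeneous, top-ranked signatures — F/Y content then grows with
  signature length, as observed.

What the generator does **not** emulate: spatial artifacts, washing and
dye chemistry (the randomized layout exists precisely to dodge spatial
effects), background structure, and any fit to the deposited data — the
preset numbers are order-of-magnitude emulations of the published
channel hierarchies. Passing recovery tests therefore show that the
pipeline detects planted multiplicative signatures under realistic noise
magnitudes, not that the real screens contain such signatures.

## Numerical and design choices

* Sample (n−1) standard deviation everywhere; fragment supports can be
  small, so the estimator choice is material.
* No background subtraction by default (an optional
  foreground − background mode exists, clipped at zero).
* Intensity rows whose spot id is not in the manifest are errors above a
  tolerance fraction (default 0); manifest spots lacking intensities are
  listed as missing but never fatal.
* Substitution-scan matrices leave missing variants as NaN (never zero)
  and resolve argmax ties position-major, then substitute order.
* Library enumeration is lexicographic; layouts, subsamples and
  simulations are seeded `numpy` Generators, so every artifact is
  byte-reproducible from its run manifest.

## Problem sizes in the test suite

The recovery checks run 20 seeded replicates of the GC screen restricted
to the cytosine channel (65,536 spots each, ~1.5 s per replicate); the
brute-force oracle cross-check uses a 250-peptide subsample, where the
naive double loop is exact and fast. The composition-trend check gates
fragments at 30 supporting signals: longer fragments in a subsampled
6-mer library have single-digit peptide supports, where R estimates are
noise-dominated and per-column rank composition is not informative —
this is a small-sample property of the statistic, documented here rather
than hidden.

## Known limitations

* The protocode codon table is a constrained reconstruction (see above);
  alternative placements of the placeholders cannot be excluded, only
  disfavoured by the tiling consistency.
* R_m is a descriptive ranking statistic; no multiple-testing
  calibration is attempted, and cross-channel normalization is out of
  scope.
* The published unique-fragment counts per length (e.g. 135 unique
  3-mers for the AU-dominant library) exceed the alphabet-theoretic
  maxima of pure substring enumeration (5³ = 125) and are not
  reproducible by this implementation; the enumeration behind them is
  not reconstructible and is not asserted.
* The real screens' channel statistics and the 23,403-peptide library
  composition require the deposited data
  (doi:10.5281/zenodo.7594469); they are covered by optional
  integration tests that run only when a local copy is present.
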