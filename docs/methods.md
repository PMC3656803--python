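# Methods

## The cross and its data model

The package analyses intraspecific backcross (N2) panels segregating a
fully penetrant recessive mutation: F1 females heterozygous for the
mutation (founder B = mutant strain, founder A = mapping strain) are bred
to homozygous mutant sires. The sire's contribution is constant, so the
only informative datum per animal and marker is the founder origin of the
allele transmitted by the dam, coded `A`/`B` (`NA` missing). Phenotype is
binary (`mutant`/`wildtype`). With penetrance 1 and phenocopy rate 0 the
phenotype is a deterministic readout of the trait-locus origin; both rates
are configurable on `CrossDesign` for sensitivity work, but every
localization step assumes full penetrance and *flags* violations rather
than modelling them.

## Map functions

Genetic distance d (stored in cM, converted to Morgans internally) maps to
recombination fraction r by Haldane, r = (1 − e^(−2d))/2, or Kosambi,
r = tanh(2d)/2, with exact closed-form inverses (round-trip error < 1e-9
cM over [0, 200] cM). Haldane is the default because the simulator places
crossovers independently per marker interval (no interference), making
Haldane the internally consistent choice; Kosambi is offered for users
converting distances from interference-aware maps. The source of the cM
coordinates a user supplies is their responsibility — public mouse map
positions do not declare a map function, so none is inferred from them.

## Simulator

One gamete per animal per chromosome: the first marker's origin is
Bernoulli(½) and each adjacent interval switches origin independently with
probability r(gap). The trait locus is carried through the same chain as a
pseudo-marker inserted in map order, so trait–marker associations are
exactly those the map implies. A trait chromosome absent from the map
models a completely unlinked trait (origin Bernoulli(½) independent of all
markers). Genotyping error is a symmetric origin flip applied before
missing-data masking; both default to 0 (no per-marker error or missing
rates are assumed for the emulated study design). Every stochastic entry
point takes an explicit seed; equal inputs give byte-identical panels.

Study-sized fixtures mirror the emulated mapping campaign: a 103-animal
panel typed for 93 microsatellites on 19 autosomes at 16 cM average
spacing; a 374-animal panel on proximal chromosome 2 with five
microsatellites whose central gap is 11 cM / 11.66 Mb and four secondary
SNPs inside it, the SNP1–SNP2 pair spanning 0.55 Mb around the trait locus
at 9.0 cM; and two complementation-cross tables (19 offspring all wild
type with 11 carriers/8 noncarriers; 22 offspring with 11 mutant carriers
and 11 wild-type noncarriers). The SNP genetic positions are not dictated
by the emulated study (which reports only physical positions); they are
placed 3 cM on either side of the trait locus so that, at n = 374, both
trait-adjacent gaps are expected to harbour ≈10 crossovers and the
bracketing SNP pair is identifiable in essentially every simulated panel —
a deliberate fixture property, chosen by power analysis, that the hard
refinement invariant relies on. Genetic and physical coordinates are
intentionally non-proportional (recombination-rate variation is the norm).

What the generator does **not** emulate: crossover interference,
sex-specific recombination, X-linkage, litter structure, segregation-
distorting viability effects, and locus-specific genotyping artefacts.
Tests passing on simulated panels therefore validate the inference logic
under the stated meiosis model, not robustness to those real-data features.

## Two-stage scan

Stage 1 classifies each typed meiosis of the first `n_initial` animals
(default 44; the subset is the stable panel prefix, a deterministic choice)
as parental or recombinant and tests 1:1 with χ² = (a−b)²/n, df 1, no
continuity correction — the uncorrected statistic is the one whose values
match classical reports — and no multiple-testing adjustment (per-marker
thresholds 0.05/0.01 are applied as-is, as is conventional for such scans).
A marker expands to the full panel iff stage-1 P < 0.1 *with* a parental
surplus; recombinant-surplus markers, however extreme, are never promoted
or called linked. Missing genotypes are excluded pairwise per marker.
Markers with zero informative meioses are reported flagged with P = 1.

Calibration note: at n = 103 the statistic is discrete; the exact
parental-side null rejection rate at the 0.05 threshold is
P(Bin(103, ½) ≥ 62) = 0.0241, not 0.025 exactly. The calibration test
checks the empirical rate against this exact binomial value, and checks
analytically that it sits within 0.0015 of the nominal 2.5%. The
calibration runs the scan single-stage (initial subset = whole panel)
because it characterizes the per-marker test itself; the two-stage
procedure's conditional stage-2 rate is a different (smaller) quantity.

## Localization by constraint intersection

Under full penetrance each animal's phenotype fixes the required
trait-locus origin (mutant → B, wild type → A). Its admissible region is
the union, over maximal runs of required-origin typed markers, of open
intervals reaching from the nearest opposite-origin marker on the left to
the nearest on the right (chromosome ends — position 0 and last marker +
10 cM margin — close terminal runs). Animals typed at a subset of markers
contribute constraints from that subset only; animals with *no*
required-origin marker are contradictory under the model and are excluded
with a warning.

The interval is **not** the naive intersection of all admissible regions:
a genuine double crossover bracketing the locus between typed markers
(probability ≈ r_left·r_right per meiosis, ~0.2% per animal at the fixture
geometry, so ~1 animal per 374-member panel) makes that intersection empty
or wrong. Instead the package returns the longest connected component of
the positions consistent with the **largest number** of animals
(consensus intersection), excluding with a warning the animals whose
admissible region misses it — precisely the double-crossover animals. Two
max-consistency components meeting at a marker position merge only if that
point itself is maximally consistent (segments are open at markers: a
locus exactly at a marker must co-segregate with it). A
no-consistent-interval error is raised when fewer than half the
constrained animals support the consensus, which signals model violation
rather than meiotic noise. With noiseless simulated data this rule makes
the true locus position lie strictly inside the returned interval in every
run — the suite asserts 100/100 — while remaining well-defined on panels
with genotyping error.

Flanking markers are the nearest typed markers bounding the component
(terminal markers with an `unbounded` flag when no recombinant closes a
side). The interval's genetic length is the raw recombinant fraction
between the flanks × 100 with SE 100·√(p̂(1−p̂)/n): it estimates the
recombinant fraction, not the map-function-corrected distance (the two
differ by < 1 cM at these scales; the uncorrected form is what classical
interval reports quote). Physical span comes from the flanking markers' bp
positions, reported in Mb to two decimals.

## Refinement with secondary markers

Recombinants between the flanks (origins differing at both typed flanking
markers) are typed for markers inside the interval. Each then carries
exactly one visible breakpoint in the ordered flank+SNP ladder; animals
with more than one origin switch (double crossovers) or missing secondary
calls are excluded with warnings. Breakpoints are assigned to
adjacent-marker gaps (per-gap crossover counts are reported; their total
equals the retained recombinants), and the same consensus constraint
intersection — clipped to the current interval — returns the refined
bracketing pair. The refined genetic length divides the locus-separating
crossover count by the *panel* size the recombinants were drawn from
(`n_total`), not the subpanel size.

## Candidate genes

Gene coordinates are 1-based inclusive internally; the BED reader converts
from 0-based half-open (round-trip tested). A gene is a candidate if any
base overlaps the open interval strictly between the flanking marker
positions — genes merely abutting a flank are excluded. Strand is carried
but ignored. Tissue filtering is an exact set-membership test on flags
supplied in an auxiliary TSV; no live annotation service is queried, and
the built-in 12-gene table is synthetic (ten genes in the demo span, one
skin-flagged).

## Complementation verdicts

Failure to complement predicts carrier → mutant and noncarrier → wild
type; complementation predicts all offspring wild type. The verdict is
`complement` when all offspring are wild type, `fail_to_complement` when
concordance with the failure prediction reaches the threshold (default
1.0 — a perfect pattern, as classical crosses are read qualitatively;
lower it for penetrance-tolerant reanalysis), and `inconclusive` otherwise,
including single-class tables, which cannot discriminate the hypotheses.
This quantitative rule is the package's own formalization of a judgement
usually made by inspection. The carrier:noncarrier ratio is χ²-tested
against 1:1 as a cross-quality check; sex is recorded but unused.

## Numerical and design choices

- All probability math in float64; interval arithmetic uses an 1e-9 cM
  tolerance for endpoint identity; component ties break to the longest,
  then leftmost.
- Chromosome-end margin: 10 cM beyond the last marker (also the allowed
  trait-position extrapolation in `CrossDesign` validation).
- Markers at identical cM positions are rejected (strictly increasing map);
  co-segregation of arbitrarily close markers is still simulable since
  r → 0 continuously.
- Problem sizes in the test suite (100-seed invariants, 200 oracle panels,
  2,000 calibration panels, 20,000 gametes, 500-panel estimator check)
  were chosen to give 3σ-level statistical resolution on each checked rate.
- Stage-1 subset choice, the uncorrected χ², the open-interval endpoint
  rule, and the raw-fraction length estimator are deliberate, documented
  conventions; alternatives (random stage-1 subsets, Yates correction,
  closed endpoints, map-function-corrected lengths) change results in ways
  the tests would detect.

## Known limitations

- Localization assumes full penetrance; penetrance < 1 or phenocopies make
  exclusions frequent and the consensus rule's guarantees no longer hold.
- The consensus intersection tolerates isolated double crossovers but not
  systematic genotyping error; errors are flagged, never integrated over.
- No likelihood-based multipoint mapping, LOD scores, or permutation
  thresholds — the scan is a per-marker χ² by design.
- Intercross (F2) designs, multigeneration pedigrees, and X-linkage are
  out of scope; reciprocal-cross X-versus-autosome reasoning is a study
  design question, not a computation this package performs.
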