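# bxmap

Positional mapping of recessive mutations in mouse backcross (N2) panels:
linkage detection by segregation-distortion scanning, locus localization by
recombinant-haplotype constraint intersection, interval refinement with
secondary markers, candidate-gene filtering, and complementation-cross
adjudication.

## Who it is for

Mouse geneticists mapping a spontaneous, fully penetrant recessive mutation
the classical way: cross the mutant strain to a mapping strain, backcross
F1 heterozygous females to homozygous mutant sires, and type the N2
offspring for polymorphic markers whose founder-strain origin reveals the
haplotype each dam transmitted. The package also serves as a teaching and
simulation tool — its generator produces panels with the exact statistical
structure such crosses assume, so every inference step can be validated
against a known truth.

## The model

In an N2 panel each offspring inherits one allele per locus from the F1
dam, of founder origin A (mapping strain) or B (mutant strain). Under full
penetrance the phenotype reveals the trait-locus origin: mutants carry B,
wild types carry A. For a marker at recombination fraction *r* from the
trait locus, a typed meiosis is *parental* (marker origin matches the
phenotype-predicted origin) with probability 1 − *r*, so linkage appears as
segregation distortion. Per marker the package tests the 1:1
parental:recombinant expectation with the two-cell Pearson statistic

    χ² = (n_par − n_rec)² / n_typed,  df = 1  (no continuity correction),

in a two-stage design: an initial subset (default 44 animals) is typed
everywhere, and only markers with P < 0.1 *and* a parental surplus are
typed on the whole panel.

Localization intersects per-animal admissibility constraints: each animal
confines the locus to the maximal runs of required-origin markers, extended
to (but excluding) the nearest opposite-origin marker — the "locus must lie
below X but above Y" logic of recombinant mutants. The interval's genetic
length is the raw recombinant fraction between the flanking markers × 100
(cM) with a binomial SE. Genetic ↔ physical distance conversion uses the
Haldane map function r = (1 − e^(−2d))/2 by default (Kosambi optional).

Finally, candidate genes are the annotations overlapping the interval's
open physical span, optionally filtered by a tissue-expression flag, and
candidate identity is tested by complementation crosses (engineered
null/+ × mutant/mutant): carrier→mutant / noncarrier→wild-type concordance
means failure to complement, i.e. allelism.

## Worked example

```sh
$ bxmap demo --seed 1 -o demo_out
localized between M2.3 and M2.4 (10.43 cM); refined to SNP1-SNP2 (0.55 Mb); 10 candidate genes, 1 tissue-expressed
```

This simulates a 103-member genome scan and a 374-member fine-mapping
panel with a trait locus at 9.0 cM on chromosome 2. The scan flags the
proximal chromosome-2 markers; the fine panel localizes the locus between
microsatellites M2.3 and M2.4 (estimated length 10.43 cM here — the
recombinant fraction among 374 meioses across the 11 cM gap), secondary SNP
typing of the recombinants refines it to the 0.55 Mb SNP1–SNP2 window, and
10 of the synthetic annotation's genes fall in that window, exactly one
flagged as skin-expressed. `demo_out/` contains the scan table, haplotype
classes, interval JSONs, candidate table, and complementation outcomes.

The same statistics are available programmatically:

```python
>>> import bxmap
>>> bxmap.chi2_gof_1to1(82, 21)     # strongest linked marker, 103 meioses
(36.126..., 1.849e-09)
>>> bxmap.recombinant_fraction_cm(41, 374)  # flanking interval length, cM
(10.96..., 1.61...)
```

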