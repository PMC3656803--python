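"""Backcross-panel simulator.

Models the cross used throughout: an F1 female heterozygous for a fully
penetrant recessive trait allele (from founder strain B) is bred back to a
homozygous mutant sire.  Every N2 offspring therefore receives a constant
mutant haplotype from the sire, and the informative datum at each marker is
the founder origin — ``A`` (wild-type strain) or ``B`` (mutant strain) — of
the single allele transmitted by the F1 dam.  Crossovers on the transmitted
gamete are realized as independent Bernoulli switches per adjacent marker
interval with probability r(gap) from the chosen map function (Haldane by
default, consistent with no interference); the trait locus is carried
through the same process as a pseudo-marker inserted in map order, so its
origin is jointly distributed with the flanking markers.

Phenotype follows the trait-locus origin: P(mutant | B origin) = penetrance,
P(mutant | A origin) = phenocopy_rate.  Genotyping error is a symmetric
origin flip applied before missing-data masking.  Every stochastic entry
point takes an explicit seed or Generator; identical inputs give
bit-identical panels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, UsageError
from .genmap import Chromosome, MapFunction, Marker, MarkerMap, cm_to_recfrac

__all__ = [
    "ORIGIN_A",
    "ORIGIN_B",
    "MUTANT",
    "WILDTYPE",
    "CrossDesign",
    "BackcrossPanel",
    "simulate_gamete",
    "simulate_gametes",
    "simulate_panel",
    "make_fixture",
    "scan_fixture_map",
    "fine_fixture_map",
    "FINE_MICROSATELLITES",
    "FINE_SNPS",
]

ORIGIN_A = "A"
ORIGIN_B = "B"
MUTANT = "mutant"
WILDTYPE = "wildtype"

#: cM beyond the terminal marker still considered part of the chromosome.
END_MARGIN_CM = 10.0


@dataclass
class CrossDesign:
    """Parameters of the backcross segregating a recessive trait locus."""

    founder_a: str
    founder_b: str
    trait_chrom: str
    trait_pos_cm: float
    penetrance: float = 1.0
    phenocopy_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("penetrance", "phenocopy_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} must lie in [0, 1], got {v}")
        if not np.isfinite(self.trait_pos_cm) or self.trait_pos_cm < 0:
            raise DomainError("trait_pos_cm must be finite and >= 0")

    def validate_against_map(self, marker_map: MarkerMap,
                             margin_cm: float = END_MARGIN_CM) -> None:
        """Check the trait position lies on (or within ``margin_cm`` of) its
        chromosome's marker span.  Absent chromosomes are allowed — they model
        a trait unlinked to every typed marker."""
        if not marker_map.has_chromosome(self.trait_chrom):
            return
        chrom = marker_map.chromosome(self.trait_chrom)
        if self.trait_pos_cm > chrom.length_cm + margin_cm:
            raise DomainError(
                f"trait position {self.trait_pos_cm} cM lies more than "
                f"{margin_cm} cM beyond the last marker of {chrom.name}"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CrossDesign":
        return cls(**json.loads(text))


@dataclass
class BackcrossPanel:
    """N2 individuals × markers founder-origin matrix plus binary phenotype.

    ``genotypes`` holds the origin ("A"/"B", NaN = missing) of the allele
    transmitted by the F1 parent; the backcross parent's contribution is
    constant and not stored.  ``trait_origins`` retains the simulated truth
    at the trait locus (None for real data).
    """

    genotypes: pd.DataFrame
    phenotypes: pd.Series
    design: CrossDesign | None = None
    marker_map: MarkerMap | None = None
    provenance: str = "simulated"
    trait_origins: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.genotypes.index.equals(self.phenotypes.index):
            raise UsageError("genotypes and phenotypes must share an index")
        bad = set(self.phenotypes.unique()) - {MUTANT, WILDTYPE}
        if bad:
            raise UsageError(f"unknown phenotype labels: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.genotypes)

    @property
    def individual_ids(self) -> list[str]:
        return list(self.genotypes.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.genotypes.columns)

    def subset_individuals(self, ids: Sequence[str]) -> "BackcrossPanel":
        return BackcrossPanel(
            genotypes=self.genotypes.loc[list(ids)],
            phenotypes=self.phenotypes.loc[list(ids)],
            design=self.design,
            marker_map=self.marker_map,
            provenance=self.provenance,
            trait_origins=None if self.trait_origins is None
            else self.trait_origins.loc[list(ids)],
        )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_gametes(
    marker_map: MarkerMap,
    chrom: str,
    n: int,
    spec: MapFunction | str = MapFunction.HALDANE,
    rng=0,
    extra_pos_cm: float | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Simulate ``n`` transmitted gametes over one chromosome's markers.

    Returns a boolean (n, m) matrix where True means founder-B origin and,
    if ``extra_pos_cm`` is given, the origin vector at that pseudo-locus
    drawn jointly through the same crossover chain.
    """
    chromosome = marker_map.chromosome(chrom)
    if not chromosome.markers:
        raise UsageError(f"chromosome {chrom!r} has no markers")
    rng = _as_rng(rng)
    pos = list(chromosome.positions_cm)
    extra_idx = None
    if extra_pos_cm is not None:
        extra_idx = int(np.searchsorted(pos, extra_pos_cm))
        pos = pos[:extra_idx] + [extra_pos_cm] + pos[extra_idx:]
    pos_arr = np.asarray(pos)
    r = cm_to_recfrac(np.diff(pos_arr), spec) if len(pos) > 1 else np.empty(0)
    first = rng.random(n) < 0.5
    if len(pos) > 1:
        switches = rng.random((n, len(pos) - 1)) < r
        chain = np.concatenate([first[:, None], switches], axis=1)
        is_b = np.logical_xor.accumulate(chain, axis=1)
    else:
        is_b = first[:, None]
    if extra_idx is None:
        return is_b, None
    extra = is_b[:, extra_idx].copy()
    markers_only = np.delete(is_b, extra_idx, axis=1)
    return markers_only, extra


def simulate_gamete(
    marker_map: MarkerMap,
    chrom: str,
    spec: MapFunction | str = MapFunction.HALDANE,
    rng=0,
) -> np.ndarray:
    """One transmitted gamete as an array of origin labels "A"/"B"."""
    is_b, _ = simulate_gametes(marker_map, chrom, 1, spec, rng)
    return np.where(is_b[0], ORIGIN_B, ORIGIN_A)


def simulate_panel(
    design: CrossDesign,
    marker_map: MarkerMap,
    n: int,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    spec: MapFunction | str = MapFunction.HALDANE,
) -> BackcrossPanel:
    """Simulate a full N2 backcross panel.

    A trait chromosome absent from the map models a locus unlinked to every
    typed marker (origin drawn Bernoulli(½) independently).
    """
    if n < 1:
        raise DomainError("panel size n must be >= 1")
    for name, v in (("error_rate", error_rate), ("missing_rate", missing_rate)):
        if not 0.0 <= v <= 1.0:
            raise DomainError(f"{name} must lie in [0, 1], got {v}")
    design.validate_against_map(marker_map)
    rng = _as_rng(seed)

    blocks: list[np.ndarray] = []
    columns: list[str] = []
    trait_is_b: np.ndarray | None = None
    for chrom in marker_map.chromosomes:
        extra = design.trait_pos_cm if chrom.name == design.trait_chrom else None
        is_b, extra_vec = simulate_gametes(
            marker_map, chrom.name, n, spec, rng, extra_pos_cm=extra
        )
        blocks.append(is_b)
        columns.extend(chrom.marker_ids)
        if extra_vec is not None:
            trait_is_b = extra_vec
    if trait_is_b is None:
        trait_is_b = rng.random(n) < 0.5  # unlinked trait chromosome

    p_mut = np.where(trait_is_b, design.penetrance, design.phenocopy_rate)
    is_mutant = rng.random(n) < p_mut

    geno_b = np.concatenate(blocks, axis=1)
    if error_rate > 0:
        geno_b = np.logical_xor(geno_b, rng.random(geno_b.shape) < error_rate)
    missing = (
        rng.random(geno_b.shape) < missing_rate if missing_rate > 0
        else np.zeros(geno_b.shape, dtype=bool)
    )

    ids = [f"N2-{i + 1:04d}" for i in range(n)]
    values = np.where(geno_b, ORIGIN_B, ORIGIN_A).astype(object)
    values[missing] = np.nan
    genotypes = pd.DataFrame(values, index=ids, columns=columns)
    phenotypes = pd.Series(
        np.where(is_mutant, MUTANT, WILDTYPE), index=ids, name="phenotype"
    )
    trait_origins = pd.Series(
        np.where(trait_is_b, ORIGIN_B, ORIGIN_A), index=ids, name="trait_origin"
    )
    return BackcrossPanel(
        genotypes=genotypes,
        phenotypes=phenotypes,
        design=design,
        marker_map=marker_map,
        provenance="simulated",
        trait_origins=trait_origins,
    )


# ---------------------------------------------------------------------------
# Study-sized fixtures
# ---------------------------------------------------------------------------

#: Markers per autosome for the genome-wide scan fixture: 93 microsatellites
#: across 19 autosomes at 16 cM spacing (mouse-like chromosome count; average
#: spacing matches the 16 cM of the genome scan these panels emulate).
_SCAN_MARKERS_PER_CHROM = [7, 7, 5, 6, 5, 5, 6, 5, 5, 5, 5, 4, 5, 4, 4, 4, 4, 4, 3]
_SCAN_FIRST_CM = 2.23  # first marker near the centromeric end
_SCAN_STEP_CM = 16.0

#: Fine-mapping fixture for proximal chromosome 2: five microsatellites with
#: an 11 cM / 11.66 Mb central gap, plus four secondary SNP markers inside it
#: (SNP1–SNP2 spanning 0.55 Mb around the trait locus at 9.0 cM).
_FINE_LAYOUT = [
    # (marker_id, pos_cM, pos_bp)
    ("M2.1", 2.23, 4_200_000),
    ("M2.2", 4.50, 6_100_000),
    ("M2.3", 5.50, 7_000_000),
    ("SNP1", 6.00, 10_200_000),
    ("SNP2", 12.00, 10_750_000),
    ("SNP3", 13.50, 12_200_000),
    ("SNP4", 15.00, 15_000_000),
    ("M2.4", 16.50, 18_660_000),
    ("M2.5", 26.00, 28_000_000),
]
FINE_MICROSATELLITES = ["M2.1", "M2.2", "M2.3", "M2.4", "M2.5"]
FINE_SNPS = ["SNP1", "SNP2", "SNP3", "SNP4"]
FINE_TRAIT_POS_CM = 9.0


def scan_fixture_map() -> MarkerMap:
    """93-marker genome-wide microsatellite map (19 autosomes, 16 cM spacing)."""
    chroms = []
    for c, n_mark in enumerate(_SCAN_MARKERS_PER_CHROM, start=1):
        markers = [
            Marker(f"M{c}.{i + 1}", _SCAN_FIRST_CM + i * _SCAN_STEP_CM)
            for i in range(n_mark)
        ]
        chroms.append(Chromosome(str(c), markers))
    return MarkerMap(chroms)


def fine_fixture_map(include_snps: bool = True) -> MarkerMap:
    """Proximal-chromosome-2 fine-mapping map (5 microsatellites [+ 4 SNPs])."""
    markers = [
        Marker(mid, cm, bp)
        for mid, cm, bp in _FINE_LAYOUT
        if include_snps or not mid.startswith("SNP")
    ]
    return MarkerMap([Chromosome("2", markers)])


def scan_fixture_design() -> CrossDesign:
    return CrossDesign(
        founder_a="C57BL/6J", founder_b="C3H-mut",
        trait_chrom="2", trait_pos_cm=FINE_TRAIT_POS_CM,
    )


def fine_fixture_design() -> CrossDesign:
    return CrossDesign(
        founder_a="A/J", founder_b="C3H-mut",
        trait_chrom="2", trait_pos_cm=FINE_TRAIT_POS_CM,
    )


def make_fixture(which: str, seed: int = 0):
    """Build one of the four study-sized fixtures.

    * ``scan103``   — 103-member panel typed for 93 genome-wide markers.
    * ``fine374``   — 374-member panel on proximal Chr 2 (5 microsatellites
      + 4 secondary SNPs; localization normally uses the microsatellites and
      refinement the SNPs).
    * ``comptest19`` — 19-offspring complementation cross in which the tested
      null allele complements the trait (all offspring wild type; 11 carriers,
      8 noncarriers).
    * ``comptest22`` — 22-offspring cross in which it fails to complement
      (11 carriers all mutant, 11 noncarriers all wild type).
    """
    from .comptest import ComplementationCrossTable  # local: avoid cycle

    if which == "scan103":
        return simulate_panel(scan_fixture_design(), scan_fixture_map(),
                              n=103, seed=seed)
    if which == "fine374":
        return simulate_panel(fine_fixture_design(), fine_fixture_map(),
                              n=374, seed=seed)
    if which == "comptest19":
        sexes = ["F"] * 5 + ["M"] * 6 + ["F"] * 7 + ["M"]
        carrier = ["carrier"] * 11 + ["noncarrier"] * 8
        phen = [WILDTYPE] * 19
        return ComplementationCrossTable.from_lists(
            ids=[f"C19-{i + 1:02d}" for i in range(19)],
            sexes=sexes, carrier_status=carrier, phenotypes=phen,
            tested_gene="Il2ra-null",
            design_note="null/+ dam x trait-homozygote sire",
        )
    if which == "comptest22":
        sexes = ["F"] * 6 + ["M"] * 5 + ["F"] * 10 + ["M"]
        carrier = ["carrier"] * 11 + ["noncarrier"] * 11
        phen = [MUTANT] * 11 + [WILDTYPE] * 11
        return ComplementationCrossTable.from_lists(
            ids=[f"C22-{i + 1:02d}" for i in range(22)],
            sexes=sexes, carrier_status=carrier, phenotypes=phen,
            tested_gene="Gata3-null",
            design_note="null/+ dam x trait-homozygote sire",
        )
    raise UsageError(
        f"unknown fixture {which!r}; expected scan103/fine374/comptest19/comptest22"
    )
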