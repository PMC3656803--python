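"""Localization of a recessive trait locus by recombinant-haplotype constraints.

With full penetrance, every offspring's phenotype reveals the founder origin
of the trait locus on the gamete it received: mutant offspring must have
inherited the mutant-founder (B) allele, wild-type offspring the A allele.
Each individual therefore confines the locus to the chromosomal segments
whose typed markers carry the required origin — each maximal run of
required-origin markers, extended into the flanking breakpoint intervals up
to (but excluding) the nearest marker of opposite origin, or to the
chromosome end for a terminal run.  Intersecting these admissible sets over
all individuals pins the locus between two flanking markers; recombinants
whose breakpoints fall closest to the locus supply the active constraints
("the locus must lie below marker X but above marker Y").

The genetic length of the resulting interval is estimated as the raw
recombinant fraction between the flanking markers times 100 (no
map-function correction), with a binomial standard error.  Secondary
markers typed only on the recombinants refine the interval by placing each
recombinant's single breakpoint into an adjacent-marker gap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, NoConsistentIntervalError, UsageError
from .genmap import MarkerMap
from .simpanel import (
    MUTANT,
    ORIGIN_A,
    ORIGIN_B,
    WILDTYPE,
    END_MARGIN_CM,
    BackcrossPanel,
    CrossDesign,
)

__all__ = [
    "HaplotypeClass",
    "HaplotypeTable",
    "LocusInterval",
    "RefineResult",
    "tabulate_haplotypes",
    "constrain_locus",
    "localize_locus",
    "select_recombinants",
    "refine_with_markers",
    "recombinant_fraction_cm",
]

logger = logging.getLogger("bxmap.finemap")

_EPS = 1e-9


@dataclass
class HaplotypeClass:
    """One distinct (origin pattern, phenotype) class among the panel."""

    pattern: str  # e.g. "ABBBB" over the typed markers, map order
    phenotype: str
    count: int
    member_ids: list[str] = field(default_factory=list)
    marker_ids: list[str] = field(default_factory=list)


@dataclass
class HaplotypeTable:
    classes: list[HaplotypeClass]
    incomplete_ids: list[str]  # individuals missing >=1 chosen marker
    n_total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"pattern": c.pattern, "phenotype": c.phenotype, "count": c.count}
                for c in self.classes
            ]
        )


@dataclass
class LocusInterval:
    """A flanking-marker interval confining the trait locus.

    Endpoints are open at the flanking markers (the locus lies strictly
    between them).  ``genetic_length_cm`` is the recombinant fraction between
    the flanks × 100; ``physical_span_bp`` is (start, end, length) from the
    flanking markers' bp positions when both are known.
    """

    chrom: str
    left_marker: str | None
    right_marker: str | None
    span_cm: tuple[float, float]
    genetic_length_cm: float
    se_cm: float
    n_recombinant_in_interval: int
    n_typed_both: int
    physical_span_bp: tuple[int, int, int] | None = None
    supporting_constraints: list[tuple[str, str]] = field(default_factory=list)
    contradictory_ids: list[str] = field(default_factory=list)
    unbounded_left: bool = False
    unbounded_right: bool = False

    @property
    def physical_span_mb(self) -> float | None:
        if self.physical_span_bp is None:
            return None
        return round(self.physical_span_bp[2] / 1e6, 2)


@dataclass
class RefineResult:
    crossover_counts: list[tuple[str, str, int]]  # (left, right, n) per gap
    interval: LocusInterval
    excluded_ids: list[str]  # double crossovers / missing secondary calls


def recombinant_fraction_cm(k: int, n: int) -> tuple[float, float]:
    """Interval length estimate: 100·k/n cM with binomial SE 100·√(p̂(1−p̂)/n)."""
    if n <= 0:
        raise DomainError("n must be positive")
    p_hat = k / n
    return 100.0 * p_hat, 100.0 * float(np.sqrt(p_hat * (1 - p_hat) / n))


def tabulate_haplotypes(
    panel: BackcrossPanel, marker_ids: Sequence[str] | None = None
) -> HaplotypeTable:
    """Collapse the panel into distinct (haplotype pattern, phenotype) classes.

    Markers must lie on one chromosome and are taken in map order.
    Individuals missing any chosen marker are reported separately in
    ``incomplete_ids`` rather than silently dropped; class counts plus
    incomplete individuals sum to the panel size.
    """
    marker_ids = _ordered_markers(panel, marker_ids)
    geno = panel.genotypes[marker_ids]
    complete = geno.notna().all(axis=1)
    incomplete_ids = list(geno.index[~complete])

    classes: dict[tuple[str, str], HaplotypeClass] = {}
    for ind_id, row in geno[complete].iterrows():
        pattern = "".join(row[m] for m in marker_ids)
        phen = panel.phenotypes.loc[ind_id]
        key = (pattern, phen)
        if key not in classes:
            classes[key] = HaplotypeClass(
                pattern=pattern, phenotype=phen, count=0,
                member_ids=[], marker_ids=list(marker_ids),
            )
        classes[key].count += 1
        classes[key].member_ids.append(ind_id)
    ordered = sorted(
        classes.values(), key=lambda c: (-c.count, c.pattern, c.phenotype)
    )
    return HaplotypeTable(ordered, incomplete_ids, panel.n)


def _ordered_markers(
    panel: BackcrossPanel, marker_ids: Sequence[str] | None
) -> list[str]:
    """Resolve and validate a single-chromosome, map-ordered marker subset."""
    if panel.marker_map is None:
        raise UsageError("panel carries no marker map")
    if marker_ids is None:
        marker_ids = panel.marker_ids
    chroms = {panel.marker_map.marker(m)[0] for m in marker_ids}
    if len(chroms) != 1:
        raise UsageError(
            f"markers span several chromosomes ({sorted(chroms)}); "
            "choose a single-chromosome subset"
        )
    chrom = panel.marker_map.chromosome(chroms.pop())
    ordered = [m for m in chrom.marker_ids if m in set(marker_ids)]
    missing = set(marker_ids) - set(panel.marker_ids)
    if missing:
        raise UsageError(f"markers not typed in panel: {sorted(missing)}")
    return ordered


def _required_origin(phenotype: str) -> str:
    return ORIGIN_B if phenotype == MUTANT else ORIGIN_A


def _admissible_segments(
    origins: Sequence[str],
    positions: Sequence[float],
    required: str,
    chrom_start: float,
    chrom_end: float,
) -> list[tuple[float, float]]:
    """Admissible open segments for one individual's typed haplotype.

    Each maximal run of required-origin markers yields one segment reaching
    from the nearest opposite-origin marker on its left (exclusive; chromosome
    start if none) to the nearest opposite-origin marker on its right
    (exclusive; chromosome end if none).
    """
    segments: list[tuple[float, float]] = []
    m = len(origins)
    i = 0
    while i < m:
        if origins[i] != required:
            i += 1
            continue
        j = i
        while j + 1 < m and origins[j + 1] == required:
            j += 1
        lo = positions[i - 1] if i > 0 else chrom_start
        hi = positions[j + 1] if j + 1 < m else chrom_end
        segments.append((lo, hi))
        i = j + 1
    return segments


def constrain_locus(
    hap: HaplotypeClass,
    design: CrossDesign,
    marker_map: MarkerMap,
    end_margin_cm: float = END_MARGIN_CM,
) -> list[tuple[float, float]]:
    """Admissible map segments for the trait locus given one haplotype class.

    Returns open (lo_cM, hi_cM) segments; an empty list flags a
    contradiction — no marker carries the origin the phenotype requires,
    impossible under full penetrance without genotyping/phenotyping error.
    """
    if not hap.marker_ids:
        raise UsageError("haplotype class carries no markers")
    chrom_name, _ = marker_map.marker(hap.marker_ids[0])
    chrom = marker_map.chromosome(chrom_name)
    positions = [marker_map.marker(m)[1].pos_cm for m in hap.marker_ids]
    required = _required_origin(hap.phenotype)
    return _admissible_segments(
        list(hap.pattern), positions, required,
        chrom_start=0.0, chrom_end=chrom.length_cm + end_margin_cm,
    )


def _consensus_region(
    constraints_by_id: dict[str, list[tuple[float, float]]],
    domain: tuple[float, float],
) -> tuple[tuple[float, float], list[str], int]:
    """Longest connected region consistent with the most individuals.

    A plain intersection of every individual's admissible set is fragile:
    one genuine double crossover bracketing the locus between typed markers
    makes it empty.  The consensus region instead maximizes the number of
    consistent individuals pointwise, then takes the longest connected
    component of the argmax set; individuals whose admissible set misses the
    region entirely are returned for exclusion (double crossovers under full
    penetrance).  Raises when fewer than half the individuals support the
    consensus — a model violation rather than occasional meiotic noise.
    """
    dlo, dhi = domain
    points = {dlo, dhi}
    for segs in constraints_by_id.values():
        for lo, hi in segs:
            if dlo <= lo <= dhi:
                points.add(lo)
            if dlo <= hi <= dhi:
                points.add(hi)
    pts = sorted(points)
    elem = [(a, b) for a, b in zip(pts, pts[1:]) if b - a > _EPS]
    if not elem:
        raise NoConsistentIntervalError("degenerate (zero-length) domain")
    mids = np.array([(a + b) / 2 for a, b in elem])
    cover = np.zeros(len(elem), dtype=int)
    covered_by: dict[str, np.ndarray] = {}
    for ind_id, segs in constraints_by_id.items():
        mask = np.zeros(len(elem), dtype=bool)
        for lo, hi in segs:
            mask |= (mids > lo) & (mids < hi)
        covered_by[ind_id] = mask
        cover += mask
    best = int(cover.max()) if len(constraints_by_id) else 0
    at_max = cover == best

    def _point_cover(p: float) -> int:
        # interior points (marker positions) are open in every segment
        return sum(
            any(lo < p < hi for lo, hi in segs)
            for segs in constraints_by_id.values()
        )

    # connected components of consecutive max-coverage elementary intervals;
    # adjacent intervals merge only if their shared point (a marker position,
    # open in the constraints that end there) is itself maximally consistent
    components: list[tuple[float, float]] = []
    i = 0
    while i < len(elem):
        if not at_max[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < len(elem)
            and at_max[j + 1]
            and abs(elem[j][1] - elem[j + 1][0]) < _EPS
            and _point_cover(elem[j][1]) == best
        ):
            j += 1
        components.append((elem[i][0], elem[j][1]))
        i = j + 1
    region = max(components, key=lambda c: c[1] - c[0])
    in_region = (mids > region[0]) & (mids < region[1])
    excluded = [
        ind_id for ind_id, mask in covered_by.items()
        if not (mask & in_region).any()
    ]
    n = len(constraints_by_id)
    if n and best * 2 < n:
        raise NoConsistentIntervalError(
            f"consensus region supported by only {best} of {n} individuals"
        )
    return region, excluded, best


def localize_locus(
    panel: BackcrossPanel,
    design: CrossDesign | None = None,
    marker_map: MarkerMap | None = None,
    marker_ids: Sequence[str] | None = None,
    end_margin_cm: float = END_MARGIN_CM,
) -> LocusInterval:
    """Intersect all individuals' admissibility constraints into one interval.

    Each individual contributes constraints from its typed markers only
    (pairwise use of partial haplotypes).  Contradictory individuals — none
    of whose typed markers carries the required origin — are excluded with a
    logged warning and listed on the result.  The returned interval is the
    maximal connected component of the intersection; its flanking markers
    are the nearest typed markers bounding it (terminal markers, with an
    ``unbounded_*`` flag, when no recombinant closes that side).
    """
    design = design or panel.design
    marker_map = marker_map or panel.marker_map
    if design is None or marker_map is None:
        raise UsageError("localize_locus needs a design and a marker map")
    marker_ids = _ordered_markers(panel, marker_ids)
    chrom_name, _ = marker_map.marker(marker_ids[0])
    chrom = marker_map.chromosome(chrom_name)
    positions = np.array([marker_map.marker(m)[1].pos_cm for m in marker_ids])
    chrom_start, chrom_end = 0.0, chrom.length_cm + end_margin_cm

    geno = panel.genotypes[marker_ids]
    contradictory: list[str] = []
    constraints_by_id: dict[str, list[tuple[float, float]]] = {}
    for ind_id, row in geno.iterrows():
        typed_mask = row.notna()
        if not typed_mask.any():
            continue
        origins = list(row[typed_mask])
        pos = list(positions[typed_mask.to_numpy()])
        required = _required_origin(panel.phenotypes.loc[ind_id])
        segs = _admissible_segments(origins, pos, required, chrom_start, chrom_end)
        if not segs:
            contradictory.append(ind_id)
            logger.warning(
                "individual %s contradicts full penetrance at %s; excluded",
                ind_id, chrom_name,
            )
            continue
        constraints_by_id[ind_id] = segs
    if not constraints_by_id:
        raise NoConsistentIntervalError(
            f"no individual carries usable constraints on chromosome {chrom_name}"
        )
    (lo, hi), outliers, _ = _consensus_region(
        constraints_by_id, (chrom_start, chrom_end)
    )
    for ind_id in outliers:
        logger.warning(
            "individual %s is inconsistent with the consensus interval "
            "(double crossover around the locus); excluded", ind_id,
        )
        contradictory.append(ind_id)
        constraints_by_id.pop(ind_id)

    left_idx = int(np.searchsorted(positions, lo + _EPS)) - 1
    right_idx = int(np.searchsorted(positions, hi - _EPS))
    unbounded_left = left_idx < 0
    unbounded_right = right_idx >= len(marker_ids)
    left_marker = marker_ids[max(left_idx, 0)]
    right_marker = marker_ids[min(right_idx, len(marker_ids) - 1)]
    if unbounded_left or unbounded_right:
        logger.warning(
            "interval unbounded by recombinants on %s side(s); terminal "
            "markers reported",
            "both" if unbounded_left and unbounded_right
            else ("left" if unbounded_left else "right"),
        )

    return _build_interval(
        panel, marker_map, chrom_name, left_marker, right_marker, (lo, hi),
        constraints_by_id, contradictory,
        unbounded_left=unbounded_left, unbounded_right=unbounded_right,
    )


def _build_interval(
    panel, marker_map, chrom_name, left_marker, right_marker, span_cm,
    constraints_by_id, contradictory, unbounded_left=False, unbounded_right=False,
) -> LocusInterval:
    left_pos = marker_map.marker(left_marker)[1].pos_cm
    right_pos = marker_map.marker(right_marker)[1].pos_cm

    g = panel.genotypes
    both = g[left_marker].notna() & g[right_marker].notna()
    rec = both & (g[left_marker] != g[right_marker])
    n_both, k = int(both.sum()), int(rec.sum())
    if n_both > 0:
        length_cm, se_cm = recombinant_fraction_cm(k, n_both)
    else:
        length_cm, se_cm = float("nan"), float("nan")

    supporting: list[tuple[str, str]] = []
    lo, hi = span_cm
    for ind_id, segs in constraints_by_id.items():
        for slo, shi in segs:
            if slo <= lo + _EPS and shi >= hi - _EPS:
                if abs(slo - left_pos) < _EPS and not unbounded_left:
                    supporting.append((ind_id, "locus_below_left"))
                if abs(shi - right_pos) < _EPS and not unbounded_right:
                    supporting.append((ind_id, "locus_above_right"))

    lbp = marker_map.marker(left_marker)[1].pos_bp
    rbp = marker_map.marker(right_marker)[1].pos_bp
    physical = None
    if lbp is not None and rbp is not None:
        start, end = sorted((lbp, rbp))
        physical = (start, end, end - start)

    return LocusInterval(
        chrom=chrom_name,
        left_marker=left_marker,
        right_marker=right_marker,
        span_cm=(float(lo), float(hi)),
        genetic_length_cm=length_cm,
        se_cm=se_cm,
        n_recombinant_in_interval=k,
        n_typed_both=n_both,
        physical_span_bp=physical,
        supporting_constraints=supporting,
        contradictory_ids=contradictory,
        unbounded_left=unbounded_left,
        unbounded_right=unbounded_right,
    )


def select_recombinants(
    panel: BackcrossPanel, interval: LocusInterval
) -> BackcrossPanel:
    """Sub-panel of individuals recombinant between the flanking markers.

    Individuals missing either flanking marker are excluded (logged); panel
    order is preserved.
    """
    g = panel.genotypes
    left, right = interval.left_marker, interval.right_marker
    both = g[left].notna() & g[right].notna()
    n_missing = int((~both).sum())
    if n_missing:
        logger.warning(
            "%d individuals missing a flanking-marker call excluded from "
            "recombinant selection", n_missing,
        )
    keep = both & (g[left] != g[right])
    return panel.subset_individuals(list(g.index[keep]))


def refine_with_markers(
    subpanel: BackcrossPanel,
    new_marker_ids: Sequence[str],
    design: CrossDesign | None = None,
    marker_map: MarkerMap | None = None,
    interval: LocusInterval | None = None,
    n_total: int | None = None,
) -> RefineResult:
    """Refine the interval with secondary markers typed on the recombinants.

    Each selected recombinant carries exactly one breakpoint between the old
    flanking markers; it is assigned to the adjacent-marker gap where its
    origin switches, and the phenotype constraint places the locus on the
    required-origin side.  Recombinants showing more than one origin switch
    (double crossovers) or missing secondary calls are excluded with a
    warning.  The refined interval is bounded by the innermost markers with
    at least one locus-separating crossover on each side; its genetic length
    uses ``n_total`` (the number of individuals the recombinants were drawn
    from) when given.
    """
    design = design or subpanel.design
    marker_map = marker_map or subpanel.marker_map
    if design is None or marker_map is None:
        raise UsageError("refine_with_markers needs a design and a marker map")
    chroms = {marker_map.marker(m)[0] for m in new_marker_ids}
    if len(chroms) != 1:
        raise UsageError("secondary markers must lie on one chromosome")
    chrom = marker_map.chromosome(chroms.pop())
    if interval is not None:
        left, right = interval.left_marker, interval.right_marker
    else:
        old = [m for m in _ordered_markers(subpanel, None)
               if m not in set(new_marker_ids)]
        left, right = old[0], old[-1]
    left_pos = marker_map.marker(left)[1].pos_cm
    right_pos = marker_map.marker(right)[1].pos_cm
    for m in new_marker_ids:
        p = marker_map.marker(m)[1].pos_cm
        if not (left_pos < p < right_pos):
            raise UsageError(
                f"secondary marker {m!r} at {p} cM lies outside the "
                f"({left}, {right}) span"
            )
    ordered = [left] + sorted(new_marker_ids,
                              key=lambda m: marker_map.marker(m)[1].pos_cm) + [right]
    positions = [marker_map.marker(m)[1].pos_cm for m in ordered]

    gap_counts = {i: 0 for i in range(len(ordered) - 1)}
    excluded: list[str] = []
    switch_by_id: dict[str, int] = {}
    constraints_by_id: dict[str, list[tuple[float, float]]] = {}
    geno = subpanel.genotypes
    for ind_id in subpanel.individual_ids:
        row = geno.loc[ind_id, ordered]
        if row.isna().any():
            logger.warning("recombinant %s missing a secondary call; excluded", ind_id)
            excluded.append(ind_id)
            continue
        origins = list(row)
        switches = [i for i in range(len(origins) - 1) if origins[i] != origins[i + 1]]
        if len(switches) != 1:
            logger.warning(
                "recombinant %s shows %d origin switches in the span "
                "(double crossover); excluded", ind_id, len(switches),
            )
            excluded.append(ind_id)
            continue
        required = _required_origin(subpanel.phenotypes.loc[ind_id])
        segs = _admissible_segments(origins, positions, required,
                                    chrom_start=left_pos, chrom_end=right_pos)
        segs = [(max(lo, left_pos), min(hi, right_pos)) for lo, hi in segs]
        segs = [(lo, hi) for lo, hi in segs if hi - lo > _EPS]
        if not segs:
            logger.warning("recombinant %s contradicts full penetrance; excluded",
                           ind_id)
            excluded.append(ind_id)
            continue
        switch_by_id[ind_id] = switches[0]
        constraints_by_id[ind_id] = segs
    if not constraints_by_id:
        raise NoConsistentIntervalError(
            "no recombinant carries usable secondary-marker constraints"
        )
    (lo, hi), outliers, _ = _consensus_region(
        constraints_by_id, (left_pos, right_pos)
    )
    for ind_id in outliers:
        logger.warning(
            "recombinant %s is inconsistent with the consensus interval "
            "(hidden double crossover); excluded", ind_id,
        )
        excluded.append(ind_id)
        constraints_by_id.pop(ind_id)
        switch_by_id.pop(ind_id)
    for gap in switch_by_id.values():
        gap_counts[gap] += 1
    pos_arr = np.array(positions)
    li = int(np.searchsorted(pos_arr, lo + _EPS)) - 1
    ri = int(np.searchsorted(pos_arr, hi - _EPS))
    li, ri = max(li, 0), min(ri, len(ordered) - 1)
    new_left, new_right = ordered[li], ordered[ri]

    # recombinants between the refined flanks (locus-separating crossovers)
    k = sum(n for g_idx, n in gap_counts.items() if li <= g_idx < ri)
    if n_total:
        length_cm, se_cm = recombinant_fraction_cm(k, n_total)
    else:
        length_cm, se_cm = float("nan"), float("nan")

    lbp = marker_map.marker(new_left)[1].pos_bp
    rbp = marker_map.marker(new_right)[1].pos_bp
    physical = None
    if lbp is not None and rbp is not None:
        start, end = sorted((lbp, rbp))
        physical = (start, end, end - start)

    supporting = []
    for ind_id, segs in constraints_by_id.items():
        for slo, shi in segs:
            if slo <= lo + _EPS and shi >= hi - _EPS:
                if abs(slo - pos_arr[li]) < _EPS:
                    supporting.append((ind_id, "locus_below_left"))
                if abs(shi - pos_arr[ri]) < _EPS:
                    supporting.append((ind_id, "locus_above_right"))

    refined = LocusInterval(
        chrom=chrom.name,
        left_marker=new_left,
        right_marker=new_right,
        span_cm=(float(lo), float(hi)),
        genetic_length_cm=length_cm,
        se_cm=se_cm,
        n_recombinant_in_interval=k,
        n_typed_both=n_total or 0,
        physical_span_bp=physical,
        supporting_constraints=supporting,
    )
    counts = [
        (ordered[i], ordered[i + 1], gap_counts[i]) for i in range(len(ordered) - 1)
    ]
    return RefineResult(crossover_counts=counts, interval=refined,
                        excluded_ids=excluded)
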