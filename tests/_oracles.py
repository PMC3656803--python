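"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's interval arithmetic: localization is
re-derived by pointwise consistency counting on a dense cM grid, and gene
overlap by a naive linear scan.
"""

from __future__ import annotations

import numpy as np

from bxmap.simpanel import MUTANT, ORIGIN_A, ORIGIN_B


def _consistent_at(x: float, positions, origins, required: str) -> bool:
    """Is locus position ``x`` consistent with one typed haplotype?

    Consistent iff the nearest typed marker on at least one side of ``x``
    carries the required origin (the locus can share a required-origin run
    or sit in the breakpoint gap adjacent to one); positions exactly at a
    marker take that marker's origin.
    """
    left = None
    right = None
    for pos, org in zip(positions, origins):
        if abs(pos - x) < 1e-9:
            return org == required
        if pos < x:
            left = org
        elif right is None:
            right = org
    if left is not None and left == required:
        return True
    if right is not None and right == required:
        return True
    return False


def grid_localize(panel, marker_ids, step=0.01, end_margin_cm=10.0):
    """Grid-scan localization: maximal-consistency region by enumeration.

    Returns (lo_cM, hi_cM) of the longest run of grid points consistent
    with the largest number of individuals.
    """
    marker_map = panel.marker_map
    chrom_name = marker_map.marker(marker_ids[0])[0]
    chrom = marker_map.chromosome(chrom_name)
    positions = [marker_map.marker(m)[1].pos_cm for m in marker_ids]
    end = chrom.length_cm + end_margin_cm
    grid = np.arange(0.0, end + step / 2, step)

    counts = np.zeros(len(grid), dtype=int)
    geno = panel.genotypes[marker_ids]
    for ind_id, row in geno.iterrows():
        typed = row.notna()
        if not typed.any():
            continue
        orgs = np.array(list(row[typed]))
        pos = np.array([p for p, t in zip(positions, typed) if t])
        required = ORIGIN_B if panel.phenotypes.loc[ind_id] == MUTANT else ORIGIN_A
        # vectorized pointwise consistency: nearest typed marker on either side
        idx = np.searchsorted(pos, grid)
        ok_left = np.zeros(len(grid), dtype=bool)
        has_left = idx > 0
        ok_left[has_left] = orgs[idx[has_left] - 1] == required
        ok_right = np.zeros(len(grid), dtype=bool)
        has_right = idx < len(pos)
        ok_right[has_right] = orgs[np.minimum(idx[has_right], len(pos) - 1)] == required
        ok = ok_left | ok_right
        # grid points essentially at a marker take that marker's origin
        for p, o in zip(pos, orgs):
            at = np.abs(grid - p) < 1e-9
            ok[at] = o == required
        counts += ok

    best = counts.max()
    at_max = counts == best
    # longest run of consecutive argmax grid points
    runs = []
    i = 0
    while i < len(grid):
        if not at_max[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(grid) and at_max[j + 1]:
            j += 1
        runs.append((i, j))
        i = j + 1
    i, j = max(runs, key=lambda r: grid[r[1]] - grid[r[0]])
    return float(grid[i]), float(grid[j])


def naive_overlap_scan(chrom, lo, hi, genes):
    """O(n) open-interval overlap oracle for gene records."""
    out = []
    for g in genes:
        if g.chrom != chrom:
            continue
        covered = any(lo < p < hi for p in range(g.start_bp, g.end_bp + 1)) \
            if (g.end_bp - g.start_bp) < 10_000 else (g.end_bp > lo and g.start_bp < hi)
        if covered:
            out.append(g)
    return sorted(out, key=lambda g: (g.start_bp, g.gene_id))
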