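"""Shared readers and writers: panel CSV, design JSON, result JSON.

Panel CSV dialect: one row per individual, columns ``id,phenotype,<marker>...``
with genotype values ``A``/``B``/``NA``.  All files are UTF-8 with LF line
endings; lines starting with ``#`` are metadata comments and are skipped on
read, so outputs can embed their provenance (seed, config hash) in-band.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .finemap import LocusInterval
from .genmap import MarkerMap
from .simpanel import MUTANT, ORIGIN_A, ORIGIN_B, WILDTYPE, BackcrossPanel, CrossDesign

__all__ = [
    "read_panel",
    "write_panel",
    "read_design",
    "write_design",
    "interval_to_dict",
    "write_interval_json",
]

_VALID_GENO = {ORIGIN_A, ORIGIN_B}


def write_panel(panel: BackcrossPanel, path, metadata: dict | None = None) -> None:
    path = Path(path)
    df = panel.genotypes.copy()
    df.insert(0, "phenotype", panel.phenotypes)
    df.index.name = "id"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, na_rep="NA", lineterminator="\n")


def read_panel(
    path,
    design: CrossDesign | None = None,
    marker_map: MarkerMap | None = None,
    provenance: str = "real",
) -> BackcrossPanel:
    path = Path(path)
    try:
        df = pd.read_csv(
            path, dtype=str, comment="#",
            keep_default_na=False, na_values=["NA"],
        )
    except pd.errors.EmptyDataError:
        raise ParseError(f"panel file {path} is empty") from None
    if df.empty or "id" not in df.columns or "phenotype" not in df.columns:
        raise ParseError(
            f"panel file {path} must have columns id,phenotype,<markers...>"
        )
    if df["id"].duplicated().any():
        dupes = sorted(set(df.loc[df["id"].duplicated(), "id"]))
        raise ParseError(f"panel file {path}: duplicate ids {dupes}")
    df = df.set_index("id")
    phen = df.pop("phenotype")
    bad_phen = set(phen.dropna().unique()) - {MUTANT, WILDTYPE}
    if bad_phen:
        raise ParseError(
            f"panel file {path}: unknown phenotype values {sorted(bad_phen)}"
        )
    geno = df
    values = geno.to_numpy(dtype=object)
    mask_bad = ~(pd.isna(values) | np.isin(values, list(_VALID_GENO)))
    if mask_bad.any():
        i, j = np.argwhere(mask_bad)[0]
        raise ParseError(
            f"panel file {path}: unknown genotype {values[i, j]!r} at "
            f"individual {geno.index[i]!r}, marker {geno.columns[j]!r}"
        )
    return BackcrossPanel(
        genotypes=geno,
        phenotypes=phen,
        design=design,
        marker_map=marker_map,
        provenance=provenance,
    )


def read_design(path) -> CrossDesign:
    return CrossDesign.from_json(Path(path).read_text(encoding="utf-8"))


def write_design(design: CrossDesign, path) -> None:
    Path(path).write_text(design.to_json() + "\n", encoding="utf-8")


def interval_to_dict(interval: LocusInterval) -> dict:
    d = {
        "chrom": interval.chrom,
        "left_marker": interval.left_marker,
        "right_marker": interval.right_marker,
        "span_cm": list(interval.span_cm),
        "genetic_length_cm": interval.genetic_length_cm,
        "se_cm": interval.se_cm,
        "n_recombinant_in_interval": interval.n_recombinant_in_interval,
        "n_typed_both": interval.n_typed_both,
        "physical_span_bp": (
            None if interval.physical_span_bp is None
            else list(interval.physical_span_bp)
        ),
        "physical_span_mb": interval.physical_span_mb,
        "supporting_constraints": [
            list(t) for t in interval.supporting_constraints
        ],
        "contradictory_ids": interval.contradictory_ids,
        "unbounded_left": interval.unbounded_left,
        "unbounded_right": interval.unbounded_right,
    }
    return d


def write_interval_json(interval: LocusInterval, path,
                        metadata: dict | None = None) -> None:
    payload = interval_to_dict(interval)
    if metadata:
        payload["metadata"] = metadata
    Path(path).write_text(
        json.dumps(payload, indent=2, default=float) + "\n", encoding="utf-8"
    )
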