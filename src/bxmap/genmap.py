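"""Genetic-map data model and map-function mathematics.

A genetic map orders polymorphic markers along chromosomes by genetic
position (centiMorgans) and, optionally, physical position (base pairs).
Map functions translate genetic distance d (in Morgans internally) into the
recombination fraction r — the probability that one meiosis transmits a
recombinant chromatid between two loci:

* Haldane (no crossover interference):  r = (1 − e^(−2d)) / 2
* Kosambi (partial interference):       r = tanh(2d) / 2

Both are strictly increasing, approach 0.5 as d → ∞, and behave as r ≈ d
for small d (1 cM ≈ 1% recombination).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ParseError, UsageError

__all__ = [
    "MapFunction",
    "Marker",
    "Chromosome",
    "MarkerMap",
    "cm_to_recfrac",
    "recfrac_to_cm",
    "read_map_tsv",
    "write_map_tsv",
]


class MapFunction(str, enum.Enum):
    """Mapping between genetic distance and recombination fraction."""

    HALDANE = "haldane"
    KOSAMBI = "kosambi"

    @classmethod
    def coerce(cls, value: "MapFunction | str") -> "MapFunction":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise DomainError(
                f"unknown map function {value!r}; expected 'haldane' or 'kosambi'"
            ) from None


def cm_to_recfrac(d_cm, spec: MapFunction | str = MapFunction.HALDANE):
    """Convert genetic distance in cM to a recombination fraction in [0, 0.5).

    Accepts scalars or array-likes; distances must be finite and non-negative.
    """
    spec = MapFunction.coerce(spec)
    d = np.asarray(d_cm, dtype=float)
    if not np.all(np.isfinite(d)):
        raise DomainError("genetic distance must be finite")
    if np.any(d < 0):
        raise DomainError("genetic distance must be non-negative")
    morgans = d / 100.0
    if spec is MapFunction.HALDANE:
        r = 0.5 * (1.0 - np.exp(-2.0 * morgans))
    else:
        r = 0.5 * np.tanh(2.0 * morgans)
    return float(r) if np.isscalar(d_cm) else r


def recfrac_to_cm(r, spec: MapFunction | str = MapFunction.HALDANE):
    """Exact inverse of :func:`cm_to_recfrac`; ``r`` must lie in [0, 0.5)."""
    spec = MapFunction.coerce(spec)
    rr = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(rr)):
        raise DomainError("recombination fraction must be finite")
    if np.any(rr < 0) or np.any(rr >= 0.5):
        raise DomainError("recombination fraction must lie in [0, 0.5)")
    if spec is MapFunction.HALDANE:
        morgans = -0.5 * np.log1p(-2.0 * rr)
    else:
        morgans = 0.5 * np.arctanh(2.0 * rr)
    d = morgans * 100.0
    return float(d) if np.isscalar(r) else d


@dataclass(frozen=True)
class Marker:
    """One mapped marker: identifier, genetic position (cM), optional bp."""

    marker_id: str
    pos_cm: float
    pos_bp: int | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.pos_cm) or self.pos_cm < 0:
            raise DomainError(
                f"marker {self.marker_id!r}: pos_cM must be finite and >= 0"
            )
        if self.pos_bp is not None and self.pos_bp <= 0:
            raise DomainError(f"marker {self.marker_id!r}: pos_bp must be positive")


@dataclass
class Chromosome:
    name: str
    markers: list[Marker] = field(default_factory=list)

    def __post_init__(self) -> None:
        cm = [m.pos_cm for m in self.markers]
        if any(b <= a for a, b in zip(cm, cm[1:])):
            raise DomainError(
                f"chromosome {self.name!r}: pos_cM must be strictly increasing"
            )
        bp = [m.pos_bp for m in self.markers]
        if all(p is not None for p in bp) and len(bp) > 1:
            diffs = [b - a for a, b in zip(bp, bp[1:])]
            if not (all(d > 0 for d in diffs) or all(d < 0 for d in diffs)):
                raise DomainError(
                    f"chromosome {self.name!r}: pos_bp must be strictly monotone"
                )

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    @property
    def positions_cm(self) -> np.ndarray:
        return np.array([m.pos_cm for m in self.markers], dtype=float)

    @property
    def length_cm(self) -> float:
        return self.markers[-1].pos_cm if self.markers else 0.0


@dataclass
class MarkerMap:
    """Ordered markers on one or more chromosomes; marker ids unique genome-wide."""

    chromosomes: list[Chromosome]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for chrom in self.chromosomes:
            for m in chrom.markers:
                if m.marker_id in seen:
                    raise DomainError(f"duplicate marker id {m.marker_id!r}")
                seen.add(m.marker_id)

    def chromosome(self, name: str) -> Chromosome:
        for chrom in self.chromosomes:
            if chrom.name == name:
                return chrom
        raise UsageError(f"chromosome {name!r} not in map")

    def has_chromosome(self, name: str) -> bool:
        return any(c.name == name for c in self.chromosomes)

    def marker(self, marker_id: str) -> tuple[str, Marker]:
        """Return ``(chromosome_name, marker)`` for a marker id."""
        for chrom in self.chromosomes:
            for m in chrom.markers:
                if m.marker_id == marker_id:
                    return chrom.name, m
        raise UsageError(f"marker {marker_id!r} not in map")

    @property
    def marker_ids(self) -> list[str]:
        return [m for c in self.chromosomes for m in c.marker_ids]

    @property
    def n_markers(self) -> int:
        return sum(len(c.markers) for c in self.chromosomes)

    def subset(self, marker_ids: Sequence[str]) -> "MarkerMap":
        """Map restricted to the given markers (map order preserved)."""
        wanted = set(marker_ids)
        missing = wanted - set(self.marker_ids)
        if missing:
            raise UsageError(f"markers not in map: {sorted(missing)}")
        chroms = []
        for chrom in self.chromosomes:
            kept = [m for m in chrom.markers if m.marker_id in wanted]
            if kept:
                chroms.append(Chromosome(chrom.name, kept))
        return MarkerMap(chroms)


def read_map_tsv(path) -> MarkerMap:
    """Read a marker map from TSV with columns chrom/marker/pos_cM/pos_bp.

    ``pos_bp`` may be blank (unknown physical position); coordinates are
    1-based base pairs.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "marker": str},
                         comment="#")
    except pd.errors.EmptyDataError:
        raise ParseError(f"map file {path} is empty") from None
    required = {"chrom", "marker", "pos_cM"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"map file {path} must have columns chrom/marker/pos_cM[/pos_bp]; "
            f"found {list(df.columns)}"
        )
    if "pos_bp" not in df.columns:
        df["pos_bp"] = np.nan
    chroms: list[Chromosome] = []
    for name in df["chrom"].drop_duplicates():
        sub = df[df["chrom"] == name]
        markers = [
            Marker(
                str(row.marker),
                float(row.pos_cM),
                None if pd.isna(row.pos_bp) else int(row.pos_bp),
            )
            for row in sub.itertuples()
        ]
        chroms.append(Chromosome(str(name), markers))
    return MarkerMap(chroms)


def write_map_tsv(marker_map: MarkerMap, path) -> None:
    rows = [
        {
            "chrom": chrom.name,
            "marker": m.marker_id,
            "pos_cM": m.pos_cm,
            "pos_bp": "" if m.pos_bp is None else m.pos_bp,
        }
        for chrom in marker_map.chromosomes
        for m in chrom.markers
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
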