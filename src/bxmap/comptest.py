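"""Complementation-cross analysis.

A heterozygous carrier of an engineered null allele in the candidate gene is
crossed to a homozygote for the recessive trait mutation.  If the two
mutations are allelic, null carriers inherit two defective copies and
express the trait (failure to complement); if the genes are distinct, every
offspring keeps one functional copy of each and is phenotypically normal
(complementation).  The analysis checks the carrier:noncarrier ratio against
the 1:1 testcross expectation and scores phenotype–genotype concordance with
the failure-to-complement prediction (carrier → mutant, noncarrier → wild
type).

The verdict rule is this module's formalization — the underlying crosses are
read out qualitatively — with a configurable concordance threshold
(default 1.0, i.e. a perfect pattern is required) for penetrance-tolerant
reanalysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .errors import DomainError, ParseError
from .linkscan import chi2_gof_1to1
from .simpanel import MUTANT, WILDTYPE

__all__ = [
    "ComplementationCrossTable",
    "ComplementationOutcome",
    "carrier_ratio_test",
    "allelism_verdict",
    "read_offspring_csv",
    "write_offspring_csv",
]

CARRIER = "carrier"
NONCARRIER = "noncarrier"


@dataclass
class ComplementationCrossTable:
    """Offspring of one complementation cross.

    ``offspring`` columns: id, sex, carrier (carrier/noncarrier for the
    engineered null, PCR-typed for every animal), phenotype (mutant/wildtype).
    """

    offspring: pd.DataFrame
    tested_gene: str
    design_note: str = ""

    def __post_init__(self) -> None:
        required = {"id", "sex", "carrier", "phenotype"}
        if not required.issubset(self.offspring.columns):
            raise ParseError(
                f"offspring table needs columns {sorted(required)}"
            )
        bad = set(self.offspring["carrier"]) - {CARRIER, NONCARRIER}
        if bad:
            raise ParseError(f"unknown carrier status values: {sorted(bad)}")
        bad = set(self.offspring["phenotype"]) - {MUTANT, WILDTYPE}
        if bad:
            raise ParseError(f"unknown phenotype values: {sorted(bad)}")
        if self.offspring["id"].duplicated().any():
            dupes = self.offspring.loc[self.offspring["id"].duplicated(), "id"]
            raise ParseError(f"duplicate offspring ids: {sorted(set(dupes))}")

    @classmethod
    def from_lists(
        cls,
        ids: Sequence[str],
        sexes: Sequence[str],
        carrier_status: Sequence[str],
        phenotypes: Sequence[str],
        tested_gene: str,
        design_note: str = "",
    ) -> "ComplementationCrossTable":
        df = pd.DataFrame(
            {"id": ids, "sex": sexes, "carrier": carrier_status,
             "phenotype": phenotypes}
        )
        return cls(df, tested_gene, design_note)

    @property
    def n(self) -> int:
        return len(self.offspring)

    @property
    def n_carrier(self) -> int:
        return int((self.offspring["carrier"] == CARRIER).sum())

    @property
    def n_noncarrier(self) -> int:
        return int((self.offspring["carrier"] == NONCARRIER).sum())


@dataclass
class ComplementationOutcome:
    tested_gene: str
    n_carrier: int
    n_noncarrier: int
    ratio_chi2: float
    ratio_p: float
    concordance: float  # agreement with the failure-to-complement prediction
    verdict: str  # complement | fail_to_complement | inconclusive
    note: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {k: v for k, v in vars(self).items()}, indent=2, default=float
        )


def carrier_ratio_test(table: ComplementationCrossTable) -> tuple[float, float]:
    """Carrier:noncarrier counts against the 1:1 testcross expectation."""
    if table.n == 0:
        raise DomainError("empty offspring table")
    return chi2_gof_1to1(table.n_carrier, table.n_noncarrier)


def allelism_verdict(
    table: ComplementationCrossTable, concordance_threshold: float = 1.0
) -> ComplementationOutcome:
    """Adjudicate allelism from phenotype–genotype concordance.

    Failure to complement predicts carrier → mutant and noncarrier → wild
    type; complementation predicts every offspring wild type.  The verdict is
    ``complement`` when all offspring are wild type, ``fail_to_complement``
    when concordance with the failure prediction reaches the threshold, and
    ``inconclusive`` otherwise (including single-class tables, which cannot
    discriminate the two predictions).
    """
    if table.n == 0:
        raise DomainError("empty offspring table")
    chi2, p = carrier_ratio_test(table)
    df = table.offspring
    predicted_fail = df["carrier"].map({CARRIER: MUTANT, NONCARRIER: WILDTYPE})
    concordance = float((df["phenotype"] == predicted_fail).mean())
    all_wildtype = bool((df["phenotype"] == WILDTYPE).all())

    note = ""
    if table.n_carrier == 0 or table.n_noncarrier == 0:
        verdict = "inconclusive"
        note = (
            "single-class table: both carriers and noncarriers are needed to "
            "discriminate complementation from failure to complement"
        )
    elif all_wildtype:
        verdict = "complement"
    elif concordance >= concordance_threshold:
        verdict = "fail_to_complement"
    else:
        verdict = "inconclusive"
        note = "mixed phenotype pattern; see concordance"
    return ComplementationOutcome(
        tested_gene=table.tested_gene,
        n_carrier=table.n_carrier,
        n_noncarrier=table.n_noncarrier,
        ratio_chi2=chi2,
        ratio_p=p,
        concordance=concordance,
        verdict=verdict,
        note=note,
    )


def read_offspring_csv(path, tested_gene: str,
                       design_note: str = "") -> ComplementationCrossTable:
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"offspring file {path} is empty") from None
    return ComplementationCrossTable(df, tested_gene, design_note)


def write_offspring_csv(table: ComplementationCrossTable, path) -> None:
    table.offspring.to_csv(path, index=False, lineterminator="\n")
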