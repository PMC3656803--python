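"""Genome-wide two-stage segregation-distortion scan.

Each typed meiosis is classified as *parental* (trait allele co-transmitted
with a mutant-strain marker allele, or wild-type allele with a wild-type-
strain marker allele) or *recombinant* (the reverse pairings).  Under no
linkage the two classes are 1:1; linkage shows as a parental surplus.  The
per-marker test is the two-cell Pearson goodness-of-fit statistic

    chi2 = (n_parental - n_recombinant)^2 / n_typed,   df = 1,

with no continuity correction and no multiple-testing adjustment — each
marker is called against fixed per-marker thresholds (P < 0.05 significant,
P < 0.01 highly significant), and only parental-surplus markers are ever
called linked.  The scan is two-staged: an initial subset (default 44
individuals, in stable panel order) is typed for every marker, and a marker
is promoted to full-panel typing only when the initial test gives P below
``expand_p`` (default 0.1) *with* a parental surplus.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, UndefinedTestError, UsageError
from .simpanel import MUTANT, ORIGIN_B, BackcrossPanel, CrossDesign

__all__ = [
    "MarkerScanRecord",
    "classify_meiosis",
    "chi2_gof_1to1",
    "two_stage_scan",
    "call_linked_markers",
    "segregation_ratio_test",
    "scan_to_frame",
    "plot_scan",
]

PARENTAL = "parental"
RECOMBINANT = "recombinant"


@dataclass
class MarkerScanRecord:
    marker_id: str
    n_typed: int
    n_parental: int
    n_recombinant: int
    chi2: float
    p_value: float
    neglog10p_signed: float
    stage: str  # "initial" | "expanded"
    flagged: bool = False  # zero informative meioses
    linkage_call: str | None = None  # set by call_linked_markers


def classify_meiosis(origin: str, phenotype: str, design: CrossDesign | None = None) -> str:
    """Classify one typed meiosis as parental or recombinant.

    Parental = mutant offspring carrying the mutant-founder (B) marker allele,
    or wild-type offspring carrying the A allele; recombinant otherwise.
    Missing origins must be excluded by the caller (pairwise deletion).
    """
    if origin is None or (isinstance(origin, float) and np.isnan(origin)):
        raise DomainError("cannot classify a missing origin; exclude the meiosis")
    mutant = phenotype == MUTANT
    b_origin = origin == ORIGIN_B
    return PARENTAL if mutant == b_origin else RECOMBINANT


def chi2_gof_1to1(a: int, b: int) -> tuple[float, float]:
    """Pearson goodness-of-fit against a 1:1 ratio, 1 df, no continuity
    correction: chi2 = (a-b)^2/(a+b)."""
    if a < 0 or b < 0:
        raise DomainError("counts must be non-negative")
    n = a + b
    if n == 0:
        raise UndefinedTestError("1:1 goodness-of-fit undefined on zero counts")
    chi2 = (a - b) ** 2 / n
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def segregation_ratio_test(n_mutant: int, n_wildtype: int) -> tuple[float, float, str]:
    """Test offspring counts against the 1 mutant : 1 wild-type testcross ratio."""
    chi2, p = chi2_gof_1to1(n_mutant, n_wildtype)
    verdict = "consistent with testcross" if p >= 0.05 else "inconsistent with testcross"
    return chi2, p, verdict


def _parental_recombinant_counts(
    geno: pd.DataFrame, phenotypes: pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-marker (parental, recombinant) counts with pairwise
    deletion of missing genotypes."""
    typed = geno.notna().to_numpy()
    is_b = (geno == ORIGIN_B).to_numpy()
    is_mut = (phenotypes == MUTANT).to_numpy()[:, None]
    parental = (is_b == is_mut) & typed
    n_par = parental.sum(axis=0)
    n_typed = typed.sum(axis=0)
    return n_par, n_typed - n_par


def _signed_neglog10(p: np.ndarray, n_par: np.ndarray, n_rec: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        mag = -np.log10(p)
    return np.where(n_rec > n_par, -mag, mag)


def two_stage_scan(
    panel: BackcrossPanel,
    design: CrossDesign | None = None,
    n_initial: int = 44,
    expand_p: float = 0.1,
) -> list[MarkerScanRecord]:
    """Scan every marker for co-segregation with the trait phenotype.

    Stage 1 types the first ``n_initial`` individuals (stable panel order);
    a marker is promoted to the full panel iff its stage-1 P < ``expand_p``
    and parentals exceed recombinants.  Markers with zero informative
    meioses are reported flagged with p = 1.
    """
    if n_initial > panel.n:
        raise DomainError(
            f"n_initial={n_initial} exceeds the panel size {panel.n}"
        )
    if n_initial < 1:
        raise DomainError("n_initial must be >= 1")
    geno = panel.genotypes
    phen = panel.phenotypes

    par1, rec1 = _parental_recombinant_counts(geno.iloc[:n_initial], phen.iloc[:n_initial])
    n1 = par1 + rec1
    with np.errstate(divide="ignore", invalid="ignore"):
        chi1 = np.where(n1 > 0, (par1 - rec1) ** 2 / np.maximum(n1, 1), 0.0)
    p1 = stats.chi2.sf(chi1, df=1)
    p1 = np.where(n1 > 0, p1, 1.0)
    promote = (p1 < expand_p) & (par1 > rec1) & (n_initial < panel.n)

    par_f, rec_f = _parental_recombinant_counts(geno, phen)
    par = np.where(promote, par_f, par1)
    rec = np.where(promote, rec_f, rec1)
    n_typed = par + rec
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2v = np.where(n_typed > 0, (par - rec) ** 2 / np.maximum(n_typed, 1), 0.0)
    p = stats.chi2.sf(chi2v, df=1)
    p = np.where(n_typed > 0, p, 1.0)
    signed = _signed_neglog10(p, par, rec)

    records = []
    for j, marker_id in enumerate(geno.columns):
        records.append(
            MarkerScanRecord(
                marker_id=marker_id,
                n_typed=int(n_typed[j]),
                n_parental=int(par[j]),
                n_recombinant=int(rec[j]),
                chi2=float(chi2v[j]),
                p_value=float(p[j]),
                neglog10p_signed=float(signed[j]),
                stage="expanded" if promote[j] else "initial",
                flagged=bool(n_typed[j] == 0),
            )
        )
    return records


def call_linked_markers(
    scan: list[MarkerScanRecord],
    alpha_significant: float = 0.05,
    alpha_highly: float = 0.01,
) -> list[MarkerScanRecord]:
    """Label each record none/significant/highly_significant.

    Only markers with a parental surplus can be called linked; a
    recombinant surplus, however extreme, is never a linkage signal.
    """
    if not scan:
        raise UsageError("empty scan")
    out = []
    for rec in scan:
        call = "none"
        if rec.n_parental > rec.n_recombinant and not rec.flagged:
            if rec.p_value < alpha_highly:
                call = "highly_significant"
            elif rec.p_value < alpha_significant:
                call = "significant"
        out.append(replace(rec, linkage_call=call))
    return out


def scan_to_frame(scan: list[MarkerScanRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in scan])


def plot_scan(scan, marker_map=None, ax=None,
              alpha_significant: float = 0.05, alpha_highly: float = 0.01):
    """Manhattan-style bar plot of signed -log10 P with guide lines at the
    significant / highly-significant thresholds."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3.5))
    ys = [r.neglog10p_signed for r in scan]
    ax.bar(range(len(scan)), ys, width=0.8, color="steelblue")
    ax.axhline(-np.log10(alpha_significant), color="orange", lw=1,
               label=f"P = {alpha_significant}")
    ax.axhline(-np.log10(alpha_highly), color="red", lw=1,
               label=f"P = {alpha_highly}")
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_ylabel("signed $-\\log_{10} P$")
    ax.set_xlabel("marker (map order)")
    ax.legend(loc="upper right", fontsize=8)
    return ax
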