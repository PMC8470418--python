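"""Clade-contrast differential-conservation screen.

For every gene of a reference proteome the screen contrasts a focal clade
(here modeled on Otomorpha fish) with a reference clade (modeled on
Euteleosteomorpha): a gene with no focal-clade ortholog but solid
reference support is called ABSENT; otherwise a divergence score

    D = (mean(reference identities) - mean(focal identities)) / sd(reference identities)

measures how far the focal sequences fall below the reference spread, and
the gene is called HIGH_DIVERGENCE (D >= z_hi), MILD_DIVERGENCE
(z_lo <= D < z_hi) or CONSERVED (D < z_lo).  Genes without enough
reference support to evaluate are NOT_EVALUABLE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ABSENT = "ABSENT"
HIGH_DIVERGENCE = "HIGH_DIVERGENCE"
MILD_DIVERGENCE = "MILD_DIVERGENCE"
CONSERVED = "CONSERVED"
NOT_EVALUABLE = "NOT_EVALUABLE"

CATEGORIES = (ABSENT, HIGH_DIVERGENCE, MILD_DIVERGENCE, CONSERVED, NOT_EVALUABLE)
FLAGGED = (ABSENT, HIGH_DIVERGENCE, MILD_DIVERGENCE)


@dataclass(frozen=True)
class ConservationParams:
    """Thresholds of the surrogate classifier (all configurable)."""

    z_hi: float = 3.0
    z_lo: float = 1.5
    min_ref_presence_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.z_lo > self.z_hi:
            raise ValueError("z_lo must not exceed z_hi")
        if not 0 <= self.min_ref_presence_frac <= 1:
            raise ValueError("min_ref_presence_frac must be in [0, 1]")

    @property
    def gap(self) -> float:
        return self.z_hi - self.z_lo


@dataclass
class ConservationCall:
    gene: str
    category: str
    divergence_score: float  # NaN when undefined


def divergence_score(focal_identities, ref_identities) -> float:
    """Standardized reference-minus-focal identity deficit; NaN if undefined.

    Requires at least two reference identities with nonzero spread and at
    least one focal identity; the reference standard deviation uses the
    sample convention (ddof = 1).
    """
    focal = np.asarray(list(focal_identities), dtype=float)
    ref = np.asarray(list(ref_identities), dtype=float)
    if focal.size < 1 or ref.size < 2:
        return float("nan")
    sd = ref.std(ddof=1)
    if sd == 0:
        return float("nan")
    return float((ref.mean() - focal.mean()) / sd)


def classify_gene(row, params: ConservationParams = ConservationParams()) -> ConservationCall:
    """Classify one clade-table row (mapping or Series with the table fields)."""
    gene = str(row["gene"])
    n_ref = int(row["n_ref"])
    ref_frac = row["ref_presence"] / n_ref if n_ref else 0.0
    if int(row["focal_presence"]) == 0:
        if ref_frac >= params.min_ref_presence_frac:
            return ConservationCall(gene, ABSENT, float("nan"))
        return ConservationCall(gene, NOT_EVALUABLE, float("nan"))
    score = divergence_score(row["focal_identities"], row["ref_identities"])
    if np.isnan(score) or ref_frac < params.min_ref_presence_frac:
        return ConservationCall(gene, NOT_EVALUABLE, score)
    if score >= params.z_hi:
        return ConservationCall(gene, HIGH_DIVERGENCE, score)
    if score >= params.z_lo:
        return ConservationCall(gene, MILD_DIVERGENCE, score)
    return ConservationCall(gene, CONSERVED, score)


def screen_proteome(
    table: pd.DataFrame, params: ConservationParams = ConservationParams()
) -> tuple[pd.DataFrame, dict]:
    """Classify every gene of a clade table.

    Returns the per-gene calls (gene, category, divergence_score) and a
    summary with per-category counts and the flagged total
    (ABSENT + HIGH_DIVERGENCE + MILD_DIVERGENCE).
    """
    if len(table) < 1:
        raise ValueError("clade table is empty")
    records = table.to_dict("records")
    calls = [classify_gene(row, params) for row in records]
    out = pd.DataFrame(
        {
            "gene": [c.gene for c in calls],
            "category": [c.category for c in calls],
            "divergence_score": [c.divergence_score for c in calls],
        }
    )
    counts = {cat: int((out["category"] == cat).sum()) for cat in CATEGORIES}
    summary = {
        "counts": counts,
        "flagged": sum(counts[c] for c in FLAGGED),
        "total": len(out),
    }
    return out, summary


def flagged_genes(calls: pd.DataFrame) -> set[str]:
    """Genes with an atypical focal-clade behavior (absent or diverged)."""
    return set(calls.loc[calls["category"].isin(FLAGGED), "gene"])
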