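"""Hypergeometric over-representation test with multiple-testing correction.

Given a study gene set and a flat term -> genes annotation map, each term
is tested for over-representation with the upper-tail hypergeometric
probability of drawing at least k annotated genes in a study of size n
from a population of N genes of which K carry the term.  P-values are
adjusted with Benjamini-Hochberg by default (Bonferroni selectable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

_CORRECTIONS = {"bh": "fdr_bh", "bonferroni": "bonferroni"}


@dataclass
class AnnotationMap:
    """Flat term annotations over a gene population."""

    terms: dict[str, frozenset]
    names: dict[str, str] = field(default_factory=dict)
    population: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.terms = {t: frozenset(g) for t, g in self.terms.items()}
        if not self.population:
            self.population = frozenset().union(*self.terms.values()) if self.terms else frozenset()
        stray = {g for genes in self.terms.values() for g in genes} - set(self.population)
        if stray:
            raise ValueError(f"annotated genes outside population: {sorted(stray)[:5]}")

    @classmethod
    def from_table(cls, table: pd.DataFrame, population=None) -> "AnnotationMap":
        terms: dict[str, set] = {}
        names: dict[str, str] = {}
        for term_id, name, gene in table[["term_id", "term_name", "gene"]].itertuples(index=False):
            terms.setdefault(str(term_id), set()).add(str(gene))
            names[str(term_id)] = str(name)
        pop = frozenset(map(str, population)) if population is not None else frozenset()
        return cls(terms={t: frozenset(g) for t, g in terms.items()}, names=names,
                   population=pop)

    def annotation_counts(self, genes) -> dict[str, int]:
        """Number of terms annotating each of the given genes."""
        counts = {str(g): 0 for g in genes}
        for term_genes in self.terms.values():
            for g in term_genes:
                if g in counts:
                    counts[g] += 1
        return counts


def hypergeometric_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, K, n)."""
    if not (0 <= k <= min(n, K) and n <= N and K <= N and n >= 0 and K >= 0):
        raise ValueError(f"invalid hypergeometric bounds: k={k} n={n} K={K} N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    study, annotations: AnnotationMap, correction: str = "bh"
) -> pd.DataFrame:
    """Over-representation results for every annotated term.

    Returns one row per term with at least one annotated population gene,
    sorted by (adjusted_p, term_id).  Raises when study genes fall outside
    the annotation population.
    """
    if correction not in _CORRECTIONS:
        raise ValueError(f"correction must be one of {sorted(_CORRECTIONS)}")
    study = set(map(str, study))
    pop = set(annotations.population)
    outside = sorted(study - pop)
    if outside:
        raise ValueError(f"study genes outside population: {outside[:10]}")
    N = len(pop)
    n = len(study)
    rows = []
    for term_id in sorted(annotations.terms):
        term_genes = annotations.terms[term_id]
        K = len(term_genes)
        if K < 1:
            continue
        k = len(study & term_genes)
        rows.append(
            {
                "term_id": term_id,
                "term_name": annotations.names.get(term_id, term_id),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p_value": hypergeometric_test(k, n, K, N),
            }
        )
    result = pd.DataFrame(rows)
    if len(result):
        result["adjusted_p"] = multipletests(
            result["p_value"].to_numpy(), method=_CORRECTIONS[correction]
        )[1]
        result["adjusted_p"] = result[["p_value", "adjusted_p"]].max(axis=1)
        result = result.sort_values(
            ["adjusted_p", "term_id"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        result["adjusted_p"] = []
    return result
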