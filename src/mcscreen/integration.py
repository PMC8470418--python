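"""Evidence integration and promising-candidate prioritization.

The transcriptional screen (genes overexpressed in at least two
experiments) is intersected with the differential-conservation screen
(genes absent or diverged in the focal fish clade) to produce the
candidate list; a configurable set of known multiciliation genes is
appended; network, profile and annotation evidence is attached per gene;
and a final rule extracts the "promising" shortlist: flagged candidates
with essentially no functional annotation whose phylogenetic profile
matches a ciliary pattern.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .conservation import FLAGGED
from .phylo_profiling import CILIARY_PATTERNS

#: the eight genes with an established multiciliation role that are
#: appended to the candidate list (E2F5 for the occasionally mistyped
#: "E3F5" symbol)
DEFAULT_KNOWN_GENES = (
    "CCNO", "GEMC1", "CEP63", "CEP152", "E2F4", "E2F5", "CCDC78", "CDC20B",
)

DEFAULT_MAX_ANNOTATIONS = 0

EVIDENCE_COLUMNS = [
    "gene", "known", "overexpr_count", "expression_cluster",
    "cluster_signature_group", "conservation_category", "network_cluster",
    "profile_cluster", "profile_patterns", "annotation_count", "promising",
]


@dataclass
class CandidateEvidence:
    """Merged per-gene evidence record."""

    gene: str
    known: bool = False
    overexpr_count: int = 0
    expression_cluster: int = 0
    cluster_signature_group: str = ""
    conservation_category: str = "NOT_EVALUABLE"
    network_cluster: int | None = None
    profile_cluster: int | None = None
    profile_patterns: tuple[str, ...] = ()
    annotation_count: int = 0
    promising: bool = False


def integrate(
    retained_expression_genes, conservation_calls: pd.DataFrame
) -> tuple[list[str], dict[str, int]]:
    """Candidates = expression-retained genes with an atypical conservation call.

    Returns the sorted candidate list and per-category counts.
    """
    retained = set(map(str, retained_expression_genes))
    flagged = conservation_calls[conservation_calls["category"].isin(FLAGGED)]
    by_category: dict[str, int] = {}
    candidates = []
    for gene, category in zip(flagged["gene"], flagged["category"]):
        if gene in retained:
            candidates.append(gene)
            by_category[category] = by_category.get(category, 0) + 1
    return sorted(candidates), by_category


def append_known(candidates, known_genes=DEFAULT_KNOWN_GENES) -> pd.DataFrame:
    """Union of candidates and known genes with a ``known`` flag.

    Idempotent: genes on both lists appear once, flagged known.
    """
    known = list(dict.fromkeys(map(str, known_genes)))
    if not known:
        raise ValueError("known gene list is empty")
    cand = set(map(str, candidates))
    genes = sorted(cand | set(known))
    return pd.DataFrame(
        {
            "gene": genes,
            "candidate": [g in cand for g in genes],
            "known": [g in set(known) for g in genes],
        }
    )


def prioritize(
    evidence: list[CandidateEvidence],
    ciliary_profile_clusters=frozenset(),
    multiciliated_signature_groups=frozenset(),
    max_annotations: int = DEFAULT_MAX_ANNOTATIONS,
    ciliary_patterns=CILIARY_PATTERNS,
) -> list[CandidateEvidence]:
    """Select and rank the promising shortlist.

    A gene is promising when it is essentially unannotated
    (``annotation_count <= max_annotations``), its conservation category is
    flagged (absent or diverged in the focal clade), and its phylogenetic
    profile is ciliary-like -- either a pattern label in
    ``ciliary_patterns`` or a profile cluster listed in
    ``ciliary_profile_clusters``.  Genes whose expression-cluster
    signature group is in ``multiciliated_signature_groups`` rank first;
    ordering is deterministic on (rank, gene).
    """
    promising = []
    for rec in evidence:
        ciliary = bool(set(rec.profile_patterns) & set(ciliary_patterns)) or (
            rec.profile_cluster in set(ciliary_profile_clusters)
        )
        if (
            rec.annotation_count <= max_annotations
            and rec.conservation_category in FLAGGED
            and ciliary
        ):
            rec.promising = True
            promising.append(rec)
        else:
            rec.promising = False
    def rank(rec: CandidateEvidence):
        first = rec.cluster_signature_group in set(multiciliated_signature_groups)
        return (0 if first else 1, rec.gene)
    return sorted(promising, key=rank)


def evidence_frame(records: list[CandidateEvidence]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = asdict(rec)
        row["profile_patterns"] = ",".join(rec.profile_patterns)
        row["network_cluster"] = "" if rec.network_cluster is None else rec.network_cluster
        row["profile_cluster"] = "" if rec.profile_cluster is None else rec.profile_cluster
        rows.append(row)
    return pd.DataFrame(rows, columns=EVIDENCE_COLUMNS)


def write_report(
    records: list[CandidateEvidence], summaries: dict, out_dir: str | Path
) -> dict[str, Path]:
    """Write the evidence table, a text summary and a JSON summary.

    Deterministic given identical inputs: re-running produces identical
    bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "evidence": out / "evidence.tsv",
        "summary_txt": out / "summary.txt",
        "summary_json": out / "summary.json",
    }
    frame = evidence_frame(sorted(records, key=lambda r: r.gene))
    frame.to_csv(paths["evidence"], sep="\t", index=False)
    with open(paths["summary_json"], "w") as fh:
        json.dump(summaries, fh, indent=2, sort_keys=True)
        fh.write("\n")
    lines = ["candidate screen summary", "========================"]
    for key in sorted(summaries):
        lines.append(f"{key}: {json.dumps(summaries[key], sort_keys=True)}")
    with open(paths["summary_txt"], "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return paths
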