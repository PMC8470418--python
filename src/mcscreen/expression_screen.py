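"""Overexpression screen across multiciliation experiments.

Each differential-expression table is filtered for overexpressed genes
(logFC >= 1 and p <= 0.05 by default, both thresholds inclusive),
identifiers are harmonized to human symbols through ortholog maps, and
the per-experiment gene sets are compiled into a binary gene x experiment
matrix.  Gene profiles are clustered with the Jaccard distance, Ward.D2
linkage and a dynamic hybrid tree cut; clusters whose members are
overexpressed in a single experiment are discarded, and the surviving
clusters are summarized by regulator signatures (the set of experiments
in which most of the cluster responds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .hierarchy import ClusterAssignment, dynamic_hybrid_cut, ward_linkage

logger = logging.getLogger(__name__)

DEFAULT_LOGFC_MIN = 1.0
DEFAULT_P_MAX = 0.05
DEFAULT_DEEP_SPLIT = 2
DEFAULT_MIN_CLUSTER_SIZE = 20
DEFAULT_SIGNATURE_THRESHOLD = 0.5


@dataclass
class ExperimentTable:
    """One experiment's differential-expression results."""

    experiment_id: str
    data: pd.DataFrame  # columns: gene_id, logfc, pvalue

    def __post_init__(self) -> None:
        missing = [c for c in ("gene_id", "logfc", "pvalue") if c not in self.data.columns]
        if missing:
            raise ValueError(f"experiment {self.experiment_id}: missing columns {missing}")


def filter_overexpressed(
    table: ExperimentTable,
    logfc_min: float = DEFAULT_LOGFC_MIN,
    p_max: float = DEFAULT_P_MAX,
) -> set[str]:
    """Genes with logFC >= ``logfc_min`` and p <= ``p_max`` (inclusive).

    Duplicate gene rows keep the smallest p-value before thresholding.
    Rows with missing logFC or p-value raise, naming the offending genes.
    """
    if not (np.isfinite(logfc_min) and np.isfinite(p_max)):
        raise ValueError("thresholds must be finite")
    df = table.data
    bad = df[df["logfc"].isna() | df["pvalue"].isna()]
    if len(bad):
        names = ", ".join(map(str, bad["gene_id"].head(10)))
        raise ValueError(
            f"experiment {table.experiment_id}: missing logfc/pvalue for {names}"
        )
    if ((df["pvalue"] < 0) | (df["pvalue"] > 1)).any():
        raise ValueError(f"experiment {table.experiment_id}: p-values outside [0, 1]")
    dedup = df.sort_values(["gene_id", "pvalue"], kind="mergesort").drop_duplicates(
        "gene_id", keep="first"
    )
    kept = dedup[(dedup["logfc"] >= logfc_min) & (dedup["pvalue"] <= p_max)]
    return set(kept["gene_id"].astype(str))


def build_ortholog_lookup(pairs: pd.DataFrame) -> dict[str, set[str]]:
    """Many-to-many source gene -> set of human symbols."""
    if (pairs["source_gene"].astype(str).str.len() == 0).any() or (
        pairs["target_gene"].astype(str).str.len() == 0
    ).any():
        raise ValueError("ortholog map contains empty labels")
    lookup: dict[str, set[str]] = {}
    for src, tgt in zip(pairs["source_gene"], pairs["target_gene"]):
        lookup.setdefault(str(src), set()).add(str(tgt))
    return lookup


def harmonize_ids(
    gene_sets: dict[str, set[str]],
    maps: dict[str, dict[str, set[str]]],
    experiment_sources: dict[str, str | None],
) -> dict[str, set[str]]:
    """Map per-experiment gene sets to human symbols (union semantics).

    ``experiment_sources`` names the source organism of each experiment;
    a source of ``None`` or ``"human"`` leaves identifiers untouched.  A
    source gene with several human co-orthologs contributes all of them;
    unmapped genes are dropped and counted in the log.
    """
    harmonized: dict[str, set[str]] = {}
    for exp_id, genes in gene_sets.items():
        source = experiment_sources.get(exp_id)
        if source is None or source == "human":
            harmonized[exp_id] = set(genes)
            continue
        if source not in maps:
            raise ValueError(f"no ortholog map for source '{source}' (experiment {exp_id})")
        lookup = maps[source]
        mapped: set[str] = set()
        dropped = 0
        for g in genes:
            targets = lookup.get(g)
            if targets:
                mapped |= targets
            else:
                dropped += 1
        if dropped:
            logger.info("experiment %s: dropped %d unmapped genes", exp_id, dropped)
        harmonized[exp_id] = mapped
    return harmonized


def build_binary_matrix(gene_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Binary gene x experiment matrix; 1 = overexpressed in that experiment.

    Column order follows the input experiment order, rows are sorted
    lexicographically; every row has at least one nonzero cell.
    """
    if len(gene_sets) < 2:
        raise ValueError("need at least two experiments")
    union = sorted(set().union(*gene_sets.values()))
    if not union:
        raise ValueError("no overexpressed genes in any experiment")
    data = {exp: [1 if g in genes else 0 for g in union] for exp, genes in gene_sets.items()}
    matrix = pd.DataFrame(data, index=union, dtype=int)
    matrix.index.name = "gene"
    return matrix


def jaccard_distance(a, b) -> float:
    """1 - |a AND b| / |a OR b| for 0/1 vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    union = np.count_nonzero(a | b)
    if union == 0:
        raise ValueError("Jaccard distance undefined for two all-zero vectors")
    return 1.0 - np.count_nonzero(a & b) / union


def jaccard_distance_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """Pairwise Jaccard distances between the rows of a binary matrix."""
    X = matrix.to_numpy(dtype=bool)
    if (~X.any(axis=1)).any():
        raise ValueError("binary matrix has all-zero rows")
    return squareform(pdist(X, metric="jaccard"))


def cluster_expression_profiles(
    matrix: pd.DataFrame,
    deep_split: int = DEFAULT_DEEP_SPLIT,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
) -> ClusterAssignment:
    """Jaccard + Ward.D2 + dynamic hybrid cut on the gene rows."""
    D = jaccard_distance_matrix(matrix)
    Z = ward_linkage(D)
    assignment = dynamic_hybrid_cut(
        Z, D, deep_split=deep_split, min_cluster_size=min_cluster_size,
        items=list(matrix.index),
    )
    assignment.params["distance"] = "jaccard"
    return assignment


def drop_single_experiment_genes(
    matrix: pd.DataFrame, clusters: ClusterAssignment
) -> tuple[set[str], set[str], list[int]]:
    """Remove single-experiment clusters and single-experiment genes.

    A cluster is removed when every member is overexpressed in exactly one
    experiment; in addition any gene with a single overexpression call is
    excluded, so the retained set contains genes overexpressed in at least
    two experiments.  Retained and removed sets partition the matrix rows.
    """
    labels = clusters.as_dict()
    if set(labels) != set(matrix.index):
        raise ValueError("cluster assignment does not cover the matrix rows")
    row_sums = matrix.sum(axis=1)
    removed_clusters = []
    for cid in clusters.cluster_ids:
        members = clusters.members(cid)
        if all(row_sums[g] == 1 for g in members):
            removed_clusters.append(cid)
    removed = {g for g in matrix.index if row_sums[g] == 1 or labels[g] in removed_clusters}
    retained = set(matrix.index) - removed
    return retained, removed, removed_clusters


@dataclass
class ClusterSignature:
    """Per-cluster experiment activity fractions and derived signatures."""

    fractions: pd.DataFrame  # clusters x experiments, values in [0, 1]
    signature_threshold: float
    signatures: dict[int, frozenset] = field(default_factory=dict)
    groups: dict[tuple, list[int]] = field(default_factory=dict)


def cluster_signatures(
    matrix: pd.DataFrame,
    clusters: ClusterAssignment,
    signature_threshold: float = DEFAULT_SIGNATURE_THRESHOLD,
) -> ClusterSignature:
    """Fraction of each cluster's genes overexpressed per experiment.

    The signature of a cluster is the set of experiments where the
    fraction reaches ``signature_threshold``; clusters with identical
    signatures are grouped together.
    """
    labels = clusters.as_dict()
    if set(labels) != set(matrix.index):
        raise ValueError("cluster assignment does not cover the matrix rows")
    rows = {}
    for cid in clusters.cluster_ids:
        members = clusters.members(cid)
        if not members:
            raise ValueError(f"cluster {cid} is empty")
        rows[cid] = matrix.loc[members].mean(axis=0)
    fractions = pd.DataFrame(rows).T
    fractions.index.name = "cluster"
    signatures = {
        cid: frozenset(fractions.columns[fractions.loc[cid] >= signature_threshold])
        for cid in fractions.index
    }
    groups: dict[tuple, list[int]] = {}
    for cid, sig in signatures.items():
        groups.setdefault(tuple(sorted(sig)), []).append(cid)
    return ClusterSignature(
        fractions=fractions,
        signature_threshold=signature_threshold,
        signatures=signatures,
        groups={k: sorted(v) for k, v in groups.items()},
    )


@dataclass
class ExpressionScreenResult:
    matrix: pd.DataFrame
    clusters: ClusterAssignment
    retained: set[str]
    removed: set[str]
    removed_clusters: list[int]
    signatures: ClusterSignature


def run_expression_screen(
    tables: list[ExperimentTable],
    maps: dict[str, dict[str, set[str]]] | None = None,
    experiment_sources: dict[str, str | None] | None = None,
    logfc_min: float = DEFAULT_LOGFC_MIN,
    p_max: float = DEFAULT_P_MAX,
    deep_split: int = DEFAULT_DEEP_SPLIT,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    signature_threshold: float = DEFAULT_SIGNATURE_THRESHOLD,
) -> ExpressionScreenResult:
    """Full screen: filter, harmonize, build matrix, cluster, drop, sign."""
    gene_sets = {
        t.experiment_id: filter_overexpressed(t, logfc_min, p_max) for t in tables
    }
    if maps is not None:
        sources = experiment_sources or {t.experiment_id: None for t in tables}
        gene_sets = harmonize_ids(gene_sets, maps, sources)
    matrix = build_binary_matrix(gene_sets)
    clusters = cluster_expression_profiles(matrix, deep_split, min_cluster_size)
    retained, removed, removed_clusters = drop_single_experiment_genes(matrix, clusters)
    signatures = cluster_signatures(matrix, clusters, signature_threshold)
    return ExpressionScreenResult(
        matrix=matrix,
        clusters=clusters,
        retained=retained,
        removed=removed,
        removed_clusters=removed_clusters,
        signatures=signatures,
    )
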