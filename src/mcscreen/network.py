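"""Interaction-network expansion and community detection.

Starting from a candidate gene list and a weighted interaction edge list
(STRING-style), the neighborhood is expanded with two confidence
thresholds: list-list interactions are kept at a permissive score
(default 0.7) while external genes must interact with at least two list
genes at a stricter score (default 0.9) to be admitted.  The resulting
graph is partitioned into communities by greedy modularity maximization
(a deterministic surrogate for layout-based community clustering) and
summarized per community.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .hierarchy import ClusterAssignment

logger = logging.getLogger(__name__)

DEFAULT_T_INTERNAL = 0.7
DEFAULT_T_EXTERNAL = 0.9
DEFAULT_MIN_LIST_PARTNERS = 2


def normalize_scores(edges: pd.DataFrame, score_scale: str = "auto") -> pd.DataFrame:
    """Bring scores to [0, 1]; STRING ships 0-1000 integers.

    ``score_scale`` is "auto" (divide by 1000 when the maximum exceeds 1),
    "unit" (already in [0, 1]) or "milli" (always divide by 1000).
    """
    edges = edges.copy()
    scores = edges["score"].astype(float)
    if score_scale == "auto":
        score_scale = "milli" if scores.max() > 1.0 else "unit"
    if score_scale == "milli":
        scores = scores / 1000.0
    elif score_scale != "unit":
        raise ValueError(f"unknown score_scale: {score_scale}")
    if (scores < 0).any() or (scores > 1).any():
        raise ValueError("scores outside [0, 1] after normalization")
    edges["score"] = scores
    return edges


def expand_neighborhood(
    list_genes,
    edges: pd.DataFrame,
    t_internal: float = DEFAULT_T_INTERNAL,
    t_external: float = DEFAULT_T_EXTERNAL,
    min_list_partners: int = DEFAULT_MIN_LIST_PARTNERS,
    score_scale: str = "auto",
) -> nx.Graph:
    """Expand the candidate list into an interaction subnetwork.

    Rules (all thresholds inclusive): list-list edges are kept at score >=
    ``t_internal``; an external gene is admitted when it has edges at
    score >= ``t_external`` to at least ``min_list_partners`` distinct
    list genes, and only those qualifying edges are kept;
    external-external edges are kept when both endpoints are admitted and
    the score reaches ``t_external``.  List genes present in the edge
    table remain as nodes even when all their edges are filtered out;
    list genes absent from the edge table are skipped with a warning.
    """
    if not (0 <= t_internal <= t_external <= 1):
        raise ValueError("need 0 <= t_internal <= t_external <= 1")
    edges = normalize_scores(edges, score_scale)
    # canonical undirected form, best score per pair, no self-loops
    a = edges["gene_a"].astype(str)
    b = edges["gene_b"].astype(str)
    lo = np.where(a < b, a, b)
    hi = np.where(a < b, b, a)
    canon = pd.DataFrame({"u": lo, "v": hi, "score": edges["score"].to_numpy()})
    canon = canon[canon["u"] != canon["v"]]
    canon = canon.sort_values(["u", "v", "score"]).drop_duplicates(["u", "v"], keep="last")

    list_set = set(map(str, list_genes))
    seen = set(canon["u"]) | set(canon["v"])
    unknown = sorted(list_set - seen)
    if unknown:
        logger.warning("%d list genes not present in the edge table; skipped", len(unknown))
    anchored = sorted(list_set & seen)

    is_list_u = canon["u"].isin(list_set).to_numpy()
    is_list_v = canon["v"].isin(list_set).to_numpy()
    score = canon["score"].to_numpy()

    ll = canon[is_list_u & is_list_v & (score >= t_internal)]
    le = canon[(is_list_u ^ is_list_v) & (score >= t_external)]
    partners: dict[str, set[str]] = {}
    for u, v in zip(le["u"], le["v"]):
        ext, lst = (u, v) if v in list_set else (v, u)
        partners.setdefault(ext, set()).add(lst)
    admitted = {g for g, p in partners.items() if len(p) >= min_list_partners}
    le_kept = le[
        le.apply(lambda r: (r["u"] in admitted) or (r["v"] in admitted), axis=1)
    ] if len(le) else le
    ee = canon[
        ~is_list_u & ~is_list_v & (score >= t_external)
        & canon["u"].isin(admitted) & canon["v"].isin(admitted)
    ]

    G = nx.Graph()
    for g in anchored:
        G.add_node(g, is_list_member=True)
    for g in sorted(admitted):
        G.add_node(g, is_list_member=False)
    for part in (ll, le_kept, ee):
        for u, v, s in part[["u", "v", "score"]].itertuples(index=False):
            G.add_edge(u, v, score=float(s))
    return G


def detect_communities(graph: nx.Graph) -> ClusterAssignment:
    """Partition the graph by greedy modularity maximization.

    Communities are labeled 1..K ordered by decreasing size then smallest
    member; isolated nodes form singleton communities.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if graph.number_of_edges() == 0:
        comms = [{n} for n in graph.nodes]
    else:
        comms = [set(c) for c in nx.community.greedy_modularity_communities(
            graph, weight="score"
        )]
    comms.sort(key=lambda c: (-len(c), min(c)))
    nodes = sorted(graph.nodes)
    label_of = {}
    for lab, c in enumerate(comms, start=1):
        for node in c:
            label_of[node] = lab
    return ClusterAssignment(
        items=nodes,
        labels=np.array([label_of[n] for n in nodes]),
        params={"method": "greedy_modularity"},
    )


def summarize_clusters(
    graph: nx.Graph, communities: ClusterAssignment, candidate_list
) -> pd.DataFrame:
    """Per-community size and candidate-list membership counts."""
    if set(communities.items) != set(graph.nodes):
        raise ValueError("community assignment does not cover the graph nodes")
    cand = set(map(str, candidate_list))
    rows = []
    for cid in communities.cluster_ids:
        members = communities.members(cid)
        in_list = sorted(m for m in members if m in cand)
        rows.append(
            {
                "cluster": cid,
                "size": len(members),
                "n_list_members": len(in_list),
                "list_members": ",".join(in_list),
            }
        )
    df = pd.DataFrame(rows)
    assert df["size"].sum() == graph.number_of_nodes()
    return df
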