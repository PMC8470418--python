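"""Phylogenetic profiling: presence/absence profiles, clustering, patterns.

A phylogenetic profile is a binary vector of a gene's ortholog presence
across a species panel.  Profiles are compared with the correlation
distance 1 - Pearson(a, b), clustered with Ward.D2 and the dynamic
hybrid tree cut, and each cluster is annotated with clade-level patterns
(broadly present, absent in non-ciliated clades, absent in the focal
clade, metazoa- or chordate-restricted) computed from per-clade presence
fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hierarchy import ClusterAssignment, dynamic_hybrid_cut, ward_linkage

PRESENT_BROADLY = "PRESENT_BROADLY"
ABSENT_NONCILIATED = "ABSENT_NONCILIATED"
ABSENT_FOCAL_CLADE = "ABSENT_FOCAL_CLADE"
CHORDATE_RESTRICTED = "CHORDATE_RESTRICTED"
METAZOA_RESTRICTED = "METAZOA_RESTRICTED"
NONE_PATTERN = "NONE"

#: patterns compatible with a ciliary or multiciliary phylogenetic history
CILIARY_PATTERNS = frozenset(
    {ABSENT_NONCILIATED, ABSENT_FOCAL_CLADE, CHORDATE_RESTRICTED, METAZOA_RESTRICTED}
)

MAX_CORRELATION_DISTANCE = 2.0  # sentinel for constant (undefined) profiles

DEFAULT_TAU_ABSENT = 0.1
DEFAULT_TAU_PRESENT = 0.6


def build_profile_matrix(presence: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    """Align a gene x species presence table to the panel's species order."""
    panel_species = list(panel["species"])
    missing = [s for s in presence.columns if s not in set(panel_species)]
    if missing:
        raise ValueError(f"species missing from panel: {missing[:5]}")
    ordered = [s for s in panel_species if s in presence.columns]
    matrix = presence[ordered].astype(int)
    matrix.index.name = "gene"
    return matrix


def correlation_distance(a, b) -> float:
    """1 - Pearson(a, b); constant vectors get the maximal sentinel distance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if a.size < 2:
        raise ValueError("vectors must have length >= 2")
    if a.std() == 0 or b.std() == 0:
        return MAX_CORRELATION_DISTANCE
    r = np.corrcoef(a, b)[0, 1]
    return float(1.0 - r)


def correlation_distance_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """Pairwise correlation distances between profile rows.

    Rows that are constant (all present or all absent) have an undefined
    Pearson correlation; they are placed at the sentinel distance 2 from
    every other row so clustering stays total.
    """
    X = matrix.to_numpy(dtype=float)
    n = X.shape[0]
    std = X.std(axis=1)
    constant = std == 0
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(X)
    D = 1.0 - C
    D[constant, :] = MAX_CORRELATION_DISTANCE
    D[:, constant] = MAX_CORRELATION_DISTANCE
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, MAX_CORRELATION_DISTANCE)
    return (D + D.T) / 2.0


def cluster_profiles(
    matrix: pd.DataFrame, deep_split: int = 2, min_cluster_size: int = 20
) -> ClusterAssignment:
    """Correlation distance + Ward.D2 + dynamic hybrid cut on profile rows."""
    if len(matrix) < 2:
        raise ValueError("need at least two gene profiles")
    D = correlation_distance_matrix(matrix)
    Z = ward_linkage(D)
    assignment = dynamic_hybrid_cut(
        Z, D, deep_split=deep_split, min_cluster_size=min_cluster_size,
        items=list(matrix.index),
    )
    assignment.params["distance"] = "correlation"
    return assignment


@dataclass
class ProfileClusterAnnotation:
    """Pattern labels and per-clade presence fractions per profile cluster."""

    patterns: dict[int, list[str]]
    clade_fractions: pd.DataFrame  # clusters x clade groups


def _clade_masks(panel: pd.DataFrame, vertebrate_subclades) -> dict[str, np.ndarray]:
    subclade = panel["subclade"].to_numpy()
    vertebrate = np.isin(subclade, list(vertebrate_subclades))
    focal = panel["focal"].to_numpy(bool)
    return {
        "all": np.ones(len(panel), bool),
        "ciliated": panel["ciliated"].to_numpy(bool),
        "non_ciliated": ~panel["ciliated"].to_numpy(bool),
        "focal": focal,
        "non_focal_vertebrate": vertebrate & ~focal,
        "metazoa": (panel["supergroup"] == "Metazoa").to_numpy(),
        "non_metazoa": (panel["supergroup"] != "Metazoa").to_numpy(),
        "chordate": (panel["clade"] == "Chordata").to_numpy(),
        "non_chordate": (panel["clade"] != "Chordata").to_numpy(),
        "supergroups_min": np.zeros(len(panel), bool),  # placeholder, filled below
    }


def annotate_clusters(
    matrix: pd.DataFrame,
    clusters: ClusterAssignment,
    panel: pd.DataFrame,
    tau_absent: float = DEFAULT_TAU_ABSENT,
    tau_present: float = DEFAULT_TAU_PRESENT,
    vertebrate_subclades=("Vertebrata", "Otomorpha"),
) -> ProfileClusterAnnotation:
    """Label profile clusters by their per-clade presence fractions.

    A cluster is ABSENT_FOCAL_CLADE when its focal-clade presence fraction
    is at most ``tau_absent`` while non-focal vertebrates reach
    ``tau_present``; ABSENT_NONCILIATED when non-ciliated clades fall at or
    below ``tau_absent`` and ciliated clades reach ``tau_present``;
    CHORDATE_/METAZOA_RESTRICTED when presence concentrates inside that
    clade; PRESENT_BROADLY when every supergroup reaches ``tau_present``.
    Labels may co-occur and are reported sorted; NONE when nothing matches.
    """
    labels = clusters.as_dict()
    if set(labels) != set(matrix.index):
        raise ValueError("cluster assignment does not cover the matrix rows")
    panel = panel.set_index("species").loc[list(matrix.columns)].reset_index()
    masks = _clade_masks(panel, vertebrate_subclades)
    supergroups = sorted(panel["supergroup"].unique())

    X = matrix.to_numpy(float)
    patterns: dict[int, list[str]] = {}
    rows = {}
    for cid in clusters.cluster_ids:
        member_idx = [i for i, g in enumerate(matrix.index) if labels[g] == cid]
        sub = X[member_idx]
        frac = {
            name: float(sub[:, mask].mean()) if mask.any() else float("nan")
            for name, mask in masks.items()
            if name != "supergroups_min"
        }
        sg_fracs = [
            float(sub[:, (panel["supergroup"] == sg).to_numpy()].mean())
            for sg in supergroups
        ]
        frac["supergroups_min"] = min(sg_fracs)
        rows[cid] = frac

        found = []
        if frac["supergroups_min"] >= tau_present:
            found.append(PRESENT_BROADLY)
        if frac["non_ciliated"] <= tau_absent and frac["ciliated"] >= tau_present:
            found.append(ABSENT_NONCILIATED)
        if frac["focal"] <= tau_absent and frac["non_focal_vertebrate"] >= tau_present:
            found.append(ABSENT_FOCAL_CLADE)
        if frac["non_chordate"] <= tau_absent and frac["chordate"] >= tau_present:
            found.append(CHORDATE_RESTRICTED)
        if frac["non_metazoa"] <= tau_absent and frac["metazoa"] >= tau_present:
            found.append(METAZOA_RESTRICTED)
        patterns[cid] = sorted(found) if found else [NONE_PATTERN]

    clade_fractions = pd.DataFrame(rows).T
    clade_fractions.index.name = "cluster"
    return ProfileClusterAnnotation(patterns=patterns, clade_fractions=clade_fractions)
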