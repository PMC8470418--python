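"""Readers and writers for the flat TSV formats the pipeline exchanges.

All tables are plain tab-separated text with headers; identity lists are
comma-joined inside a single field.  Writers sort deterministically so
re-running a step reproduces byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

DE_COLUMNS = ["gene_id", "logfc", "pvalue"]
CLADE_COLUMNS = [
    "gene", "focal_presence", "n_focal", "ref_presence", "n_ref",
    "focal_identities", "ref_identities",
]
PANEL_COLUMNS = ["species", "supergroup", "clade", "subclade", "ciliated", "focal"]
EDGE_COLUMNS = ["gene_a", "gene_b", "score"]


def read_experiment_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df[DE_COLUMNS]


def write_experiment_table(df: pd.DataFrame, path: str | Path) -> None:
    df[DE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_ortholog_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["source_gene", "target_gene"]:
        raise ValueError(f"{path}: expected columns source_gene, target_gene")
    return df


def write_ortholog_map(df: pd.DataFrame, path: str | Path) -> None:
    df[["source_gene", "target_gene"]].to_csv(path, sep="\t", index=False)


def read_binary_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int)


def write_binary_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.astype(int)
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_cluster_assignment(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["cluster"].to_numpy(int), index=df["gene"], name="cluster")


def write_cluster_assignment(labels: pd.Series, path: str | Path) -> None:
    df = pd.DataFrame({"gene": labels.index, "cluster": labels.to_numpy(int)})
    df.to_csv(path, sep="\t", index=False)


def _join_ids(values) -> str:
    return ",".join(repr(float(v)) for v in values)


def _split_ids(text) -> list[float]:
    if isinstance(text, float) and np.isnan(text):
        return []
    text = str(text).strip()
    if not text:
        return []
    return [float(x) for x in text.split(",")]


def read_clade_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    missing = [c for c in CLADE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[CLADE_COLUMNS].copy()
    for col in ("focal_presence", "n_focal", "ref_presence", "n_ref"):
        df[col] = df[col].astype(int)
    df["focal_identities"] = df["focal_identities"].map(_split_ids)
    df["ref_identities"] = df["ref_identities"].map(_split_ids)
    return df


def write_clade_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df[CLADE_COLUMNS].copy()
    out["focal_identities"] = out["focal_identities"].map(_join_ids)
    out["ref_identities"] = out["ref_identities"].map(_join_ids)
    out.to_csv(path, sep="\t", index=False)


def read_species_panel(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["ciliated"] = df["ciliated"].astype(bool)
    df["focal"] = df["focal"].astype(bool)
    return df[PANEL_COLUMNS]


def write_species_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel[PANEL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df[EDGE_COLUMNS]


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges[EDGE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("term_id", "term_name", "gene") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df[["term_id", "term_name", "gene"]]


def write_annotation_table(df: pd.DataFrame, path: str | Path) -> None:
    df[["term_id", "term_name", "gene"]].to_csv(path, sep="\t", index=False)
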