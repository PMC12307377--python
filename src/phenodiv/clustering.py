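"""Hierarchical clustering of accessions and per-cluster trait profiles.

Accessions are clustered agglomeratively on Euclidean distances over
z-scored traits (Ward linkage by default - the standard choice for trait
dendrograms; average and complete linkage are available for sensitivity
runs). The tree is cut into k groups (default 5) and labels are renumbered
by descending cluster size, ties broken by the first member's position, so
reports are stable across runs and row permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .errors import AlignmentError, ConfigurationError
from .traits import PhenotypeTable

LINKAGES = ("ward", "average", "complete")


@dataclass
class ClusterResult:
    """Cut dendrogram: per-accession labels plus the merge history.

    ``merge_history`` is the scipy linkage matrix (rows: merged node ids,
    merge height, new cluster size).
    """

    assignments: pd.Series  # accession_id -> label 1..k
    merge_history: np.ndarray
    k: int
    labels: list[str]  # leaf order of merge_history

    @property
    def sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()


def hierarchical_cluster(
    z: pd.DataFrame, linkage: str = "ward", k: int = 5
) -> ClusterResult:
    """Cluster rows of a (standardized) trait matrix and cut at k groups."""
    if linkage not in LINKAGES:
        raise ConfigurationError(
            f"linkage must be one of {LINKAGES}, got {linkage!r}"
        )
    n = len(z)
    if not 1 <= k <= n:
        raise ConfigurationError(f"need 1 <= k <= n={n}, got k={k}")
    x = z.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ConfigurationError("clustering input contains missing values")
    merge = hierarchy.linkage(x, method=linkage, metric="euclidean")
    raw = hierarchy.fcluster(merge, t=k, criterion="maxclust")
    # renumber labels: descending size, then first occurrence
    order = {}
    sizes = pd.Series(raw).value_counts()
    first_pos = {lab: int(np.argmax(raw == lab)) for lab in sizes.index}
    ranked = sorted(sizes.index, key=lambda lab: (-sizes[lab], first_pos[lab]))
    order = {lab: i + 1 for i, lab in enumerate(ranked)}
    labels = pd.Series(
        [order[lab] for lab in raw], index=z.index, name="cluster"
    )
    return ClusterResult(
        assignments=labels,
        merge_history=merge,
        k=int(k),
        labels=[str(i) for i in z.index],
    )


def cluster_profiles(
    table: PhenotypeTable, result: ClusterResult
) -> pd.DataFrame:
    """Per-cluster, per-trait summaries (mean, sd, min, quartiles, max).

    Long format: one row per (cluster, trait); this is the numeric backbone
    of violin-plot panels of cluster phenotypes.
    """
    ids = set(table.data["accession_id"].astype(str))
    unknown = [i for i in result.assignments.index.astype(str) if i not in ids]
    if unknown:
        raise AlignmentError(
            f"assignments contain unknown accession(s): {unknown[:5]}"
        )
    values = table.values()
    joined = values.join(result.assignments, how="inner")
    if len(joined) != len(result.assignments):
        raise AlignmentError("assignments do not cover the table")
    rows = []
    for (label, trait), grp in (
        joined.melt(id_vars="cluster", var_name="trait")
        .groupby(["cluster", "trait"], sort=True)
    ):
        v = grp["value"].dropna()
        rows.append(
            {
                "cluster": label,
                "trait": trait,
                "n": int(len(v)),
                "mean": v.mean(),
                "sd": v.std(ddof=1) if len(v) > 1 else 0.0,
                "min": v.min(),
                "q25": v.quantile(0.25),
                "median": v.median(),
                "q75": v.quantile(0.75),
                "max": v.max(),
            }
        )
    out = pd.DataFrame(rows)
    trait_order = {t.abbreviation: i for i, t in enumerate(table.registry)}
    out["__o"] = out["trait"].map(trait_order)
    out = (
        out.sort_values(["cluster", "__o"])
        .drop(columns="__o")
        .reset_index(drop=True)
    )
    return out


def to_newick(result: ClusterResult) -> str:
    """Dendrogram as a newick string; leaf names are accession ids and
    branch lengths are derived from merge heights."""
    tree = hierarchy.to_tree(result.merge_history)
    labels = result.labels

    def build(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({build(tree.left, tree.dist)},{build(tree.right, tree.dist)});"
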