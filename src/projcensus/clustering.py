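"""Row clustering of connectivity matrices and cluster-level statistics.

Agglomerative clustering with complete linkage on 1 - Spearman rank
correlation, plus Fisher-exact layer enrichment, within-cluster similarity,
and ANOVA/Tukey cluster contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .tracer import ConnectivityMatrix


@dataclass
class Dendrogram:
    """Complete-linkage merge tree over matrix rows (heights = 1 - rho)."""

    linkage: np.ndarray  # scipy linkage matrix
    leaf_ids: list[str]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return self.leaf_ids[node.id]
            left, right = node.get_left(), node.get_right()
            dl = node.dist - left.dist
            dr = node.dist - right.dist
            return f"({render(left)}:{dl:.6g},{render(right)}:{dr:.6g})"

        return render(tree) + ";"


@dataclass
class ClusterAssignment:
    labels: pd.Series  # row id -> cluster label in 1..k
    k: int

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])


def _as_frame(matrix) -> pd.DataFrame:
    return matrix.data if isinstance(matrix, ConnectivityMatrix) else matrix


def spearman_distance_matrix(frame: pd.DataFrame) -> np.ndarray:
    """Pairwise 1 - Spearman rho over mutually observed (non-NaN) columns."""
    values = frame.to_numpy(dtype=float)
    n = len(values)
    observed = ~np.isnan(values)
    for i, row_id in enumerate(frame.index):
        row = values[i][observed[i]]
        if row.size < 2 or np.all(row == row[0]):
            raise ValueError(
                f"row {row_id!r} is constant; Spearman correlation undefined"
            )
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = observed[i] & observed[j]
            if both.sum() < 2:
                raise ValueError(
                    f"rows {frame.index[i]!r}, {frame.index[j]!r} share <2 observed targets"
                )
            rho = stats.spearmanr(values[i][both], values[j][both]).statistic
            if np.isnan(rho):  # a row constant on the common support
                rho = 0.0
            dist[i, j] = dist[j, i] = 1.0 - rho
    return dist


def spearman_complete_cluster(
    matrix, k: int
) -> tuple[Dendrogram, ClusterAssignment]:
    """Cluster rows (complete linkage, Spearman distance) and cut at k clusters."""
    frame = _as_frame(matrix)
    if len(frame) < 2:
        raise ValueError("need at least 2 rows to cluster")
    if k > len(frame):
        raise ValueError(f"k={k} exceeds row count {len(frame)}")
    dist = spearman_distance_matrix(frame)
    condensed = dist[np.triu_indices(len(frame), k=1)]
    linkage = hierarchy.linkage(condensed, method="complete")
    raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    # relabel 1..k in order of first appearance for determinism
    relabel, next_label = {}, 1
    labels = np.empty(len(raw), dtype=int)
    for i, lab in enumerate(raw):
        if lab not in relabel:
            relabel[lab] = next_label
            next_label += 1
        labels[i] = relabel[lab]
    assignment = ClusterAssignment(
        labels=pd.Series(labels, index=frame.index, name="cluster"), k=k
    )
    return Dendrogram(linkage, list(frame.index)), assignment


def layer_enrichment(
    assignment: ClusterAssignment, layer_of_row: pd.Series
) -> pd.DataFrame:
    """Two-sided Fisher exact test per (cluster, layer) 2x2 in/out table."""
    labels = assignment.labels
    missing = set(labels.index) - set(layer_of_row.index)
    if missing:
        raise ValueError(f"rows without a layer label: {sorted(missing)[:5]}")
    layers = layer_of_row.loc[labels.index]
    records = []
    for cluster in sorted(labels.unique()):
        in_cluster = labels == cluster
        if not in_cluster.any():
            warnings.warn(f"cluster {cluster} is empty; skipped")
            continue
        for layer in sorted(layers.unique()):
            in_layer = layers == layer
            table = [
                [int((in_cluster & in_layer).sum()), int((in_cluster & ~in_layer).sum())],
                [int((~in_cluster & in_layer).sum()), int((~in_cluster & ~in_layer).sum())],
            ]
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            records.append(
                {"cluster": cluster, "layer": layer, "odds_ratio": odds, "p_value": p}
            )
    return pd.DataFrame.from_records(records)


def within_cluster_similarity(matrix, assignment: ClusterAssignment) -> pd.Series:
    """Mean pairwise Spearman rho over all unordered within-cluster pairs."""
    frame = _as_frame(matrix)
    dist = spearman_distance_matrix(frame)
    rho = 1.0 - dist
    out = {}
    index = {row_id: i for i, row_id in enumerate(frame.index)}
    for cluster in sorted(assignment.labels.unique()):
        members = [index[m] for m in assignment.members(cluster)]
        if len(members) < 2:
            out[cluster] = np.nan
            continue
        ii, jj = np.triu_indices(len(members), k=1)
        pairs = rho[np.ix_(members, members)][ii, jj]
        out[cluster] = float(pairs.mean())
    return pd.Series(out, name="mean_spearman")


def _mixed_anova_interaction(
    values: np.ndarray, clusters: np.ndarray
) -> tuple[float, float]:
    """Split-plot ANOVA interaction (between = cluster, within = target area).

    Rows are subjects (experiments/cells), columns repeated measures.
    Returns (F, p) for the cluster x area interaction. Classic sums of
    squares; groups may be unbalanced.
    """
    n, t = values.shape
    grand = values.mean()
    groups = [values[clusters == c] for c in np.unique(clusters)]
    ss_area = float(n * ((values.mean(axis=0) - grand) ** 2).sum())
    ss_between = 0.0
    ss_cells = 0.0  # cluster x area cell means about grand mean
    for g in groups:
        ng = len(g)
        ss_between += ng * t * (g.mean() - grand) ** 2
        ss_cells += ng * float(((g.mean(axis=0) - grand) ** 2).sum())
    ss_interaction = ss_cells - ss_between - ss_area
    subject_means = values.mean(axis=1)
    ss_subjects = t * float(((subject_means - grand) ** 2).sum())
    ss_total = float(((values - grand) ** 2).sum())
    ss_within_subj = ss_total - ss_subjects
    ss_within_subj_err = ss_within_subj - ss_area - ss_interaction
    k = len(groups)
    df_inter = (k - 1) * (t - 1)
    df_err = (n - k) * (t - 1)
    if df_inter <= 0 or df_err <= 0 or ss_within_subj_err <= 0:
        return np.nan, np.nan
    f_stat = (ss_interaction / df_inter) / (ss_within_subj_err / df_err)
    p = float(stats.f.sf(f_stat, df_inter, df_err))
    return float(f_stat), p


def cluster_contrasts(matrix, assignment: ClusterAssignment) -> dict:
    """One-way ANOVA + Tukey on per-row nonzero-target counts, and a
    two-way repeated-measures (split-plot) interaction test of
    cluster x target area on the fraction values."""
    frame = _as_frame(matrix)
    labels = assignment.labels.loc[frame.index]
    counts = (frame > 0).sum(axis=1).to_numpy(dtype=float)
    clusters = labels.to_numpy()
    groups = [counts[clusters == c] for c in np.unique(clusters)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 clusters with >=2 members")
    report: dict = {}
    if all(np.var(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        report["anova_indegree"] = {"F": 0.0, "p": 1.0, "testable": False}
    else:
        f_stat, p = stats.f_oneway(*groups)
        report["anova_indegree"] = {"F": float(f_stat), "p": float(p), "testable": True}
        tukey = pairwise_tukeyhsd(counts, clusters)
        report["tukey_indegree"] = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )
    values = np.nan_to_num(frame.to_numpy(dtype=float))
    f_int, p_int = _mixed_anova_interaction(values, clusters)
    report["interaction_cluster_by_target"] = {
        "F": f_int,
        "p": p_int,
        "testable": bool(np.isfinite(f_int)),
    }
    return report
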