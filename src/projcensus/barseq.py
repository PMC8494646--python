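"""Barcoded single-neuron projection analysis.

Count matrices of neurons x dissected target areas are spike-in normalized,
scaled so per-area means over projecting neurons match across brains, and
clustered into major classes by bisecting k-means on log strengths. Binary
projection subgroups are then split off recursively by maximizing the
reduction in Shannon entropy of the laminar (soma-depth) distribution, with
permutation significance, and re-merged when laminar distributions are
indistinguishable (rank-sum + median-window rule) within a major class.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import BisectingKMeans

DEPTH_BIN_WIDTH = 25.0  # um, laminar entropy discretization


@dataclass
class BarcodeDataset:
    """Neurons x areas barcode counts with spike-ins and soma metadata."""

    counts: pd.DataFrame  # nonnegative integers
    spikein: pd.Series
    soma_depth: pd.Series  # um from pia
    brain_id: pd.Series
    soma_ml: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.counts.index
        for name, series in [
            ("spikein", self.spikein),
            ("soma_depth", self.soma_depth),
            ("brain_id", self.brain_id),
        ]:
            if not idx.equals(series.index):
                raise ValueError(f"{name} index does not match counts index")
        if (self.counts.to_numpy() < 0).any() or (self.spikein < 0).any():
            raise ValueError("counts and spike-ins must be nonnegative")

    @property
    def areas(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_neurons(self) -> int:
        return len(self.counts)


@dataclass
class NormalizedProjections:
    """Spike-in- and brain-normalized projection strengths."""

    values: pd.DataFrame
    log_values: pd.DataFrame
    soma_depth: pd.Series
    brain_id: pd.Series
    scale_factors: pd.DataFrame  # brains x areas


def normalize_barcodes(data: BarcodeDataset) -> NormalizedProjections:
    """Spike-in normalization, then per-area cross-brain mean matching.

    Step 1 divides each neuron's counts by its spike-in count (neurons with a
    zero spike-in are dropped with a warning). Step 2 rescales each brain per
    area so that the mean over neurons with nonzero counts equals that of the
    reference (first) brain; areas with no projecting neurons in a brain keep
    factor 1. ``log_values`` holds log1p of the result.
    """
    keep = data.spikein > 0
    if not keep.all():
        warnings.warn(
            f"dropping {(~keep).sum()} neurons with zero spike-in counts"
        )
    counts = data.counts.loc[keep]
    values = counts.div(data.spikein.loc[keep], axis=0)
    brains = list(pd.unique(data.brain_id.loc[keep]))
    factors = pd.DataFrame(1.0, index=brains, columns=data.areas)
    if len(brains) > 1:
        nonzero = counts > 0
        for area in data.areas:
            means = {}
            for brain in brains:
                sel = (data.brain_id.loc[keep] == brain) & nonzero[area]
                if sel.any():
                    means[brain] = values.loc[sel, area].mean()
            if not means:
                continue
            reference = next(b for b in brains if b in means)
            for brain in brains:
                if brain in means:
                    factors.loc[brain, area] = means[reference] / means[brain]
                else:
                    warnings.warn(
                        f"area {area!r}: no projecting neurons in brain {brain!r}; "
                        "scale factor left at 1"
                    )
        scale = factors.loc[data.brain_id.loc[keep]].to_numpy()
        values = values * scale
    return NormalizedProjections(
        values=values,
        log_values=np.log1p(values),
        soma_depth=data.soma_depth.loc[keep],
        brain_id=data.brain_id.loc[keep],
        scale_factors=factors,
    )


def binarize(norm: NormalizedProjections, threshold: float = 0.0) -> pd.DataFrame:
    """Projection presence flags: normalized strength strictly above threshold."""
    return norm.values > threshold


# ---------------------------------------------------------------------------
# major classes


def major_class_clustering(
    norm: NormalizedProjections, n_classes: int = 4, seed: int = 0
) -> pd.Series:
    """Bisecting k-means on log-transformed strengths into n_classes clusters."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    model = BisectingKMeans(
        n_clusters=n_classes, random_state=seed, n_init=10, init="k-means++"
    )
    labels = model.fit_predict(norm.log_values.to_numpy())
    return pd.Series(labels, index=norm.values.index, name="major_class")


def annotate_major_classes(
    labels: pd.Series,
    norm: NormalizedProjections,
    area_roles: dict[str, list[str]],
) -> dict[int, str]:
    """Name 4 clusters CT / L5 ET / IT Str+ / IT Str- from role-area means.

    ``area_roles`` maps 'thalamus', 'brainstem' and 'striatum' to lists of
    area names. ET is the cluster with the highest mean brainstem strength,
    CT the highest thalamus strength among the rest, and the remaining two
    are IT Str+/- by striatal strength.
    """
    clusters = sorted(labels.unique())
    if len(clusters) != 4:
        raise ValueError("annotation defined for exactly 4 clusters")
    means = {
        role: {
            c: norm.values.loc[labels == c, areas].to_numpy().mean()
            for c in clusters
        }
        for role, areas in area_roles.items()
    }
    names: dict[int, str] = {}
    et = max(clusters, key=lambda c: means["brainstem"][c])
    names[et] = "L5 ET"
    rest = [c for c in clusters if c != et]
    ct = max(rest, key=lambda c: means["thalamus"][c])
    names[ct] = "CT"
    it = [c for c in rest if c != ct]
    strp = max(it, key=lambda c: means["striatum"][c])
    names[strp] = "IT Str+"
    names[next(c for c in it if c != strp)] = "IT Str-"
    return names


# ---------------------------------------------------------------------------
# entropy-reduction binary-projection splitting


@dataclass
class SplitNode:
    """Internal node of the subgroup tree: one accepted binary-pattern split."""

    areas: tuple[str, ...]
    pattern: tuple[int, ...]  # required presence(1)/absence(0) per area
    delta_h: float  # entropy reduction, bits
    p_value: float
    match: "SplitNode | LeafNode" = None  # neurons satisfying the pattern
    rest: "SplitNode | LeafNode" = None


@dataclass
class LeafNode:
    neuron_ids: list[str]
    label: int = -1


@dataclass
class SubgroupTree:
    root: SplitNode | LeafNode
    labels: pd.Series = field(default=None)  # neuron id -> leaf label

    def leaves(self) -> list[LeafNode]:
        out: list[LeafNode] = []

        def walk(node) -> None:
            if isinstance(node, LeafNode):
                out.append(node)
            else:
                walk(node.match)
                walk(node.rest)

        walk(self.root)
        return out


def _entropy_bits(counts: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shannon entropy in bits of count vectors along ``axis``."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=axis, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, counts / np.where(totals == 0, 1, totals), 0)
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1)), 0.0)
    return -(p * logp).sum(axis=axis)


def _enumerate_patterns(
    areas: list[str], max_areas: int
) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All (area index combo, presence/absence pattern) up to max_areas areas."""
    out = []
    for size in range(1, max_areas + 1):
        for combo in itertools.combinations(range(len(areas)), size):
            for bits in itertools.product((0, 1), repeat=size):
                out.append((combo, bits))
    return out


def _membership_matrix(
    binary: np.ndarray, patterns
) -> np.ndarray:
    """Boolean (neurons x patterns): neuron satisfies the pattern exactly."""
    n = binary.shape[0]
    M = np.empty((n, len(patterns)), dtype=bool)
    for j, (combo, bits) in enumerate(patterns):
        m = np.ones(n, dtype=bool)
        for a, bit in zip(combo, bits):
            m &= binary[:, a] == bool(bit)
        M[:, j] = m
    return M


def _split_deltas(M: np.ndarray, onehot: np.ndarray) -> np.ndarray:
    """Entropy reduction for every candidate pattern split (vectorized).

    ``M``: neurons x patterns membership, ``onehot``: neurons x depth-bins.
    Degenerate splits (empty side) get -inf.
    """
    n = M.shape[0]
    total = onehot.sum(axis=0)
    h_parent = _entropy_bits(total)
    c_in = M.T.astype(float) @ onehot  # patterns x bins
    c_out = total[None, :] - c_in
    n_in = c_in.sum(axis=1)
    n_out = n - n_in
    h_in = _entropy_bits(c_in, axis=1)
    h_out = _entropy_bits(c_out, axis=1)
    with np.errstate(invalid="ignore"):
        delta = h_parent - (n_in * h_in + n_out * h_out) / n
    delta[(n_in == 0) | (n_out == 0)] = -np.inf
    return delta


def entropy_split(
    binary: pd.DataFrame,
    depths: pd.Series,
    max_areas: int = 3,
    alpha: float = 0.05,
    n_perm: int = 999,
    min_node: int = 20,
    bin_width: float = DEPTH_BIN_WIDTH,
    seed: int = 0,
    null: str = "max",
) -> SubgroupTree:
    """Recursive binary-projection partitioning by laminar entropy reduction.

    At each node every presence/absence pattern over up to ``max_areas`` areas
    is scored by the reduction in Shannon entropy (bits) of the 25-um-binned
    soma-depth distribution. The best split is kept if its permutation
    p-value (depths shuffled within the node) is below ``alpha``; recursion
    continues on both sides until nodes are too small or no significant
    reduction remains.

    ``null='max'`` re-maximizes over all candidate patterns in each
    permutation (controls the selection effect of choosing the best pattern);
    ``null='fixed'`` permutes only the chosen split's partition.
    """
    if null not in ("max", "fixed"):
        raise ValueError("null must be 'max' or 'fixed'")
    rng = np.random.default_rng(seed)
    areas = list(binary.columns)
    B = binary.to_numpy(dtype=bool)
    bins = np.floor(depths.loc[binary.index].to_numpy(dtype=float) / bin_width).astype(int)
    n_bins = int(bins.max()) + 1 if len(bins) else 1
    patterns = _enumerate_patterns(areas, max_areas)

    def build(idx: np.ndarray):
        node_ids = list(binary.index[idx])
        if len(idx) < max(2, min_node):
            return LeafNode(node_ids)
        onehot = np.zeros((len(idx), n_bins))
        onehot[np.arange(len(idx)), bins[idx]] = 1.0
        if _entropy_bits(onehot.sum(axis=0)) == 0:  # all in one depth bin
            return LeafNode(node_ids)
        M = _membership_matrix(B[idx], patterns)
        deltas = _split_deltas(M, onehot)
        best = int(np.argmax(deltas))
        if not np.isfinite(deltas[best]) or deltas[best] <= 0:
            return LeafNode(node_ids)
        observed = deltas[best]
        exceed = 0
        Mf = M.astype(float)
        member_best = M[:, best]
        for _ in range(n_perm):
            perm = rng.permutation(len(idx))
            if null == "max":
                stat = np.max(_split_deltas(Mf, onehot[perm]))
            else:
                c_in = member_best.astype(float) @ onehot[perm]
                c_all = onehot.sum(axis=0)
                n_in = c_in.sum()
                stat = _entropy_bits(c_all) - (
                    n_in * _entropy_bits(c_in)
                    + (len(idx) - n_in) * _entropy_bits(c_all - c_in)
                ) / len(idx)
            if stat >= observed:
                exceed += 1
        p = (1 + exceed) / (n_perm + 1)
        if p >= alpha:
            return LeafNode(node_ids)
        combo, bits = patterns[best]
        node = SplitNode(
            areas=tuple(areas[a] for a in combo),
            pattern=tuple(bits),
            delta_h=float(observed),
            p_value=float(p),
        )
        node.match = build(idx[member_best])
        node.rest = build(idx[~member_best])
        return node

    root = build(np.arange(len(binary)))
    tree = SubgroupTree(root=root)
    labels = pd.Series(index=binary.index, dtype=int, name="subgroup")
    for i, leaf in enumerate(tree.leaves(), start=1):
        leaf.label = i
        labels.loc[leaf.neuron_ids] = i
    tree.labels = labels
    return tree


# ---------------------------------------------------------------------------
# laminar merging


def merge_by_laminae(
    tree: SubgroupTree,
    norm: NormalizedProjections,
    major_class: pd.Series,
    alpha: float = 0.05,
    median_window: float = 200.0,
    bonferroni: str = "pass",
) -> pd.Series:
    """Merge subgroup leaves with indistinguishable laminar distributions.

    Candidate merges are pairs of current groups sharing a major class,
    examined from the smallest Euclidean distance between mean projection
    vectors. A pair merges iff the rank-sum test on soma depths is
    non-significant after Bonferroni correction (over the candidates examined
    in the current pass, or globally with ``bonferroni='global'``) and the
    group depth medians differ by at most ``median_window`` um. Passes repeat
    until no merge applies.
    """
    if bonferroni not in ("pass", "global"):
        raise ValueError("bonferroni must be 'pass' or 'global'")
    labels = tree.labels.copy()
    depths = norm.soma_depth.loc[labels.index]
    values = norm.values.loc[labels.index]
    classes = major_class.loc[labels.index]

    def group_class(group: int) -> object:
        # groups never span classes if leaves are class-pure; else majority
        return classes[labels == group].mode().iloc[0]

    total_candidates_examined = 0
    while True:
        groups = sorted(labels.unique())
        if len(groups) < 2:
            break
        means = {g: values[labels == g].mean(axis=0).to_numpy() for g in groups}
        gclass = {g: group_class(g) for g in groups}
        candidates = [
            (float(np.linalg.norm(means[a] - means[b])), a, b)
            for a, b in itertools.combinations(groups, 2)
            if gclass[a] == gclass[b]
        ]
        if not candidates:
            break
        candidates.sort()
        m_pass = len(candidates)
        merged = False
        for _, a, b in candidates:
            total_candidates_examined += 1
            da = depths[labels == a].to_numpy()
            db = depths[labels == b].to_numpy()
            if abs(np.median(da) - np.median(db)) > median_window:
                continue
            p = stats.ranksums(da, db).pvalue
            m = m_pass if bonferroni == "pass" else total_candidates_examined
            if min(p * m, 1.0) >= alpha:  # not significantly different
                labels[labels == b] = a
                merged = True
                break
        if not merged:
            break
    # relabel contiguously in order of appearance
    relabel = {g: i for i, g in enumerate(pd.unique(labels), start=1)}
    return labels.map(relabel).rename("subgroup")


# ---------------------------------------------------------------------------
# descriptive statistics


def conditional_projection_prob(
    binary: pd.DataFrame, x: str, y: str, stratum=None
) -> dict:
    """P(x | y=1), P(x | y=0) and their difference on a neuron stratum."""
    sub = binary if stratum is None else binary.loc[stratum]
    if len(sub) == 0:
        raise ValueError("stratum is empty")
    y1 = sub[sub[y]]
    y0 = sub[~sub[y]]
    p1 = float(y1[x].mean()) if len(y1) else np.nan
    p0 = float(y0[x].mean()) if len(y0) else np.nan
    return {
        "p_x_given_y1": p1,
        "p_x_given_y0": p0,
        "delta": p1 - p0 if np.isfinite(p1) and np.isfinite(p0) else np.nan,
        "n_y1": int(len(y1)),
        "n_y0": int(len(y0)),
    }


def sublayer_enrichment(
    labels: pd.Series, sublayer: pd.Series, top: int = 2
) -> pd.DataFrame:
    """Subgroup enrichment per sublayer with top-k ranking.

    Enrichment = (subgroup share within the sublayer) / (overall subgroup
    share). Returns a tidy frame with a ``rank`` column (1 = most enriched)
    for the top ``top`` subgroups of each sublayer.
    """
    sublayer = sublayer.loc[labels.index]
    overall = labels.value_counts(normalize=True)
    records = []
    for sl in sorted(sublayer.unique()):
        members = labels[sublayer == sl]
        if len(members) == 0:
            continue
        local = members.value_counts(normalize=True)
        enrichment = (local / overall).dropna().sort_values(ascending=False)
        for rank, (subgroup, value) in enumerate(
            enrichment.head(top).items(), start=1
        ):
            records.append(
                {
                    "sublayer": sl,
                    "subgroup": subgroup,
                    "enrichment": float(value),
                    "rank": rank,
                    "n_neurons": int(len(members)),
                }
            )
    return pd.DataFrame.from_records(records)


def cluster_homogeneity(
    norm: NormalizedProjections,
    labels: pd.Series,
    sizes: list[int],
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Centroid-stability curves under with-replacement down-sampling.

    For each cluster and target size, draws ``n_boot`` resamples with
    replacement and reports Pearson correlations between the resampled and
    full-data centroids.
    """
    rng = np.random.default_rng(seed)
    records = []
    values = norm.values.loc[labels.index].to_numpy()
    for cluster in sorted(labels.unique()):
        rows = values[(labels == cluster).to_numpy()]
        if len(rows) == 0:
            warnings.warn(f"cluster {cluster} empty; skipped")
            continue
        full = rows.mean(axis=0)
        for size in sizes:
            draws = rng.integers(0, len(rows), size=(n_boot, size))
            centroids = rows[draws].mean(axis=1)
            cf = full - full.mean()
            cc = centroids - centroids.mean(axis=1, keepdims=True)
            denom = np.linalg.norm(cc, axis=1) * np.linalg.norm(cf)
            with np.errstate(invalid="ignore"):
                corr = np.where(denom > 0, cc @ cf / denom, 1.0)
            # identical constant rows: centroid == full centroid -> corr 1
            exact = np.all(np.isclose(centroids, full[None, :]), axis=1)
            corr = np.where(denom == 0, np.where(exact, 1.0, np.nan), corr)
            for b, c in enumerate(corr):
                records.append(
                    {
                        "cluster": cluster,
                        "size": size,
                        "boot": b,
                        "correlation": float(c),
                    }
                )
    return pd.DataFrame.from_records(records)
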