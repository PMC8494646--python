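"""Single-neuron axonal projection quantification and population analyses.

SWC morphologies are validated as single trees, axon cable is assigned to
regions through an annotation volume (1-um sub-segment midpoint rule), and
per-neuron region fractions feed three analyses: hierarchical clustering
(see :mod:`projcensus.clustering`), XOR projection-discreteness testing
against fixed-margin shuffles with a one-tailed Levene variance test, and
constrained least-squares decomposition of bulk tracer patterns into
single-cell cluster proportions (NNLS or BVLS, bounds 0.01-1).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .regions import RegionOntology


class SwcNode(NamedTuple):
    id: int
    type: int  # 1 soma, 2 axon, 3/4 dendrite
    x: float
    y: float
    z: float
    radius: float
    parent: int  # -1 for root


class MorphologyError(ValueError):
    pass


@dataclass
class NeuronMorphology:
    """A validated single-tree reconstruction.

    Invariants: exactly one root, every parent exists, no cycles, and no node
    has more than two children (a trifurcation indicates a reconstruction
    error) except the soma root.
    """

    nodes: list[SwcNode]
    _by_id: dict[int, SwcNode] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {}
        for node in self.nodes:
            if node.id in self._by_id:
                raise MorphologyError(f"duplicate node id {node.id}")
            self._by_id[node.id] = node
        roots = [n for n in self.nodes if n.parent == -1]
        if len(roots) == 0:
            raise MorphologyError("no root node (cycle or breaks)")
        if len(roots) > 1:
            raise MorphologyError(f"breaks: {len(roots)} roots found")
        self.root = roots[0]
        children: dict[int, int] = {}
        for node in self.nodes:
            if node.parent != -1:
                if node.parent == node.id:
                    raise MorphologyError(f"node {node.id} is its own parent (cycle)")
                if node.parent not in self._by_id:
                    raise MorphologyError(
                        f"node {node.id} references absent parent {node.parent} (breaks)"
                    )
                children[node.parent] = children.get(node.parent, 0) + 1
        self._check_acyclic()
        for nid, n_children in children.items():
            if nid != self.root.id and n_children > 2:
                raise MorphologyError(
                    f"node {nid} has {n_children} children (trifurcation)"
                )

    def _check_acyclic(self) -> None:
        ok: set[int] = set()
        for node in self.nodes:
            path: set[int] = set()
            cur = node
            while cur.parent != -1 and cur.id not in ok:
                if cur.id in path:
                    raise MorphologyError(f"cycle through node {cur.id}")
                path.add(cur.id)
                cur = self._by_id[cur.parent]
            ok.update(path)
            ok.add(cur.id)

    def segments(self, types: set[int] | None = None):
        """Yield (parent_xyz, child_xyz) arrays for child nodes of given types."""
        for node in self.nodes:
            if node.parent == -1:
                continue
            if types is not None and node.type not in types:
                continue
            parent = self._by_id[node.parent]
            yield (
                np.array([parent.x, parent.y, parent.z]),
                np.array([node.x, node.y, node.z]),
            )

    def total_length(self, types: set[int] | None = None) -> float:
        return float(
            sum(np.linalg.norm(b - a) for a, b in self.segments(types))
        )


def read_swc(path) -> NeuronMorphology:
    """Parse a 7-column SWC text file ('#' comments); order-independent."""
    nodes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise MorphologyError(
                    f"{path}:{lineno}: expected 7 columns, got {len(parts)}"
                )
            nodes.append(
                SwcNode(
                    int(parts[0]), int(parts[1]),
                    float(parts[2]), float(parts[3]), float(parts[4]),
                    float(parts[5]), int(parts[6]),
                )
            )
    # re-order so parents precede children (permitted in input)
    nodes.sort(key=lambda n: n.id)
    return NeuronMorphology(nodes)


def write_swc(morph: NeuronMorphology, path) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for n in morph.nodes:
            fh.write(
                f"{n.id} {n.type} {n.x:.17g} {n.y:.17g} {n.z:.17g} "
                f"{n.radius:.17g} {n.parent}\n"
            )


@dataclass
class AnnotationVolume:
    """3D voxel grid of integer region codes (0 = outside brain)."""

    grid: np.ndarray  # (nx, ny, nz) int
    voxel_size: float  # um
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    region_ids: dict[int, str] | None = None  # code -> region id

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")

    def region_at(self, xyz: np.ndarray) -> str | None:
        idx = np.floor((np.asarray(xyz) - np.asarray(self.origin)) / self.voxel_size)
        idx = idx.astype(int)
        if np.any(idx < 0) or np.any(idx >= self.grid.shape):
            return None
        code = int(self.grid[tuple(idx)])
        if code == 0:
            return None
        if self.region_ids is not None:
            return self.region_ids.get(code, str(code))
        return str(code)

    def save(self, directory) -> None:
        """Raw int32 voxel dump + JSON header (text header, binary payload)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        header = {
            "shape": list(self.grid.shape),
            "dtype": "int32",
            "voxel_size": self.voxel_size,
            "origin": list(self.origin),
            "region_ids": self.region_ids,
        }
        (directory / "volume.json").write_text(json.dumps(header, indent=2))
        self.grid.astype(np.int32).tofile(directory / "volume.raw")

    @classmethod
    def load(cls, directory) -> "AnnotationVolume":
        directory = Path(directory)
        header = json.loads((directory / "volume.json").read_text())
        grid = np.fromfile(directory / "volume.raw", dtype=np.int32).reshape(
            header["shape"]
        )
        region_ids = header.get("region_ids")
        if region_ids is not None:
            region_ids = {int(k): v for k, v in region_ids.items()}
        return cls(
            grid=grid,
            voxel_size=header["voxel_size"],
            origin=tuple(header["origin"]),
            region_ids=region_ids,
        )


UNANNOTATED = "unannotated"


def axon_length_by_region(
    morph: NeuronMorphology,
    volume: AnnotationVolume,
    ontology: RegionOntology | None = None,
    step: float = 1.0,
    axon_types: set[int] = frozenset({2}),
) -> pd.Series:
    """Axon cable length (um) per region, by sub-segment midpoint assignment.

    Each axon segment is subdivided into pieces of at most ``step`` um; each
    piece's length accrues to the region of its midpoint voxel. With an
    ontology, leaf regions roll up to their summary-target ancestor.
    Out-of-volume cable lands in the 'unannotated' bucket.
    """
    totals: dict[str, float] = {}
    rollup_cache: dict[str, str] = {}

    def rollup(region: str) -> str:
        if ontology is None or region not in ontology:
            return region
        if region in rollup_cache:
            return rollup_cache[region]
        node = ontology.node(region)
        resolved = region
        if not node.is_summary_target:
            for anc in ontology.ancestors(region):
                if anc.is_summary_target:
                    resolved = anc.id
                    break
        rollup_cache[region] = resolved
        return resolved

    any_axon = False
    for a, b in morph.segments(types=set(axon_types)):
        any_axon = True
        length = float(np.linalg.norm(b - a))
        if length == 0:
            continue
        n_pieces = max(1, int(np.ceil(length / step)))
        fractions = (np.arange(n_pieces) + 0.5) / n_pieces
        midpoints = a[None, :] + fractions[:, None] * (b - a)[None, :]
        piece_len = length / n_pieces
        for mid in midpoints:
            region = volume.region_at(mid)
            key = UNANNOTATED if region is None else rollup(region)
            totals[key] = totals.get(key, 0.0) + piece_len
    if any_axon and set(totals) <= {UNANNOTATED} and totals:
        warnings.warn("entire axon outside the annotation volume")
    return pd.Series(totals, dtype=float).sort_index()


@dataclass
class SingleCellMatrix:
    """Neurons x regions axon fractions (hemispheres summed; rows sum to 1)."""

    fractions: pd.DataFrame
    soma_layer: pd.Series | None = None
    cluster_label: pd.Series | None = None

    def __post_init__(self) -> None:
        values = self.fractions.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValueError("fractions must be nonnegative")
        sums = values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("every row must sum to 1 +- 1e-9")

    def cluster_means(self) -> pd.DataFrame:
        """Regions x clusters matrix of cluster-mean fraction patterns."""
        if self.cluster_label is None:
            raise ValueError("no cluster labels")
        return self.fractions.groupby(self.cluster_label).mean().T

    def cluster_sizes(self) -> pd.Series:
        return self.cluster_label.value_counts()


def sum_hemispheres(lengths: pd.DataFrame) -> pd.DataFrame:
    """Merge 'region:ipsi'/'region:contra' columns into per-structure totals."""

    def structure(col: str) -> str:
        region, _, hemi = col.rpartition(":")
        return region if hemi in ("ipsi", "contra") and region else col

    return lengths.T.groupby([structure(c) for c in lengths.columns]).sum().T


def fraction_matrix(
    lengths: pd.DataFrame,
    soma_layer: pd.Series | None = None,
    cluster_label: pd.Series | None = None,
) -> SingleCellMatrix:
    """Row-normalize per-neuron per-region lengths; zero-total neurons dropped."""
    totals = lengths.sum(axis=1)
    keep = totals > 0
    if not keep.all():
        warnings.warn(
            f"excluding {(~keep).sum()} neurons with zero total length"
        )
    fractions = lengths.loc[keep].div(totals.loc[keep], axis=0)
    return SingleCellMatrix(
        fractions=fractions,
        soma_layer=None if soma_layer is None else soma_layer.loc[keep],
        cluster_label=None if cluster_label is None else cluster_label.loc[keep],
    )


# ---------------------------------------------------------------------------
# XOR discreteness


def _pairwise_xor(binary: np.ndarray) -> np.ndarray:
    """Condensed pairwise XOR distances (regions targeted by exactly one)."""
    A = binary.astype(np.int64)
    d = A.sum(axis=1)
    cross = A @ A.T
    full = d[:, None] + d[None, :] - 2 * cross
    return full[np.triu_indices(len(A), k=1)]


def fixed_margin_shuffle(
    binary: np.ndarray,
    rng: np.random.Generator,
    n_swaps: int | None = None,
) -> np.ndarray:
    """Randomize a binary matrix preserving row and column sums exactly.

    Iterated checkerboard swaps: pick (r1,c1),(r2,c2) with a 1/0-0/1
    checkerboard and flip it. ``n_swaps`` successful swaps are applied
    (default 10x the number of ones).
    """
    A = binary.astype(np.int8).copy()
    ones = int(A.sum())
    if ones == 0 or ones == A.size:
        return A
    target = 10 * ones if n_swaps is None else n_swaps
    done = 0
    attempts = 0
    max_attempts = 200 * max(target, 1)
    n, m = A.shape
    while done < target and attempts < max_attempts:
        batch = min(4096, max_attempts - attempts)
        r1 = rng.integers(0, n, batch)
        r2 = rng.integers(0, n, batch)
        c1 = rng.integers(0, m, batch)
        c2 = rng.integers(0, m, batch)
        for i in range(batch):
            a, b, c, d2 = r1[i], r2[i], c1[i], c2[i]
            if A[a, c] == 1 and A[b, d2] == 1 and A[a, d2] == 0 and A[b, c] == 0:
                A[a, c] = A[b, d2] = 0
                A[a, d2] = A[b, c] = 1
                done += 1
                if done >= target:
                    break
        attempts += batch
    return A


def bernoulli_shuffle(
    binary: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Independent per-region Bernoulli null with matched column frequencies."""
    p = binary.mean(axis=0)
    return (rng.random(binary.shape) < p[None, :]).astype(np.int8)


@dataclass
class XorTestResult:
    actual_distances: np.ndarray
    shuffled_distances: np.ndarray
    levene_statistic: float
    p_value: float  # one-tailed: var(actual) > var(shuffled)
    var_actual: float
    var_shuffled: float


def xor_discreteness_test(
    binary: pd.DataFrame | np.ndarray,
    n_shuffles: int = 100,
    seed: int = 0,
    null: str = "fixed_margin",
) -> XorTestResult:
    """Test whether pairwise XOR distances are over-dispersed vs a shuffled null.

    The null pools XOR distances from ``n_shuffles`` randomized matrices
    (fixed-margin checkerboard swaps by default, or per-region Bernoulli with
    ``null='bernoulli'``). Significance by a one-tailed Levene test
    (mean-centered) of variance(actual) > variance(shuffled).
    """
    A = (
        binary.to_numpy(dtype=np.int8)
        if isinstance(binary, pd.DataFrame)
        else np.asarray(binary, dtype=np.int8)
    )
    if len(A) < 3:
        raise ValueError("need at least 3 neurons")
    rng = np.random.default_rng(seed)
    actual = _pairwise_xor(A)
    shuffled_parts = []
    for _ in range(n_shuffles):
        if null == "fixed_margin":
            S = fixed_margin_shuffle(A, rng)
        elif null == "bernoulli":
            S = bernoulli_shuffle(A, rng)
        else:
            raise ValueError("null must be 'fixed_margin' or 'bernoulli'")
        shuffled_parts.append(_pairwise_xor(S))
    shuffled = np.concatenate(shuffled_parts)
    var_a = float(np.var(actual, ddof=1)) if len(actual) > 1 else 0.0
    var_s = float(np.var(shuffled, ddof=1)) if len(shuffled) > 1 else 0.0
    if var_a == 0.0:
        return XorTestResult(actual, shuffled, 0.0, 1.0, var_a, var_s)
    stat, p_two = stats.levene(actual, shuffled, center="mean")
    p_one = p_two / 2 if var_a > var_s else 1 - p_two / 2
    return XorTestResult(actual, shuffled, float(stat), float(p_one), var_a, var_s)


# ---------------------------------------------------------------------------
# bulk composition


@dataclass
class CompositionEstimate:
    A: pd.DataFrame  # regions x clusters (cluster mean patterns)
    b: pd.Series  # bulk regional pattern
    x: pd.Series  # raw solution
    proportions: pd.Series  # x renormalized to sum 1
    rss: float  # ||Ax - b||^2 / ||b||^2
    method: str
    bounds: tuple[float, float] | None


def estimate_composition(
    matrix: SingleCellMatrix,
    bulk: pd.Series,
    min_cluster_size: int = 15,
    method: str = "nnls",
    bounds: tuple[float, float] = (0.01, 1.0),
    renormalize_regions: bool = False,
) -> CompositionEstimate:
    """Decompose a bulk regional pattern into cluster-mean mixtures.

    Solves argmin_x ||Ax - b||_2 with x >= 0 (``method='nnls'``) or with box
    constraints (``method='bvls'``, default bounds 0.01-1). Columns of A are
    mean fraction patterns of clusters with at least ``min_cluster_size``
    members. ``renormalize_regions=True`` restricts A and b to regions with
    bulk signal and renormalizes both.
    """
    if method not in ("nnls", "bvls"):
        raise ValueError("method must be 'nnls' or 'bvls'")
    sizes = matrix.cluster_sizes()
    eligible = sorted(sizes.index[sizes >= min_cluster_size])
    if len(eligible) < 2:
        raise ValueError(
            f"need >=2 clusters with >= {min_cluster_size} members, found {len(eligible)}"
        )
    means = matrix.cluster_means()[eligible]
    regions = means.index.intersection(bulk.index)
    A_df = means.loc[regions]
    b = bulk.loc[regions].astype(float)
    if renormalize_regions:
        keep = b > 0
        A_df, b = A_df.loc[keep], b.loc[keep]
        b = b / b.sum()
        A_df = A_df / A_df.sum(axis=0)
    A = A_df.to_numpy()
    if np.linalg.matrix_rank(A) < A.shape[1]:
        warnings.warn("cluster-mean matrix is rank deficient; solution not unique")
    if method == "nnls":
        x, _ = optimize.nnls(A, b.to_numpy())
    else:
        lo, hi = bounds
        res = optimize.lsq_linear(A, b.to_numpy(), bounds=(lo, hi))
        x = res.x
    resid = A @ x - b.to_numpy()
    rss = float(resid @ resid / (b.to_numpy() @ b.to_numpy()))
    x_series = pd.Series(x, index=eligible, name="x")
    total = x_series.sum()
    proportions = x_series / total if total > 0 else x_series * np.nan
    return CompositionEstimate(
        A=A_df,
        b=b,
        x=x_series,
        proportions=proportions.rename("proportion"),
        rss=rss,
        method=method,
        bounds=bounds if method == "bvls" else None,
    )
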