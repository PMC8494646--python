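"""Cortical layer/sublayer delineation from soma-depth histograms.

Soma depths are binned every 25 um from the pia, one count column per label
source. Bins are clustered (Euclidean distance, complete linkage) on their
per-source proportion vectors; maximal contiguous runs of same-cluster bins
become the delineated layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

DEFAULT_BIN_WIDTH = 25.0  # um


@dataclass
class DepthProfile:
    bin_edges: np.ndarray  # length n_bins + 1, um from pia
    counts: pd.DataFrame  # rows: bins, columns: label sources

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class Layer:
    name: str
    depth_min: float
    depth_max: float
    cluster: int


@dataclass
class LayerDelineation:
    layers: list[Layer]
    bin_to_layer: pd.Series  # bin index -> layer name

    def layer_of_depth(self, depth: float) -> str:
        for layer in self.layers:
            if layer.depth_min <= depth < layer.depth_max:
                return layer.name
        if depth == self.layers[-1].depth_max:
            return self.layers[-1].name
        raise KeyError(f"depth {depth} outside delineated range")

    def to_dict(self) -> dict:
        return {
            "layers": [
                {
                    "name": l.name,
                    "depth_min": l.depth_min,
                    "depth_max": l.depth_max,
                    "cluster": l.cluster,
                }
                for l in self.layers
            ]
        }


def depth_histogram(
    somas, bin_width: float = DEFAULT_BIN_WIDTH
) -> DepthProfile:
    """Bin (depth, source) records into half-open [i*w, (i+1)*w) depth bins.

    ``somas`` is an iterable of (depth_um, source) pairs or a DataFrame with
    'depth' and 'source' columns.
    """
    if isinstance(somas, pd.DataFrame):
        records = list(zip(somas["depth"], somas["source"]))
    else:
        records = list(somas)
    for i, (depth, source) in enumerate(records):
        if depth < 0:
            raise ValueError(f"record {i} ({source!r}): negative depth {depth}")
    depths = np.array([d for d, _ in records], dtype=float)
    sources = [s for _, s in records]
    n_bins = int(np.floor(depths.max() / bin_width)) + 1 if len(depths) else 1
    edges = np.arange(n_bins + 1) * bin_width
    source_names = sorted(set(sources))
    counts = np.zeros((n_bins, len(source_names)), dtype=int)
    col = {s: j for j, s in enumerate(source_names)}
    for depth, source in records:
        counts[int(np.floor(depth / bin_width)), col[source]] += 1
    return DepthProfile(
        bin_edges=edges,
        counts=pd.DataFrame(counts, columns=source_names),
    )


def delineate_layers(
    profile: DepthProfile, k: int, normalize: bool = True
) -> LayerDelineation:
    """Cluster depth bins and name maximal contiguous same-cluster runs.

    ``normalize=True`` (default) converts each source's counts to proportions
    so abundant sources do not dominate the Euclidean distance; ``False``
    clusters raw counts.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > profile.n_bins:
        raise ValueError(f"k={k} exceeds bin count {profile.n_bins}")
    features = profile.counts.to_numpy(dtype=float)
    if normalize:
        totals = features.sum(axis=0)
        totals[totals == 0] = 1.0
        features = features / totals
    if k == profile.n_bins:
        clusters = np.arange(1, profile.n_bins + 1)
    else:
        linkage = hierarchy.linkage(pdist(features), method="complete")
        clusters = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    layers: list[Layer] = []
    run_start = 0
    for i in range(1, profile.n_bins + 1):
        if i == profile.n_bins or clusters[i] != clusters[run_start]:
            layers.append(
                Layer(
                    name=f"L{len(layers) + 1}",
                    depth_min=float(profile.bin_edges[run_start]),
                    depth_max=float(profile.bin_edges[i]),
                    cluster=int(clusters[run_start]),
                )
            )
            run_start = i
    bin_to_layer = pd.Series(
        [
            next(
                l.name
                for l in layers
                if l.depth_min <= profile.bin_edges[b] < l.depth_max
            )
            for b in range(profile.n_bins)
        ],
        name="layer",
    )
    return LayerDelineation(layers=layers, bin_to_layer=bin_to_layer)
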