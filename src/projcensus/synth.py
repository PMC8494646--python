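"""Seeded synthetic-data generators with planted ground truth.

Every generator is a pure function of (config, seed): tracer experiments drawn
from class archetypes with multiplicative lognormal noise plus blank-brain
background, barcoded neurons with planted binary projection subgroups tied to
planted laminar depths, and single-neuron region-fraction profiles drawn from
cluster archetypes (optionally materialized as SWC paths through a slab
annotation volume for round-trip quantification).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .regions import (
    BilateralTarget,
    RegionNode,
    RegionOntology,
    bilateral_targets,
)
from .tracer import TracerExperiment


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configs


@dataclass
class TracerConfig:
    n_experiments_per_class: int = 5
    noise_cv: float = 0.2
    blank_background_mean: float = 0.0
    blank_background_sd: float = 0.0
    n_blank_brains: int = 90
    total_signal: float = 1e6
    injection_jitter_sd: float = 100.0  # µm around class centre

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be nonnegative")


@dataclass
class SubgroupDef:
    """Planted barcode subgroup: binary area pattern + laminar depth distribution."""

    pattern: dict[str, int]  # area -> 0/1
    depth_mean: float  # µm from pia
    depth_sd: float
    fraction: float  # mixing fraction


@dataclass
class BarcodeConfig:
    n_neurons: int = 1000
    areas: list[str] = field(
        default_factory=lambda: [f"area{i}" for i in range(1, 7)]
    )
    subgroups: list[SubgroupDef] | None = None
    mean_count: float = 30.0
    spikein_mean: float = 100.0
    n_brains: int = 2
    brain_scale_factors: tuple[float, ...] = (1.0, 1.5)
    cortical_depth: float = 1200.0  # µm, truncation bound

    def __post_init__(self) -> None:
        if self.subgroups is None:
            a = self.areas
            self.subgroups = [
                SubgroupDef({a[0]: 1, a[1]: 1, a[2]: 0}, 250.0, 60.0, 0.5),
                SubgroupDef({a[0]: 0, a[1]: 1, a[2]: 1}, 700.0, 80.0, 0.5),
            ]
        total = sum(g.fraction for g in self.subgroups)
        if not np.isclose(total, 1.0):
            raise ConfigError(f"subgroup fractions sum to {total}, expected 1")
        for g in self.subgroups:
            unknown = set(g.pattern) - set(self.areas)
            if unknown:
                raise ConfigError(f"pattern references unknown areas: {sorted(unknown)}")
        if len(self.brain_scale_factors) < self.n_brains:
            raise ConfigError("need a scale factor per brain")


@dataclass
class SingleCellConfig:
    n_cells_per_cluster: int = 30
    cluster_archetypes: dict[str, np.ndarray] | None = None  # over regions
    dirichlet_concentration: float | None = 200.0  # None = no perturbation
    axon_length_scale: float = 10000.0  # µm total axon per cell
    voxel_size: float = 10.0  # µm, for materialized annotation volumes
    slab_width: float = 50.0  # µm per region slab


@dataclass
class SyntheticConfig:
    seed: int = 0
    tracer: TracerConfig = field(default_factory=TracerConfig)
    barcode: BarcodeConfig = field(default_factory=BarcodeConfig)
    single_cell: SingleCellConfig = field(default_factory=SingleCellConfig)


@dataclass
class GroundTruth:
    """Planted labels for every generated record."""

    experiment_classes: dict[str, str] | None = None
    neuron_subgroups: np.ndarray | None = None
    neuron_depths: np.ndarray | None = None
    cell_clusters: list[str] | None = None
    mixture_proportions: dict[str, float] | None = None


# ---------------------------------------------------------------------------
# toy ontology + archetypes


def make_synthetic_ontology(n_per_division: dict[str, int] | None = None) -> RegionOntology:
    """Small schema-valid ontology for synthetic runs."""
    if n_per_division is None:
        n_per_division = {
            "isocortex": 4,
            "striatum": 2,
            "thalamus": 3,
            "midbrain": 2,
            "pons": 2,
            "medulla": 2,
        }
    nodes = [RegionNode("root", "root", None)]
    for div, n in n_per_division.items():
        tag = div.replace(" ", "_")
        nodes.append(RegionNode(tag, tag, "root", major_division=div))
        for i in range(1, n + 1):
            nodes.append(
                RegionNode(f"{tag}-{i}", f"{tag}{i}", tag, is_summary_target=True)
            )
    return RegionOntology(nodes)


def default_class_archetypes(
    ontology: RegionOntology, injection_region: str | None = None
) -> dict[str, np.ndarray]:
    """IT/ET/CT-style archetype weight vectors over bilateral targets.

    IT mass in isocortex + striatum (both hemispheres), ET in
    midbrain/pons/medulla (ipsi), CT in thalamus (ipsi); the injection
    structure carries no weight.
    """
    targets = bilateral_targets(ontology)
    if injection_region is None:
        injection_region = targets[0].region
    division = {t: ontology.division_of_region(t.region) for t in targets}
    recipes = {
        "IT": {("isocortex", "ipsi"): 0.5, ("isocortex", "contra"): 0.2,
               ("striatum", "ipsi"): 0.2, ("striatum", "contra"): 0.1},
        "ET": {("midbrain", "ipsi"): 0.3, ("pons", "ipsi"): 0.3,
               ("medulla", "ipsi"): 0.3, ("striatum", "ipsi"): 0.1},
        "CT": {("thalamus", "ipsi"): 0.9, ("isocortex", "ipsi"): 0.1},
    }
    out = {}
    for cls, recipe in recipes.items():
        w = np.zeros(len(targets))
        for (div, hemi), mass in recipe.items():
            idx = [
                i
                for i, t in enumerate(targets)
                if division[t] == div and t.hemisphere == hemi
                and t.region != injection_region
            ]
            if idx:
                w[idx] = mass / len(idx)
        out[cls] = w / w.sum()
    return out


# ---------------------------------------------------------------------------
# tracer experiments


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def generate_tracer_experiments(
    config: SyntheticConfig,
    ontology: RegionOntology | None = None,
    archetypes: dict[str, np.ndarray] | None = None,
    injection_region: str | None = None,
) -> tuple[list[TracerExperiment], GroundTruth]:
    """Draw anterograde experiments from class archetypes with noise + background."""
    rng = np.random.default_rng(config.seed)
    tc = config.tracer
    if ontology is None:
        ontology = make_synthetic_ontology()
    targets = bilateral_targets(ontology)
    if injection_region is None:
        injection_region = targets[0].region
    if archetypes is None:
        archetypes = default_class_archetypes(ontology, injection_region)
    for cls, w in archetypes.items():
        if len(w) != len(targets):
            raise ConfigError(f"archetype {cls!r} has wrong dimension")
        if np.any(np.asarray(w) < 0):
            raise ConfigError(f"archetype {cls!r} has negative weights")
    centres = {
        cls: np.array([2000.0 + 1500.0 * i, 3000.0, 1000.0])
        for i, cls in enumerate(archetypes)
    }
    experiments, labels = [], {}
    for cls, w in archetypes.items():
        w = np.asarray(w, dtype=float)
        for i in range(tc.n_experiments_per_class):
            noise = _lognormal_factor(rng, tc.noise_cv, len(targets))
            background = (
                rng.normal(tc.blank_background_mean, tc.blank_background_sd, len(targets))
                if (tc.blank_background_mean or tc.blank_background_sd)
                else np.zeros(len(targets))
            )
            signal = np.clip(w * tc.total_signal * noise + background, 0.0, None)
            xyz = centres[cls] + rng.normal(0.0, tc.injection_jitter_sd, 3)
            exp_id = f"{cls}-{i + 1}"
            experiments.append(
                TracerExperiment(
                    id=exp_id,
                    modality="anterograde",
                    label_source=cls,
                    injection_region=injection_region,
                    injection_xyz=tuple(xyz),
                    signal=dict(zip(targets, signal)),
                )
            )
            labels[exp_id] = cls
    return experiments, GroundTruth(experiment_classes=labels)


def generate_blank_brains(
    config: SyntheticConfig, ontology: RegionOntology | None = None
) -> pd.DataFrame:
    """Blank-brain signal table: pure background noise, no planted signal."""
    tc = config.tracer
    if tc.n_blank_brains < 2:
        raise ConfigError("need at least 2 blank brains (sd undefined otherwise)")
    rng = np.random.default_rng(config.seed + 1)
    if ontology is None:
        ontology = make_synthetic_ontology()
    columns = [str(t) for t in bilateral_targets(ontology)]
    values = rng.normal(
        tc.blank_background_mean,
        tc.blank_background_sd,
        size=(tc.n_blank_brains, len(columns)),
    )
    index = [f"blank-{i + 1}" for i in range(tc.n_blank_brains)]
    return pd.DataFrame(values, index=index, columns=columns)


# ---------------------------------------------------------------------------
# barcoded neurons


def generate_barcoded_neurons(config: SyntheticConfig):
    """Planted-subgroup barcode dataset.

    Returns ``(BarcodeDataset, GroundTruth)``; counts are
    Poisson(mean_count * pattern bit * brain scale), spike-ins
    Poisson(spikein_mean * brain scale), depths truncated-normal in
    [0, cortical_depth], brains assigned round-robin.
    """
    from .barseq import BarcodeDataset  # local import to avoid a cycle

    bc = config.barcode
    rng = np.random.default_rng(config.seed + 2)
    n = bc.n_neurons
    subgroup_ids = rng.choice(
        len(bc.subgroups), size=n, p=[g.fraction for g in bc.subgroups]
    )
    brain_ids = np.array([f"brain{(i % bc.n_brains) + 1}" for i in range(n)])
    scales = np.array(
        [bc.brain_scale_factors[i % bc.n_brains] for i in range(n)]
    )
    depths = np.empty(n)
    counts = np.zeros((n, len(bc.areas)), dtype=int)
    for gi, g in enumerate(bc.subgroups):
        sel = subgroup_ids == gi
        m = int(sel.sum())
        if m == 0:
            continue
        if g.depth_sd == 0:
            depths[sel] = g.depth_mean
        else:
            a = (0 - g.depth_mean) / g.depth_sd
            b = (bc.cortical_depth - g.depth_mean) / g.depth_sd
            depths[sel] = stats.truncnorm.rvs(
                a, b, loc=g.depth_mean, scale=g.depth_sd, size=m, random_state=rng
            )
        bits = np.array([g.pattern.get(area, 0) for area in bc.areas])
        lam = bc.mean_count * bits[None, :] * scales[sel, None]
        counts[sel] = rng.poisson(lam)
    spikein = rng.poisson(bc.spikein_mean * scales)
    soma_ml = rng.uniform(0, 2000.0, n)
    neuron_ids = [f"n{i + 1}" for i in range(n)]
    dataset = BarcodeDataset(
        counts=pd.DataFrame(counts, index=neuron_ids, columns=bc.areas),
        spikein=pd.Series(spikein, index=neuron_ids),
        soma_depth=pd.Series(depths, index=neuron_ids),
        soma_ml=pd.Series(soma_ml, index=neuron_ids),
        brain_id=pd.Series(brain_ids, index=neuron_ids),
    )
    truth = GroundTruth(neuron_subgroups=subgroup_ids, neuron_depths=depths)
    return dataset, truth


# ---------------------------------------------------------------------------
# single cells


def default_cluster_archetypes(regions: list[str]) -> dict[str, np.ndarray]:
    """Three roughly orthogonal cluster archetypes over a region list."""
    k = len(regions)
    thirds = np.array_split(np.arange(k), 3)
    out = {}
    for ci, idx in enumerate(thirds, start=1):
        w = np.full(k, 0.01)
        w[idx] = 1.0
        out[f"C{ci}"] = w / w.sum()
    return out


def generate_single_cells(
    config: SyntheticConfig,
    regions: list[str] | None = None,
    materialize: bool = False,
):
    """Draw per-cell region fractions from Dirichlet-perturbed cluster archetypes.

    With ``materialize=True`` also returns synthetic SWC morphologies and a
    slab annotation volume whose per-region path lengths match the fractions
    (up to voxel quantization), for round-trip testing of
    ``axon_length_by_region``.
    """
    from .single_cell import AnnotationVolume, NeuronMorphology, SingleCellMatrix, SwcNode

    sc = config.single_cell
    rng = np.random.default_rng(config.seed + 3)
    if regions is None:
        regions = [f"R{i + 1}" for i in range(9)]
    archetypes = sc.cluster_archetypes or default_cluster_archetypes(regions)
    for name, w in archetypes.items():
        if len(w) != len(regions):
            raise ConfigError(f"archetype {name!r} dimension != number of regions")
    rows, clusters, ids = [], [], []
    for name, w in archetypes.items():
        w = np.asarray(w, dtype=float)
        w = w / w.sum()
        for i in range(sc.n_cells_per_cluster):
            if sc.dirichlet_concentration is None:
                frac = w.copy()
            else:
                frac = rng.dirichlet(w * sc.dirichlet_concentration)
            rows.append(frac)
            clusters.append(name)
            ids.append(f"{name}-cell{i + 1}")
    fractions = pd.DataFrame(np.vstack(rows), index=ids, columns=regions)
    matrix = SingleCellMatrix(
        fractions=fractions,
        cluster_label=pd.Series(clusters, index=ids),
    )
    truth = GroundTruth(cell_clusters=clusters)
    if not materialize:
        return matrix, None, None, truth

    # Slab volume: region i occupies x in [i*W, (i+1)*W); cells are polylines
    # running along +y inside each slab, lengths proportional to fractions.
    W = sc.slab_width
    vox = sc.voxel_size
    max_len = sc.axon_length_scale + 2 * W * len(regions)
    nx = int(np.ceil(len(regions) * W / vox))
    ny = int(np.ceil((max_len + 2 * W) / vox))
    grid = np.zeros((nx, ny, 1), dtype=np.int32)
    for i in range(len(regions)):
        x0 = int(round(i * W / vox))
        x1 = int(round((i + 1) * W / vox))
        grid[x0:x1, :, :] = i + 1
    volume = AnnotationVolume(
        grid=grid,
        voxel_size=vox,
        origin=(0.0, 0.0, 0.0),
        region_ids={i + 1: r for i, r in enumerate(regions)},
    )
    morphologies = {}
    z = vox / 2
    for cell_id in ids:
        frac = fractions.loc[cell_id].to_numpy()
        nodes = []
        nid = 1
        y = vox  # stay strictly inside the volume
        first_region = int(np.argmax(frac > 0))
        x = (first_region + 0.5) * W
        nodes.append(SwcNode(nid, 1, x, y, z, 1.0, -1))  # soma
        parent = nid
        for ri, f in enumerate(frac):
            seg_len = f * sc.axon_length_scale
            if seg_len <= 0:
                continue
            x = (ri + 0.5) * W
            nid += 1
            nodes.append(SwcNode(nid, 2, x, y, z, 0.5, parent))  # enter slab
            parent = nid
            nid += 1
            nodes.append(SwcNode(nid, 2, x, y + seg_len, z, 0.5, parent))
            parent = nid
            y = y + seg_len
        morphologies[cell_id] = NeuronMorphology(nodes)
    return matrix, morphologies, volume, truth


def synthesize_bulk(
    matrix, proportions: dict[str, float]
) -> tuple[pd.Series, GroundTruth]:
    """Bulk regional pattern as a known mixture of cluster mean patterns."""
    means = matrix.cluster_means()
    missing = set(proportions) - set(means.columns)
    if missing:
        raise ConfigError(f"unknown clusters in mixture: {sorted(missing)}")
    bulk = sum(means[c] * p for c, p in proportions.items())
    return bulk, GroundTruth(mixture_proportions=dict(proportions))
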