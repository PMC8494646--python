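"""Weighted connectivity matrices from per-region tracer signal volumes.

Outputs (anterograde): per-experiment signal per bilateral target, masked by a
true-positive flag table, normalized to fractions of total signal excluding
the injection structure, then averaged within tracer groups.

Inputs (retrograde/rabies): per-target signal thresholded against a
blank-brain false-positive calibration (mean + k*sd, k = 6 by default) before
the same fractional normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import BilateralTarget, RegionOntology, bilateral_targets, division_of

ANTEROGRADE_MODALITIES = {"anterograde"}
RETROGRADE_MODALITIES = {"retrograde", "rabies", "CTB", "TRIO"}


@dataclass
class TracerExperiment:
    """One tracer injection experiment quantified per bilateral target."""

    id: str
    modality: str
    label_source: str
    injection_region: str
    signal: dict[BilateralTarget, float]
    injection_xyz: tuple[float, float, float] | None = None
    group_label: str | None = None

    def __post_init__(self) -> None:
        for target, value in self.signal.items():
            if not np.isnan(value) and not (np.isfinite(value) and value >= 0):
                raise ValueError(
                    f"experiment {self.id!r}: signal at {target} is {value!r}"
                )

    @property
    def group(self) -> str:
        return self.group_label if self.group_label is not None else self.id


@dataclass
class ConnectivityMatrix:
    """Rows of target fractions; each non-NaN row sums to 1 (or 0 if empty)."""

    data: pd.DataFrame  # index: row ids, columns: str(BilateralTarget)
    kind: str  # "output" | "input"

    def __post_init__(self) -> None:
        if self.kind not in ("output", "input"):
            raise ValueError(f"kind must be 'output' or 'input', got {self.kind!r}")
        values = self.data.to_numpy(dtype=float)
        if np.nanmin(values, initial=0.0) < 0:
            raise ValueError("connectivity fractions must be nonnegative")
        sums = np.nansum(values, axis=1)
        bad = ~(np.isclose(sums, 1.0, atol=1e-9) | np.isclose(sums, 0.0, atol=1e-12))
        if bad.any():
            raise ValueError(
                f"rows not normalized: {list(self.data.index[bad])}"
            )

    @property
    def targets(self) -> list[BilateralTarget]:
        return [BilateralTarget.parse(c) for c in self.data.columns]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="row")

    @classmethod
    def from_csv(cls, path, kind: str) -> "ConnectivityMatrix":
        return cls(pd.read_csv(path, index_col="row"), kind=kind)


@dataclass
class BlankCalibration:
    """Per-target false-positive statistics from blank (no-tracer) brains."""

    mean: pd.Series
    sd: pd.Series
    n_blanks: int
    k: float = 6.0

    @property
    def threshold(self) -> pd.Series:
        return self.mean + self.k * self.sd


@dataclass
class TruePositiveMask:
    """Binary (experiment, target) flags; False entries are forced to zero."""

    flags: pd.DataFrame  # bool, index experiment ids, columns str(target)

    def flags_for(self, experiment_id: str, columns: list[str]) -> np.ndarray:
        if experiment_id not in self.flags.index:
            return np.ones(len(columns), dtype=bool)
        return (
            self.flags.loc[experiment_id].reindex(columns, fill_value=True)
            .to_numpy(dtype=bool)
        )


def _target_columns(ontology: RegionOntology) -> list[str]:
    return [str(t) for t in bilateral_targets(ontology)]


def _normalized_row(
    experiment: TracerExperiment,
    columns: list[str],
    keep: np.ndarray,
) -> np.ndarray:
    """Raw signal -> fraction-of-total row, excluding injection structure.

    ``keep`` is a boolean vector (mask and/or threshold already applied).
    NaN signal entries (e.g. excluded reciprocal regions in monosynaptic
    tracing) propagate as NaN and are excluded from the normalizing total.
    """
    raw = np.full(len(columns), 0.0)
    lookup = {str(t): v for t, v in experiment.signal.items()}
    for j, col in enumerate(columns):
        raw[j] = lookup.get(col, 0.0)
    injection = {
        str(BilateralTarget(experiment.injection_region, hemi))
        for hemi in ("ipsi", "contra")
    }
    exclude = np.array([c in injection for c in columns])
    row = raw.copy()
    row[~keep & ~np.isnan(row)] = 0.0
    row[exclude] = 0.0
    total = np.nansum(row)
    if total <= 0:
        if not np.all(np.isnan(row) | (row == 0)):  # pragma: no cover
            raise AssertionError
        warnings.warn(
            f"experiment {experiment.id!r}: no signal survives; emitting all-zero row",
            stacklevel=3,
        )
        return row
    return row / total


def _group_rows(
    experiments: list[TracerExperiment],
    rows: dict[str, np.ndarray],
    columns: list[str],
) -> pd.DataFrame:
    """Average normalized member rows within each group, preserving first-seen order."""
    order: list[str] = []
    members: dict[str, list[np.ndarray]] = {}
    for exp in experiments:
        if exp.group not in members:
            members[exp.group] = []
            order.append(exp.group)
        members[exp.group].append(rows[exp.id])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        out = {g: np.nanmean(np.vstack(members[g]), axis=0) for g in order}
    return pd.DataFrame.from_dict(out, orient="index", columns=columns)


def output_fraction_matrix(
    experiments: list[TracerExperiment],
    ontology: RegionOntology,
    mask: TruePositiveMask | None = None,
) -> ConnectivityMatrix:
    """Anterograde output matrix: masked, injection-excluded fraction of total axon."""
    if not experiments:
        raise ValueError("no experiments")
    for exp in experiments:
        if exp.modality not in ANTEROGRADE_MODALITIES:
            raise ValueError(
                f"experiment {exp.id!r}: modality {exp.modality!r} is not anterograde"
            )
    columns = _target_columns(ontology)
    rows = {}
    for exp in experiments:
        keep = (
            mask.flags_for(exp.id, columns)
            if mask is not None
            else np.ones(len(columns), dtype=bool)
        )
        rows[exp.id] = _normalized_row(exp, columns, keep)
    data = _group_rows(experiments, rows, columns)
    # group averaging can break exact unit sums; renormalize non-empty rows
    values = data.to_numpy()
    sums = np.nansum(values, axis=1)
    nonzero = sums > 0
    values[nonzero] = values[nonzero] / sums[nonzero, None]
    return ConnectivityMatrix(pd.DataFrame(values, data.index, columns), kind="output")


def blank_calibration(blanks: pd.DataFrame, k: float = 6.0) -> BlankCalibration:
    """Fit per-target thresholds (mean + k*sd) from blank-brain signal rows.

    ``blanks``: rows = blank brains, columns = target keys. Sample (n-1)
    standard deviation.
    """
    if len(blanks) < 2:
        raise ValueError("need at least 2 blank brains to estimate a threshold")
    return BlankCalibration(
        mean=blanks.mean(axis=0),
        sd=blanks.std(axis=0, ddof=1),
        n_blanks=len(blanks),
        k=k,
    )


def input_fraction_matrix(
    experiments: list[TracerExperiment],
    calibration: BlankCalibration,
    ontology: RegionOntology,
) -> ConnectivityMatrix:
    """Retrograde input matrix: blank-thresholded fraction of total labelled signal."""
    if not experiments:
        raise ValueError("no experiments")
    for exp in experiments:
        if exp.modality not in RETROGRADE_MODALITIES:
            raise ValueError(
                f"experiment {exp.id!r}: modality {exp.modality!r} is not retrograde-type"
            )
    columns = _target_columns(ontology)
    threshold = calibration.threshold.reindex(columns, fill_value=0.0).to_numpy()
    rows = {}
    for exp in experiments:
        raw = np.array(
            [{str(t): v for t, v in exp.signal.items()}.get(c, 0.0) for c in columns]
        )
        with np.errstate(invalid="ignore"):
            keep = raw > threshold
        rows[exp.id] = _normalized_row(exp, columns, keep)
    data = _group_rows(experiments, rows, columns)
    values = data.to_numpy()
    sums = np.nansum(values, axis=1)
    nonzero = sums > 0
    values[nonzero] = values[nonzero] / sums[nonzero, None]
    return ConnectivityMatrix(pd.DataFrame(values, data.index, columns), kind="input")


def division_summary(
    matrix: ConnectivityMatrix, ontology: RegionOntology
) -> pd.DataFrame:
    """Sum each row's fractions by major brain division; adds an 'average' row.

    The 'average' row is the mean of the per-row division shares, renormalized
    over observed mass, so it also sums to 1.
    """
    divisions = []
    for target in matrix.targets:
        divisions.append(division_of(ontology, target))
    div_index = pd.Index(divisions, name="division")
    summed = matrix.data.T.groupby(div_index).sum(min_count=1).T
    summed = summed.fillna(0.0)
    avg = summed.mean(axis=0)
    if avg.sum() > 0:
        avg = avg / avg.sum()
    summed.loc["average"] = avg
    return summed


def injection_distances(
    experiments: list[TracerExperiment],
) -> tuple[float, float, pd.DataFrame]:
    """Mean/sd of Euclidean 3D distances over all unordered experiment pairs."""
    located = []
    for exp in experiments:
        if exp.injection_xyz is None:
            warnings.warn(f"experiment {exp.id!r} has no coordinates; excluded")
        else:
            located.append(exp)
    if len(located) < 2:
        raise ValueError("need at least 2 experiments with coordinates")
    ids = [e.id for e in located]
    xyz = np.array([e.injection_xyz for e in located], dtype=float)
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    table = pd.DataFrame(dist, index=ids, columns=ids)
    iu = np.triu_indices(len(ids), k=1)
    pairs = dist[iu]
    return float(pairs.mean()), float(pairs.std(ddof=1)) if len(pairs) > 1 else 0.0, table


def in_degree(matrix: ConnectivityMatrix) -> pd.Series:
    """Number of targets with strictly positive weight per row."""
    return (matrix.data > 0).sum(axis=1).rename("in_degree")
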