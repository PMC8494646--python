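"""Brain-region ontology: hierarchy validation, bilateral targets, division roll-up.

The ontology is a rooted tree of regions. A subset of nodes are *summary
targets*: the granularity at which signal is quantified. Each summary target
rolls up to exactly one *major brain division* (isocortex, thalamus, ...).
Targets are enumerated bilaterally (ipsi/contra relative to the injection
hemisphere), giving the column axis of every connectivity matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, NamedTuple

MAJOR_DIVISIONS = (
    "isocortex",
    "olfactory",
    "hippocampal",
    "cortical subplate",
    "striatum",
    "pallidum",
    "thalamus",
    "hypothalamus",
    "midbrain",
    "pons",
    "medulla",
    "cerebellum",
    "spinal cord",
)

HEMISPHERES = ("ipsi", "contra")


class OntologyError(ValueError):
    """Raised when an ontology file violates the tree invariants."""


class BilateralTarget(NamedTuple):
    """A summary-target region on one side of the brain."""

    region: str
    hemisphere: str  # "ipsi" | "contra"

    def __str__(self) -> str:  # serialization key used in CSV headers
        return f"{self.region}:{self.hemisphere}"

    @classmethod
    def parse(cls, key: str) -> "BilateralTarget":
        region, _, hemi = key.rpartition(":")
        if hemi not in HEMISPHERES or not region:
            raise ValueError(f"not a bilateral-target key: {key!r}")
        return cls(region, hemi)


@dataclass(frozen=True)
class RegionNode:
    id: str
    acronym: str
    parent: str | None
    is_summary_target: bool = False
    major_division: str | None = None


@dataclass
class RegionOntology:
    """Validated rooted region tree.

    Parameters
    ----------
    nodes
        Region nodes in file order. Exactly one node must have ``parent=None``
        (the root). Summary-target order is the node order, which fixes the
        column order of all downstream matrices.
    """

    nodes: list[RegionNode]
    _by_id: dict[str, RegionNode] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {}
        for node in self.nodes:
            if node.id in self._by_id:
                raise OntologyError(f"duplicate region id: {node.id!r}")
            self._by_id[node.id] = node
        roots = [n for n in self.nodes if n.parent is None]
        if len(roots) != 1:
            raise OntologyError(
                f"ontology must have exactly one root, found {len(roots)}"
            )
        self.root = roots[0]
        for node in self.nodes:
            if node.parent is not None and node.parent not in self._by_id:
                raise OntologyError(
                    f"node {node.id!r} references absent parent {node.parent!r}"
                )
        self._check_acyclic()
        for node in self.summary_targets:
            if self.division_of_region(node.id) is None:
                raise OntologyError(
                    f"summary target {node.id!r} has no major division on its path"
                )

    def _check_acyclic(self) -> None:
        seen_ok: set[str] = set()
        for node in self.nodes:
            path: list[str] = []
            cur: RegionNode | None = node
            on_path: set[str] = set()
            while cur is not None and cur.id not in seen_ok:
                if cur.id in on_path:
                    raise OntologyError(f"cycle through region {cur.id!r}")
                on_path.add(cur.id)
                path.append(cur.id)
                cur = self._by_id[cur.parent] if cur.parent is not None else None
            seen_ok.update(path)

    # -- queries ----------------------------------------------------------

    def __contains__(self, region_id: str) -> bool:
        return region_id in self._by_id

    def node(self, region_id: str) -> RegionNode:
        try:
            return self._by_id[region_id]
        except KeyError:
            raise KeyError(f"unknown region: {region_id!r}") from None

    @property
    def summary_targets(self) -> list[RegionNode]:
        return [n for n in self.nodes if n.is_summary_target]

    def ancestors(self, region_id: str) -> Iterable[RegionNode]:
        cur = self.node(region_id)
        while cur.parent is not None:
            cur = self._by_id[cur.parent]
            yield cur

    def division_of_region(self, region_id: str) -> str | None:
        """Major division of a region: its own tag, else the nearest tagged ancestor."""
        node = self.node(region_id)
        if node.major_division is not None:
            return node.major_division
        for anc in self.ancestors(region_id):
            if anc.major_division is not None:
                return anc.major_division
        return None


def load_ontology(source) -> RegionOntology:
    """Load an ontology from a JSON file path, file object, or parsed structure.

    The dialect is a flat list of node objects (optionally wrapped in
    ``{"nodes": [...]}``) with keys ``id``, ``acronym``, ``parent``,
    ``is_summary_target``, ``major_division``.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source) as fh:
            raw = json.load(fh)
    elif hasattr(source, "read"):
        raw = json.load(source)
    else:
        raw = source
    if isinstance(raw, dict):
        raw = raw["nodes"]
    nodes = []
    for rec in raw:
        division = rec.get("major_division")
        if division is not None and division not in MAJOR_DIVISIONS:
            raise OntologyError(
                f"node {rec.get('id')!r}: unknown major division {division!r}"
            )
        nodes.append(
            RegionNode(
                id=str(rec["id"]),
                acronym=str(rec.get("acronym", rec["id"])),
                parent=None if rec.get("parent") is None else str(rec["parent"]),
                is_summary_target=bool(rec.get("is_summary_target", False)),
                major_division=division,
            )
        )
    return RegionOntology(nodes)


def load_default_ontology() -> RegionOntology:
    """Packaged default ontology: 314 summary targets across 13 major divisions.

    The structure list is a schema-compatible stand-in with the documented
    target count per hemisphere; acronyms are synthetic.
    """
    ref = resources.files("projcensus").joinpath("data/default_ontology.json")
    with ref.open() as fh:
        return load_ontology(fh)


def bilateral_targets(ontology: RegionOntology) -> list[BilateralTarget]:
    """Ordered bilateral targets: all ipsi in ontology order, then all contra."""
    targets = [n.id for n in ontology.summary_targets]
    return [BilateralTarget(r, "ipsi") for r in targets] + [
        BilateralTarget(r, "contra") for r in targets
    ]


def division_of(ontology: RegionOntology, target: BilateralTarget | str) -> str:
    """Major brain division of a summary target (hemisphere-independent)."""
    region = target.region if isinstance(target, BilateralTarget) else target
    node = ontology.node(region)
    if not node.is_summary_target:
        raise KeyError(f"region {region!r} is not a summary target")
    division = ontology.division_of_region(region)
    assert division is not None  # guaranteed by ontology validation
    return division
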