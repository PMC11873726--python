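"""Domain types shared by every analysis stage.

The central objects are :class:`ExpressionMatrix` (genes x samples),
:class:`SampleMeta` (per-sample clinical/genomic annotation),
:class:`CloneTree` (rooted clone phylogeny with genotypes) and
:class:`Repertoire` (clonotype count table for one sample/chain).
All containers validate their invariants at construction time.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .errors import (
    ArgumentError,
    FormatError,
    LookupError_,
    TreeStructureError,
)

SAMPLE_TYPES = ("primary", "metastasis", "thrombus", "normal")

#: ccRCC chromatin-modifier drivers entering the "epigenetic driver" count.
EPIGENETIC_DRIVERS = ("SETD2", "PBRM1", "ARID1A", "KDM5C", "BAP1")


@dataclass
class ExpressionMatrix:
    """Dense gene x sample matrix with named, ordered axes.

    Parameters
    ----------
    values
        2-D float array of shape ``(n_genes, n_samples)``; must be finite.
    gene_ids, sample_ids
        Ordered unique identifiers matching the array dimensions.
    """

    values: np.ndarray
    gene_ids: List[str]
    sample_ids: List[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise FormatError("expression matrix must be 2-D")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for axis_name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise FormatError(f"duplicate {axis_name} identifiers: {sorted(dupes)}")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression matrix contains non-finite values")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_ids: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._gene_index[g] for g in gene_ids], dtype=int)
        except KeyError as exc:
            raise LookupError_(f"unknown gene id {exc.args[0]!r}") from exc

    def sample_index(self, sample_ids: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._sample_index[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise LookupError_(f"unknown sample id {exc.args[0]!r}") from exc

    def sample_vector(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_index([sample_id])[0]]

    def subset(
        self,
        genes: Optional[Sequence[str]] = None,
        samples: Optional[Sequence[str]] = None,
    ) -> "ExpressionMatrix":
        vals = self.values
        g = list(self.gene_ids) if genes is None else [str(x) for x in genes]
        s = list(self.sample_ids) if samples is None else [str(x) for x in samples]
        if genes is not None:
            vals = vals[self.gene_index(g), :]
        if samples is not None:
            vals = vals[:, self.sample_index(s)]
        return ExpressionMatrix(vals, g, s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass
class SampleMeta:
    """Per-sample annotation: patient, type, purity, instability, drivers, clones."""

    sample_id: str
    patient_id: str
    sample_type: str
    purity: float = 1.0
    wgii: float = 0.0
    wgd: bool = False
    driver_status: Dict[str, bool] = field(default_factory=dict)
    clones: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise FormatError(
                f"sample {self.sample_id}: unknown sample_type {self.sample_type!r}"
            )
        if not (0.0 <= float(self.purity) <= 1.0):
            raise FormatError(f"sample {self.sample_id}: purity outside [0,1]")
        if not (0.0 <= float(self.wgii) <= 1.0):
            raise FormatError(f"sample {self.sample_id}: wGII outside [0,1]")
        if self.sample_type == "normal" and self.clones:
            raise FormatError(
                f"normal sample {self.sample_id} must have an empty clone set"
            )
        self.clones = {str(c) for c in self.clones}

    @property
    def is_tumor(self) -> bool:
        return self.sample_type != "normal"

    @property
    def is_monoclonal(self) -> bool:
        return len(self.clones) == 1

    def n_epigenetic_drivers(self) -> int:
        return sum(bool(self.driver_status.get(d, False)) for d in EPIGENETIC_DRIVERS)


@dataclass
class CloneGenotype:
    """Somatic state of one clone: driver mutations, gene CN, arm events."""

    clone_id: str
    driver_mutations: Set[str] = field(default_factory=set)
    cn: Dict[str, int] = field(default_factory=dict)
    arm_events: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, value in self.cn.items():
            if int(value) < 0:
                raise FormatError(
                    f"clone {self.clone_id}: negative copy number for {gene}"
                )
        for arm, event in self.arm_events.items():
            if event not in ("loss", "neutral", "gain"):
                raise FormatError(
                    f"clone {self.clone_id}: unknown arm event {event!r} on {arm}"
                )

    def copy(self) -> "CloneGenotype":
        return CloneGenotype(
            clone_id=self.clone_id,
            driver_mutations=set(self.driver_mutations),
            cn=dict(self.cn),
            arm_events=dict(self.arm_events),
        )


class CloneTree:
    """Rooted clone phylogeny for one patient.

    ``parent`` maps every non-root clone to its parent; the unique
    parentless node is the root (MRCA). Edge lengths are implicitly 1.
    """

    def __init__(
        self,
        patient_id: str,
        edges: Iterable[Tuple[str, str]],
        nodes: Optional[Iterable[str]] = None,
        genotypes: Optional[Mapping[str, CloneGenotype]] = None,
    ) -> None:
        self.patient_id = str(patient_id)
        edge_list = [(str(p), str(c)) for p, c in edges]
        node_set = {n for e in edge_list for n in e}
        if nodes is not None:
            node_set |= {str(n) for n in nodes}
        if not node_set:
            raise TreeStructureError(f"patient {patient_id}: empty tree")
        parent: Dict[str, str] = {}
        for p, c in edge_list:
            if c in parent:
                raise TreeStructureError(
                    f"patient {patient_id}: clone {c} has multiple parents"
                )
            parent[c] = p
        roots = sorted(node_set - set(parent))
        if len(roots) != 1:
            raise TreeStructureError(
                f"patient {patient_id}: expected exactly one root, found {roots}"
            )
        self.root = roots[0]
        self.parent = parent
        self.nodes: List[str] = sorted(node_set)
        self.children: Dict[str, List[str]] = {n: [] for n in self.nodes}
        for p, c in edge_list:
            self.children[p].append(c)
        for kids in self.children.values():
            kids.sort()
        # reachability from the root guarantees connectivity / acyclicity
        seen = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node in seen:
                raise TreeStructureError(f"patient {patient_id}: cycle detected")
            seen.add(node)
            stack.extend(self.children[node])
        if seen != node_set:
            raise TreeStructureError(
                f"patient {patient_id}: disconnected clones {sorted(node_set - seen)}"
            )
        self.genotypes: Dict[str, CloneGenotype] = dict(genotypes or {})
        for clone in self.genotypes:
            if clone not in node_set:
                raise LookupError_(
                    f"patient {patient_id}: genotype for unknown clone {clone}"
                )

    # -- structure queries ------------------------------------------------

    @property
    def edges(self) -> List[Tuple[str, str]]:
        return [(p, c) for c, p in sorted(self.parent.items())]

    def has_clone(self, clone: str) -> bool:
        return clone in self.children

    def require_clone(self, clone: str) -> None:
        if not self.has_clone(clone):
            raise LookupError_(
                f"patient {self.patient_id}: unknown clone {clone!r}"
            )

    def leaves(self) -> Set[str]:
        return {n for n, kids in self.children.items() if not kids}

    def root_path(self, clone: str) -> List[str]:
        """Path from ``clone`` up to (and including) the root."""
        self.require_clone(clone)
        path = [clone]
        while path[-1] != self.root:
            path.append(self.parent[path[-1]])
        return path

    def depth(self, clone: str) -> int:
        return len(self.root_path(clone)) - 1

    def path_length(self, a: str, b: str) -> int:
        """Unrooted edge-count distance between two clones."""
        self.require_clone(a)
        self.require_clone(b)
        if a == b:
            return 0
        dist = {a: 0}
        queue = deque([a])
        while queue:
            node = queue.popleft()
            neighbours = list(self.children[node])
            if node in self.parent:
                neighbours.append(self.parent[node])
            for nxt in neighbours:
                if nxt not in dist:
                    dist[nxt] = dist[node] + 1
                    if nxt == b:
                        return dist[nxt]
                    queue.append(nxt)
        raise TreeStructureError(
            f"patient {self.patient_id}: no path between {a} and {b}"
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CloneTree):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and self.nodes == other.nodes
            and self.parent == other.parent
        )


@dataclass
class GeneAnnotation:
    """Genomic placement of one gene (1-based inclusive coordinates)."""

    gene_id: str
    chromosome: str
    arm: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"gene {self.gene_id}: start > end")
        if not self.arm.startswith(str(self.chromosome)):
            raise FormatError(
                f"gene {self.gene_id}: arm {self.arm!r} inconsistent with "
                f"chromosome {self.chromosome!r}"
            )


@dataclass
class GeneSet:
    """Named non-empty collection of gene identifiers."""

    name: str
    gene_ids: Set[str]

    def __post_init__(self) -> None:
        self.gene_ids = {str(g) for g in self.gene_ids}
        if not self.gene_ids:
            raise FormatError(f"gene set {self.name!r} is empty")


@dataclass
class Repertoire:
    """Clonotype -> positive count mapping for one sample and chain."""

    sample_id: str
    chain: str
    counts: Dict[str, int]

    def __post_init__(self) -> None:
        if self.chain not in ("TCR", "BCR"):
            raise FormatError(f"unknown chain {self.chain!r}")
        clean: Dict[str, int] = {}
        for key, count in self.counts.items():
            count = int(count)
            if count <= 0:
                raise FormatError(
                    f"repertoire {self.sample_id}/{self.chain}: "
                    f"non-positive count for clonotype {key!r}"
                )
            clean[str(key)] = count
        self.counts = clean

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_clonotypes(self) -> int:
        return len(self.counts)


def metadata_by_sample(metadata: Sequence[SampleMeta]) -> Dict[str, SampleMeta]:
    out: Dict[str, SampleMeta] = {}
    for meta in metadata:
        if meta.sample_id in out:
            raise FormatError(f"duplicate sample id {meta.sample_id!r} in metadata")
        out[meta.sample_id] = meta
    return out


def samples_of_patient(
    metadata: Sequence[SampleMeta], patient_id: str, sample_type: Optional[str] = None
) -> List[SampleMeta]:
    out = [m for m in metadata if m.patient_id == patient_id]
    if sample_type is not None:
        out = [m for m in out if m.sample_type == sample_type]
    return sorted(out, key=lambda m: m.sample_id)


def _duplicates(items: Sequence[str]) -> Set[str]:
    seen: Set[str] = set()
    dupes: Set[str] = set()
    for item in items:
        if item in seen:
            dupes.add(item)
        seen.add(item)
    return dupes


def validate_clone_membership(
    metadata: Sequence[SampleMeta], trees: Mapping[str, CloneTree]
) -> None:
    """Check that every clone named in metadata resolves in the patient tree."""
    for meta in metadata:
        if not meta.clones:
            continue
        tree = trees.get(meta.patient_id)
        if tree is None:
            raise LookupError_(f"no clone tree for patient {meta.patient_id}")
        for clone in meta.clones:
            tree.require_clone(clone)


def require_fraction(value: float, name: str) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0):
        raise ArgumentError(f"{name} must lie in [0, 1], got {value}")
    return value
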