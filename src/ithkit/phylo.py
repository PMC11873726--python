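"""Phylogeny-aware quantities: clonal distances, MRCA depth, terminal
clones, metastasis seeding classification and clone-level profiles.

Clonal distance between two samples is the minimum unrooted edge-count
path between any clone of one sample and any clone of the other; two
samples sharing a clone are at distance zero.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .datamodel import CloneTree, ExpressionMatrix, SampleMeta
from .errors import ArgumentError
from .distances import pair_type_of

logger = logging.getLogger(__name__)


@dataclass
class ClonalDistanceRecord:
    patient_id: str
    sample_a: str
    sample_b: str
    distance: int
    resolved_clone_pair: Tuple[str, str]
    pair_type: str = "primary-primary"


@dataclass
class CloneProfile:
    """Expression / TME vectors assigned to one clone from monoclonal regions."""

    clone_id: str
    patient_id: str
    expression: Optional[np.ndarray]
    tme: Optional[np.ndarray]
    n_source_regions: int
    mean_purity: float


def clonal_distance(
    tree: CloneTree, clones_a: Set[str], clones_b: Set[str]
) -> Tuple[int, Tuple[str, str]]:
    """Minimum edge-count distance between two clone sets.

    Returns the distance and the minimizing clone pair. Zero whenever the
    sets intersect.
    """
    if not clones_a or not clones_b:
        raise ArgumentError("both clone sets must be non-empty")
    for clone in sorted(clones_a | clones_b):
        tree.require_clone(clone)
    shared = sorted(clones_a & clones_b)
    if shared:
        return 0, (shared[0], shared[0])
    best = None
    best_pair = None
    for a in sorted(clones_a):
        for b in sorted(clones_b):
            d = tree.path_length(a, b)
            if best is None or d < best:
                best, best_pair = d, (a, b)
    assert best is not None and best_pair is not None
    return best, best_pair


def distance_to_mrca(tree: CloneTree, clone: str) -> int:
    """Number of edges separating ``clone`` from the tree root (MRCA)."""
    return tree.depth(clone)


def terminal_clones(tree: CloneTree) -> Set[str]:
    """Leaves of the phylogeny; internal nodes are the nonterminal clones."""
    return tree.leaves()


def sample_clonal_distances(
    metadata: Sequence[SampleMeta],
    trees: Dict[str, CloneTree],
    sample_types: Sequence[str] = ("primary",),
) -> List[ClonalDistanceRecord]:
    """All within-patient pairwise clonal distances for the given types.

    Samples with no mapped clone are excluded with a warning (tree
    mapping failed upstream).
    """
    wanted = set(sample_types)
    by_patient: Dict[str, List[SampleMeta]] = {}
    for m in metadata:
        if m.sample_type not in wanted:
            continue
        if not m.clones:
            if m.sample_type != "normal":
                logger.warning(
                    "sample %s has no mapped clones; excluded from clonal distances",
                    m.sample_id,
                )
            continue
        by_patient.setdefault(m.patient_id, []).append(m)
    out = []
    for pid in sorted(by_patient):
        tree = trees.get(pid)
        if tree is None:
            logger.warning("patient %s has no clone tree; skipped", pid)
            continue
        members = sorted(by_patient[pid], key=lambda m: m.sample_id)
        for a, b in itertools.combinations(members, 2):
            d, pair = clonal_distance(tree, a.clones, b.clones)
            out.append(
                ClonalDistanceRecord(
                    patient_id=pid,
                    sample_a=a.sample_id,
                    sample_b=b.sample_id,
                    distance=d,
                    resolved_clone_pair=pair,
                    pair_type=pair_type_of(a.sample_type, b.sample_type),
                )
            )
    return out


def classify_seeding(
    tree: CloneTree,
    primary_sample_clones: Set[str],
    metastasis_mrca_clone: str,
) -> Tuple[str, int]:
    """Label a primary sample as seeding/nonseeding for a given metastasis.

    Seeding iff the sample contains the metastasis-founding clone
    (min edge distance 0 from a contained clone to the metastasis MRCA
    clone); the distance reported is that minimum.
    """
    tree.require_clone(metastasis_mrca_clone)
    distance, _ = clonal_distance(tree, primary_sample_clones, {metastasis_mrca_clone})
    return ("seeding" if distance == 0 else "nonseeding"), distance


def assign_clone_profiles(
    expr: Optional[ExpressionMatrix],
    tme: Optional[ExpressionMatrix],
    metadata: Sequence[SampleMeta],
    tree: CloneTree,
) -> List[CloneProfile]:
    """Clone-level expression / TME profiles from monoclonal tumor regions.

    Polyclonal regions are excluded. A clone observed in one monoclonal
    region inherits that region's vectors; in several, the arithmetic
    mean. Clones seen only in polyclonal regions get no profile and are
    reported via logging.
    """
    observed: Dict[str, List[SampleMeta]] = {}
    seen_only_poly: Set[str] = set()
    for m in metadata:
        if m.patient_id != tree.patient_id or not m.is_tumor or not m.clones:
            continue
        if m.is_monoclonal:
            clone = next(iter(m.clones))
            observed.setdefault(clone, []).append(m)
        else:
            seen_only_poly |= m.clones
    unprofiled = sorted(seen_only_poly - set(observed))
    if unprofiled:
        logger.info(
            "patient %s: clones only in polyclonal regions, no profile: %s",
            tree.patient_id,
            unprofiled,
        )
    profiles = []
    for clone in sorted(observed):
        members = observed[clone]
        sample_ids = [m.sample_id for m in members]
        expr_vec = None
        if expr is not None:
            cols = [s for s in sample_ids if s in set(expr.sample_ids)]
            if cols:
                expr_vec = expr.values[:, expr.sample_index(cols)].mean(axis=1)
        tme_vec = None
        if tme is not None:
            cols = [s for s in sample_ids if s in set(tme.sample_ids)]
            if cols:
                tme_vec = tme.values[:, tme.sample_index(cols)].mean(axis=1)
        profiles.append(
            CloneProfile(
                clone_id=clone,
                patient_id=tree.patient_id,
                expression=expr_vec,
                tme=tme_vec,
                n_source_regions=len(members),
                mean_purity=float(np.mean([m.purity for m in members])),
            )
        )
    return profiles
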