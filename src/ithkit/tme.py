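"""ssGSEA scoring, signature Z-scores, antitumor/immunosuppressive TME
classification, directional transition counting with the 0.5-null
chi-squared enrichment, and 3-group infiltration clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats

from .datamodel import ExpressionMatrix, GeneSet
from .errors import ArgumentError, UndefinedStatisticError

logger = logging.getLogger(__name__)

ANTITUMOR = "antitumor"
IMMUNOSUPPRESSIVE = "immunosuppressive"


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def ssgsea_score(
    expression: np.ndarray,
    gene_ids: Sequence[str],
    gene_set: GeneSet,
    exponent: float = 0.25,
) -> float:
    """Single-sample GSEA running-sum score for one sample.

    Genes are ranked by decreasing expression (ties broken by gene id so
    scores are deterministic). With ranks ``N..1`` down the ordering, the
    score is the sum over positions of the difference between the
    weighted in-set ECDF (weights rank**exponent) and the uniform
    out-of-set ECDF. Rank-based, hence invariant under strictly monotone
    transforms of the sample's expression values.
    """
    expression = np.asarray(expression, dtype=float)
    n = expression.size
    if n != len(gene_ids):
        raise ArgumentError("expression vector and gene_ids must align")
    if exponent < 0:
        raise ArgumentError("exponent must be >= 0")
    in_set = np.array([g in gene_set.gene_ids for g in gene_ids])
    n_in = int(in_set.sum())
    if n_in == 0:
        raise UndefinedStatisticError(
            f"gene set {gene_set.name!r} has no overlap with the expression universe"
        )
    if n_in == n:
        raise UndefinedStatisticError(
            f"gene set {gene_set.name!r} covers the whole universe"
        )
    order = sorted(range(n), key=lambda i: (-expression[i], gene_ids[i]))
    ranks = np.arange(n, 0, -1, dtype=float)  # N for the top gene, 1 for the last
    in_ordered = in_set[order]
    weights = np.where(in_ordered, ranks**exponent, 0.0)
    denom_in = weights.sum()
    p_in = np.cumsum(weights) / denom_in
    p_out = np.cumsum(~in_ordered) / float(n - n_in)
    return float(np.sum(p_in - p_out))


def ssgsea_matrix(
    expr: ExpressionMatrix, gene_sets: Sequence[GeneSet], exponent: float = 0.25
) -> pd.DataFrame:
    """Sample x gene-set score table."""
    rows = {}
    for sid in expr.sample_ids:
        vec = expr.sample_vector(sid)
        rows[sid] = {
            gs.name: ssgsea_score(vec, expr.gene_ids, gs, exponent)
            for gs in gene_sets
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[
        expr.sample_ids, [gs.name for gs in gene_sets]
    ]


def zscore(values: Sequence[float]) -> np.ndarray:
    """(x - mean) / sd with the n-1 denominator, across the supplied cohort."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ArgumentError("need >= 2 samples for a Z-score")
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise UndefinedStatisticError("zero standard deviation; Z-score undefined")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# TME classification
# ---------------------------------------------------------------------------

@dataclass
class TMEClassification:
    sample_id: str
    z_teff: float
    z_myeloid: float

    @property
    def delta(self) -> float:
        return self.z_myeloid - self.z_teff

    @property
    def label(self) -> str:
        return ANTITUMOR if self.delta < 0 else IMMUNOSUPPRESSIVE


def classify_tme(z_teff: float, z_myeloid: float) -> str:
    """Antitumor iff myeloid Z minus T-effector Z is negative; ties are
    immunosuppressive."""
    if not (np.isfinite(z_teff) and np.isfinite(z_myeloid)):
        raise ArgumentError("Z-scores must be finite")
    return ANTITUMOR if (z_myeloid - z_teff) < 0 else IMMUNOSUPPRESSIVE


def classify_samples(
    teff_scores: Sequence[float],
    myeloid_scores: Sequence[float],
    sample_ids: Sequence[str],
) -> List[TMEClassification]:
    """Z-score both signatures across the cohort, then label every sample."""
    z_t = zscore(teff_scores)
    z_m = zscore(myeloid_scores)
    return [
        TMEClassification(sample_id=s, z_teff=float(t), z_myeloid=float(m))
        for s, t, m in zip(sample_ids, z_t, z_m)
    ]


# ---------------------------------------------------------------------------
# transitions
# ---------------------------------------------------------------------------

@dataclass
class TransitionTable:
    context: str
    n_stable_antitumor: int = 0
    n_stable_immunosuppressive: int = 0
    n_a_to_i: int = 0
    n_i_to_a: int = 0
    chi2: float = float("nan")
    pvalue: float = float("nan")

    @property
    def n_pairs(self) -> int:
        return (
            self.n_stable_antitumor
            + self.n_stable_immunosuppressive
            + self.n_a_to_i
            + self.n_i_to_a
        )


def count_transitions(
    pairs: Sequence[Tuple[Optional[str], Optional[str]]],
    context: str = "all-pairs",
) -> TransitionTable:
    """Tally stable/switching TME labels over oriented (early, late) pairs.

    Pairs with a missing label on either side are skipped with a log
    entry. The chi-squared enrichment against the 0.5-transition null is
    filled in when at least one switch is observed.
    """
    table = TransitionTable(context=context)
    for first, second in pairs:
        if first is None or second is None:
            logger.warning("pair with unlabeled sample skipped in %s", context)
            continue
        if first == ANTITUMOR and second == ANTITUMOR:
            table.n_stable_antitumor += 1
        elif first == IMMUNOSUPPRESSIVE and second == IMMUNOSUPPRESSIVE:
            table.n_stable_immunosuppressive += 1
        elif first == ANTITUMOR and second == IMMUNOSUPPRESSIVE:
            table.n_a_to_i += 1
        else:
            table.n_i_to_a += 1
    if table.n_a_to_i + table.n_i_to_a >= 1:
        table.chi2, table.pvalue = transition_enrichment(
            table.n_a_to_i, table.n_i_to_a
        )
    return table


def transition_enrichment(n_a_to_i: int, n_i_to_a: int) -> Tuple[float, float]:
    """Goodness-of-fit chi-squared against equal transition probabilities.

    Expected counts are (T/2, T/2) with T the total number of switches;
    1 degree of freedom, no continuity correction.
    """
    total = n_a_to_i + n_i_to_a
    if total < 1:
        raise UndefinedStatisticError("no transitions observed; test undefined")
    expected = total / 2.0
    chi2 = (n_a_to_i - expected) ** 2 / expected + (n_i_to_a - expected) ** 2 / expected
    p = float(scipy.stats.chi2.sf(chi2, df=1))
    return float(chi2), p


# ---------------------------------------------------------------------------
# oriented pair construction for transition contexts
# ---------------------------------------------------------------------------

def oriented_driver_pairs(metadata, driver: str) -> List[Tuple[str, str]]:
    """Within-patient primary pairs oriented WT -> mutant for ``driver``."""
    out = []
    by_patient: Dict[str, list] = {}
    for m in metadata:
        if m.sample_type == "primary":
            by_patient.setdefault(m.patient_id, []).append(m)
    for pid in sorted(by_patient):
        members = sorted(by_patient[pid], key=lambda m: m.sample_id)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                sa = bool(a.driver_status.get(driver, False))
                sb = bool(b.driver_status.get(driver, False))
                if sa == sb:
                    continue
                wt, mut = (a, b) if sb else (b, a)
                out.append((wt.sample_id, mut.sample_id))
    return out


def oriented_terminal_pairs(metadata, trees) -> List[Tuple[str, str]]:
    """Within-patient primary pairs oriented nonterminal -> terminal clone.

    A sample counts as terminal when it contains at least one leaf clone
    and nonterminal when all its clones are internal; mixed-status or
    clone-less samples never form an oriented pair.
    """
    out = []
    by_patient: Dict[str, list] = {}
    for m in metadata:
        if m.sample_type == "primary" and m.clones:
            by_patient.setdefault(m.patient_id, []).append(m)
    for pid in sorted(by_patient):
        tree = trees.get(pid)
        if tree is None:
            continue
        leaves = tree.leaves()
        members = sorted(by_patient[pid], key=lambda m: m.sample_id)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                a_term = bool(a.clones & leaves)
                b_term = bool(b.clones & leaves)
                if a_term == b_term:
                    continue
                early, late = (a, b) if b_term else (b, a)
                out.append((early.sample_id, late.sample_id))
    return out


def all_within_patient_pairs(metadata) -> List[Tuple[str, str]]:
    """Unordered within-patient primary pairs (lexicographic orientation)."""
    out = []
    by_patient: Dict[str, list] = {}
    for m in metadata:
        if m.sample_type == "primary":
            by_patient.setdefault(m.patient_id, []).append(m)
    for pid in sorted(by_patient):
        members = sorted(by_patient[pid], key=lambda m: m.sample_id)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                out.append((a.sample_id, b.sample_id))
    return out


def labeled_pairs(
    pairs: Sequence[Tuple[str, str]], labels: Dict[str, str]
) -> List[Tuple[Optional[str], Optional[str]]]:
    return [(labels.get(a), labels.get(b)) for a, b in pairs]


# ---------------------------------------------------------------------------
# infiltration clustering
# ---------------------------------------------------------------------------

INFILTRATION_LEVELS = ("low", "intermediate", "high")


def cluster_infiltration(
    tme: ExpressionMatrix, k: int = 3
) -> Dict[str, str]:
    """Hierarchical clustering of samples by scaled population abundances.

    Abundances are Z-scaled per population across samples, clustered
    with complete linkage on Manhattan distance and cut into ``k`` = 3
    groups, which are named low/intermediate/high by ascending mean
    total scaled abundance.
    """
    if k != 3:
        raise ArgumentError("the infiltration clustering is defined for k = 3")
    if tme.n_samples < 3:
        raise ArgumentError("need >= 3 samples to form 3 clusters")
    values = tme.values  # populations x samples
    sds = values.std(axis=1, ddof=1, keepdims=True)
    sds[sds == 0.0] = 1.0
    scaled = (values - values.mean(axis=1, keepdims=True)) / sds
    samples = scaled.T
    dist = scipy.spatial.distance.pdist(samples, metric="cityblock")
    linkage = scipy.cluster.hierarchy.linkage(dist, method="complete")
    assignments = scipy.cluster.hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    if len(set(assignments)) < k:
        raise ArgumentError("could not split the samples into 3 clusters")
    totals = samples.sum(axis=1)
    cluster_means = {
        c: float(totals[assignments == c].mean()) for c in sorted(set(assignments))
    }
    ranked = sorted(cluster_means, key=lambda c: cluster_means[c])
    names = {c: INFILTRATION_LEVELS[i] for i, c in enumerate(ranked)}
    return {
        sid: names[assignments[i]] for i, sid in enumerate(tme.sample_ids)
    }
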