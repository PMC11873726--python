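"""Transcriptional and TME distances, per-patient I-TED, and the
bootstrap inter-/intra-tumor heterogeneity ratio.

Transcriptional distance between two samples is 1 - Pearson r over a
fixed cohort-level list of top-variable genes; TME distance is
1 - cosine similarity over cell-population abundance vectors. I-TED is
the per-patient aggregate (median by default) of all primary-primary
pairwise distances.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .datamodel import ExpressionMatrix, SampleMeta, samples_of_patient
from .errors import ArgumentError, UndefinedStatisticError

logger = logging.getLogger(__name__)

PAIR_TYPES = (
    "primary-primary",
    "primary-normal",
    "primary-metastasis",
    "metastasis-metastasis",
)


@dataclass
class PairDistance:
    """Symmetric distance between two samples under one metric."""

    patient_id: str
    sample_a: str
    sample_b: str
    pair_type: str
    distance: float
    metric: str = "transcriptional"


@dataclass
class ITEDResult:
    """Per-patient intratumor expression distance."""

    patient_id: str
    ited: float
    n_pairs: int
    per_pair: List[PairDistance] = field(default_factory=list)
    aggregator: str = "median"


def top_variable_genes(expr: ExpressionMatrix, k: int) -> List[str]:
    """The ``k`` genes with the highest expression variance across samples.

    Variance uses the n-1 denominator across all supplied cohort samples;
    ties break lexicographically by gene id for determinism.
    """
    if k > expr.n_genes:
        raise ArgumentError(
            f"k={k} exceeds the number of genes ({expr.n_genes})"
        )
    if k < 1:
        raise ArgumentError("k must be >= 1")
    if expr.n_samples < 2:
        raise ArgumentError("need >= 2 samples to rank genes by variance")
    variances = expr.values.var(axis=1, ddof=1)
    order = sorted(range(expr.n_genes), key=lambda i: (-variances[i], expr.gene_ids[i]))
    return [expr.gene_ids[i] for i in order[:k]]


def transcriptional_distance(
    x: np.ndarray, y: np.ndarray, genes: Optional[Sequence[int]] = None
) -> float:
    """1 - Pearson correlation between two expression vectors.

    ``genes`` optionally restricts both vectors to the given positions.
    Raises when either restricted vector is constant (correlation
    undefined) rather than silently returning 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if genes is not None:
        idx = np.asarray(genes, dtype=int)
        x = x[idx]
        y = y[idx]
    if x.shape != y.shape or x.ndim != 1:
        raise ArgumentError("expression vectors must be 1-D and equally long")
    if x.size < 3:
        raise ArgumentError("need >= 3 genes for a correlation distance")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(np.dot(xc, xc)))
    sy = float(np.sqrt(np.dot(yc, yc)))
    if sx == 0.0 or sy == 0.0:
        raise UndefinedStatisticError(
            "correlation undefined for a constant expression vector"
        )
    r = float(np.dot(xc, yc) / (sx * sy))
    r = min(1.0, max(-1.0, r))
    return 1.0 - r


def tme_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - cosine similarity between two abundance vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ArgumentError("abundance vectors must be 1-D and equally long")
    if u.size < 2:
        raise ArgumentError("need >= 2 populations for a cosine distance")
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise UndefinedStatisticError("cosine similarity undefined for a zero vector")
    c = float(np.dot(u, v) / (nu * nv))
    c = min(1.0, max(-1.0, c))
    return 1.0 - c


def _aggregate(values: Sequence[float], aggregator: str) -> float:
    if aggregator == "median":
        return float(np.median(values))
    if aggregator == "maximum":
        return float(np.max(values))
    raise ArgumentError(f"unknown aggregator {aggregator!r}")


def pair_type_of(type_a: str, type_b: str) -> str:
    return "-".join(sorted((type_a, type_b)))


def ited(
    expr: ExpressionMatrix,
    metadata: Sequence[SampleMeta],
    patient_id: str,
    genes: Sequence[str],
    aggregator: str = "median",
) -> Optional[ITEDResult]:
    """I-TED for one patient: aggregate of all primary-primary distances.

    Normal / metastasis / thrombus samples are excluded. Patients with
    fewer than two primary samples are skipped (returns None) with a
    logged notice.
    """
    primaries = samples_of_patient(metadata, patient_id, sample_type="primary")
    primaries = [m for m in primaries if m.sample_id in set(expr.sample_ids)]
    if len(primaries) < 2:
        logger.info(
            "patient %s skipped for I-TED: %d primary sample(s)",
            patient_id,
            len(primaries),
        )
        return None
    gene_idx = expr.gene_index(genes)
    per_pair = []
    for a, b in itertools.combinations(primaries, 2):
        d = transcriptional_distance(
            expr.sample_vector(a.sample_id), expr.sample_vector(b.sample_id), gene_idx
        )
        per_pair.append(
            PairDistance(
                patient_id=patient_id,
                sample_a=a.sample_id,
                sample_b=b.sample_id,
                pair_type="primary-primary",
                distance=d,
            )
        )
    values = [p.distance for p in per_pair]
    return ITEDResult(
        patient_id=patient_id,
        ited=_aggregate(values, aggregator),
        n_pairs=len(per_pair),
        per_pair=per_pair,
        aggregator=aggregator,
    )


def cohort_ited(
    expr: ExpressionMatrix,
    metadata: Sequence[SampleMeta],
    genes: Sequence[str],
    aggregator: str = "median",
) -> List[ITEDResult]:
    """I-TED for every multi-primary patient in the cohort."""
    patients = sorted({m.patient_id for m in metadata})
    out = []
    for pid in patients:
        result = ited(expr, metadata, pid, genes, aggregator)
        if result is not None:
            out.append(result)
    return out


def all_pair_distances(
    expr: ExpressionMatrix,
    metadata: Sequence[SampleMeta],
    genes: Sequence[str],
) -> List[PairDistance]:
    """Transcriptional distances between all within-patient sample pairs."""
    gene_idx = expr.gene_index(genes)
    sample_set = set(expr.sample_ids)
    by_patient: Dict[str, List[SampleMeta]] = {}
    for m in metadata:
        if m.sample_id in sample_set:
            by_patient.setdefault(m.patient_id, []).append(m)
    out = []
    for pid in sorted(by_patient):
        members = sorted(by_patient[pid], key=lambda m: m.sample_id)
        for a, b in itertools.combinations(members, 2):
            d = transcriptional_distance(
                expr.sample_vector(a.sample_id),
                expr.sample_vector(b.sample_id),
                gene_idx,
            )
            out.append(
                PairDistance(
                    patient_id=pid,
                    sample_a=a.sample_id,
                    sample_b=b.sample_id,
                    pair_type=pair_type_of(a.sample_type, b.sample_type),
                    distance=d,
                )
            )
    return out


def inter_patient_distances(
    expr: ExpressionMatrix,
    metadata: Sequence[SampleMeta],
    genes: Sequence[str],
    sample_type: str = "primary",
) -> List[float]:
    """Distances between samples of different patients (intertumor side)."""
    gene_idx = expr.gene_index(genes)
    sample_set = set(expr.sample_ids)
    members = sorted(
        (m for m in metadata if m.sample_type == sample_type and m.sample_id in sample_set),
        key=lambda m: m.sample_id,
    )
    out = []
    for a, b in itertools.combinations(members, 2):
        if a.patient_id == b.patient_id:
            continue
        out.append(
            transcriptional_distance(
                expr.sample_vector(a.sample_id),
                expr.sample_vector(b.sample_id),
                gene_idx,
            )
        )
    return out


def inter_intra_ratio(
    intra: Sequence[float],
    inter: Sequence[float],
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> Tuple[float, float, float]:
    """mean(inter)/mean(intra) with a percentile bootstrap 95% CI.

    Both pair lists are independently resampled with replacement
    ``n_bootstrap`` times; the CI is the (2.5%, 97.5%) quantile pair of
    the resampled ratios.
    """
    intra = np.asarray(intra, dtype=float)
    inter = np.asarray(inter, dtype=float)
    if intra.size == 0 or inter.size == 0:
        raise ArgumentError("both distance lists must be non-empty")
    if n_bootstrap < 100:
        raise ArgumentError("need >= 100 bootstrap iterations")
    if intra.mean() == 0.0:
        raise UndefinedStatisticError("mean intra-tumor distance is zero")
    rng = np.random.default_rng(seed)
    ratios = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        intra_b = rng.choice(intra, size=intra.size, replace=True)
        inter_b = rng.choice(inter, size=inter.size, replace=True)
        mean_intra = intra_b.mean()
        ratios[b] = np.inf if mean_intra == 0.0 else inter_b.mean() / mean_intra
    ratio = float(inter.mean() / intra.mean())
    lo, hi = np.quantile(ratios, [0.025, 0.975])
    return ratio, float(lo), float(hi)


def summarize_pair_type_per_patient(
    pairs: Sequence[PairDistance], aggregator: str = "median"
) -> Dict[Tuple[str, str], float]:
    """Per-patient, per-pair-type summary (median default, maximum optional).

    Used when contrasting e.g. primary-primary against primary-normal
    distances with one value per patient and type.
    """
    grouped: Dict[Tuple[str, str], List[float]] = {}
    for p in pairs:
        grouped.setdefault((p.patient_id, p.pair_type), []).append(p.distance)
    return {key: _aggregate(vals, aggregator) for key, vals in sorted(grouped.items())}
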