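"""Immune repertoire statistics: Morisita-Horn overlap, Gini clonality,
clonotype sharing reports, and the overlap-vs-clonal-distance
association (delegated to the mixed-effects helper).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .datamodel import Repertoire
from .errors import ArgumentError, UndefinedStatisticError
from .models import AssociationResult, lme_association

logger = logging.getLogger(__name__)


@dataclass
class RepertoireOverlap:
    sample_a: str
    sample_b: str
    chain: str
    morisita_horn: float
    n_shared: int

    @property
    def shares_any(self) -> bool:
        return self.n_shared > 0


@dataclass
class DiversityStats:
    sample_id: str
    chain: str
    n_clonotypes: int
    gini: float
    top_clone_fraction: float


def morisita_horn(rep_a: Repertoire, rep_b: Repertoire) -> float:
    """Morisita-Horn similarity in [0, 1] over the clonotype-key union.

    MH = 2 * sum(x_i * y_i) / ((lambda_x + lambda_y) * X * Y) with
    X = sum(x), Y = sum(y), lambda = sum(c^2)/C^2 per repertoire; absent
    clonotypes count 0. Symmetric; invariant to rescaling either side.
    """
    if not rep_a.counts or not rep_b.counts:
        raise UndefinedStatisticError("Morisita-Horn undefined for an empty repertoire")
    keys = set(rep_a.counts) | set(rep_b.counts)
    x = np.array([rep_a.counts.get(k, 0) for k in sorted(keys)], dtype=float)
    y = np.array([rep_b.counts.get(k, 0) for k in sorted(keys)], dtype=float)
    total_x = x.sum()
    total_y = y.sum()
    lam_x = float(np.sum(x**2)) / total_x**2
    lam_y = float(np.sum(y**2)) / total_y**2
    return float(2.0 * np.dot(x, y) / ((lam_x + lam_y) * total_x * total_y))


def gini(rep: Repertoire) -> float:
    """Gini coefficient of the clonotype counts via the mean absolute
    difference: G = sum_ij |c_i - c_j| / (2 n^2 mean). 0 for a uniform
    repertoire; invariant to rescaling counts.
    """
    if not rep.counts:
        raise UndefinedStatisticError("Gini undefined for an empty repertoire")
    counts = np.array(sorted(rep.counts.values()), dtype=float)
    n = counts.size
    mean = counts.mean()
    if mean == 0.0:
        raise UndefinedStatisticError("Gini undefined for all-zero counts")
    # O(n log n) identity for the pairwise mean absolute difference
    ranks = np.arange(1, n + 1)
    return float(np.sum((2 * ranks - n - 1) * counts) / (n**2 * mean))


def diversity(rep: Repertoire) -> DiversityStats:
    counts = np.array(list(rep.counts.values()), dtype=float)
    return DiversityStats(
        sample_id=rep.sample_id,
        chain=rep.chain,
        n_clonotypes=rep.n_clonotypes,
        gini=gini(rep),
        top_clone_fraction=float(counts.max() / counts.sum()),
    )


def pairwise_overlap(
    rep_a: Repertoire, rep_b: Repertoire
) -> RepertoireOverlap:
    if rep_a.chain != rep_b.chain:
        raise ArgumentError("cannot compare repertoires of different chains")
    shared = set(rep_a.counts) & set(rep_b.counts)
    return RepertoireOverlap(
        sample_a=rep_a.sample_id,
        sample_b=rep_b.sample_id,
        chain=rep_a.chain,
        morisita_horn=morisita_horn(rep_a, rep_b),
        n_shared=len(shared),
    )


def shared_clonotype_report(
    primary_reps: Sequence[Repertoire],
    other_reps: Sequence[Repertoire],
) -> pd.DataFrame:
    """Sharing between each primary/other repertoire pair of one chain.

    One row per shared clonotype per pair, with within-sample frequency
    in each compartment; pairs with no shared clonotype contribute a
    single row with an empty clonotype and shares_any = False.
    """
    rows = []
    for rep_p in sorted(primary_reps, key=lambda r: r.sample_id):
        for rep_o in sorted(other_reps, key=lambda r: r.sample_id):
            if rep_p.chain != rep_o.chain:
                continue
            shared = sorted(set(rep_p.counts) & set(rep_o.counts))
            if not shared:
                rows.append(
                    {
                        "primary_sample": rep_p.sample_id,
                        "other_sample": rep_o.sample_id,
                        "chain": rep_p.chain,
                        "shares_any": False,
                        "clonotype": "",
                        "freq_primary": np.nan,
                        "freq_other": np.nan,
                    }
                )
                continue
            for key in shared:
                rows.append(
                    {
                        "primary_sample": rep_p.sample_id,
                        "other_sample": rep_o.sample_id,
                        "chain": rep_p.chain,
                        "shares_any": True,
                        "clonotype": key,
                        "freq_primary": rep_p.counts[key] / rep_p.total,
                        "freq_other": rep_o.counts[key] / rep_o.total,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "primary_sample", "other_sample", "chain", "shares_any",
            "clonotype", "freq_primary", "freq_other",
        ],
    )


def repertoire_vs_clonal_distance(
    overlaps: Sequence[RepertoireOverlap],
    clonal_distances: Dict[Tuple[str, str], int],
    groups: Dict[Tuple[str, str], str],
    purity_diffs: Optional[Dict[Tuple[str, str], float]] = None,
) -> AssociationResult:
    """Mixed-effects slope of MH similarity on clonal distance.

    Pair keys are (sample_a, sample_b) in either orientation; purity
    differences, when supplied, enter as a covariate.
    """
    y, x, g, dp = [], [], [], []
    for ov in overlaps:
        key = (ov.sample_a, ov.sample_b)
        alt = (ov.sample_b, ov.sample_a)
        use = key if key in clonal_distances else alt
        if use not in clonal_distances:
            raise ArgumentError(f"no clonal distance for pair {key}")
        y.append(ov.morisita_horn)
        x.append(float(clonal_distances[use]))
        g.append(groups[use if use in groups else key])
        if purity_diffs is not None:
            dp.append(abs(purity_diffs[use]))
    covs = pd.DataFrame({"d_purity": dp}) if purity_diffs is not None else None
    return lme_association(y, x, g, covariates=covs)
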