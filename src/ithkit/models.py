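"""Regression layer.

* per-pair gene-level difference models (expression change ~ CN change,
  epigenetic-driver change, 9p-loss change, purity change, random
  baseline covariates; patient and WGD-status as random intercepts),
* sequential-sum-of-squares variance decomposition of per-patient I-TED,
* a generic mixed-effects association helper with patient random
  intercepts (clonal-distance trends, MRCA trends, seeding contrasts),
* paired Wilcoxon driver-pathway tests,
* the locus eQTL with a 70% expression-prevalence filter.

BH-FDR is the only multiple-testing correction used anywhere.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .datamodel import (
    EPIGENETIC_DRIVERS,
    ExpressionMatrix,
    SampleMeta,
)
from .errors import ArgumentError, UndefinedStatisticError

logger = logging.getLogger(__name__)

GENE_MODEL_COVARIATES = (
    "d_cn",
    "d_epi",
    "d_9p",
    "d_purity",
    "rand_binary",
    "rand_continuous",
)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN-safe)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# pair differences
# ---------------------------------------------------------------------------

@dataclass
class SamplePairDiff:
    """Per-pair differences (second sample minus first, lexicographic order)."""

    patient_id: str
    sample_a: str
    sample_b: str
    pair_type: str
    d_expr: np.ndarray
    d_cn: np.ndarray  # float; NaN where masked (9p-arm genes / missing CN)
    d_purity: float
    d_epi: int
    d_9p: int
    d_wgd: int
    d_type: int
    rand_binary: int
    rand_continuous: float
    wgd_group: str


def _signed_status(a: bool, b: bool) -> int:
    """+1 if present in second sample only, -1 if first only, else 0."""
    return int(bool(b)) - int(bool(a))


def build_pair_diffs(
    expr: ExpressionMatrix,
    cn: Optional[ExpressionMatrix],
    gene_arms: Mapping[str, str],
    metadata: Sequence[SampleMeta],
    pair_types: Sequence[str] = ("primary-primary",),
    seed: int = 0,
) -> Tuple[List[SamplePairDiff], List[str]]:
    """All within-patient sample pairs of the requested types.

    Pairs receive a canonical lexicographic sample ordering so all d_
    signs are reproducible; every d_ field negates under a swap. CN
    differences for genes on arm 9p are masked (NaN) to avoid
    collinearity with the 9p-loss status difference. ``d_type`` encodes
    normal/metastasis contrasts (+1 second sample of the later type).
    Random baseline covariates are drawn per pair from ``seed``.
    """
    rng = np.random.default_rng(seed)
    genes = list(expr.gene_ids)
    mask_9p = np.array([gene_arms.get(g) == "9p" for g in genes])
    cn_missing = np.zeros(len(genes), dtype=bool)
    if cn is not None:
        cn_gene_set = set(cn.gene_ids)
        cn_missing = np.array([g not in cn_gene_set for g in genes])
        if cn_missing.any():
            logger.info(
                "%d genes without copy number dropped from d_cn", int(cn_missing.sum())
            )
    wanted = set(pair_types)
    sample_set = set(expr.sample_ids)
    by_patient: Dict[str, List[SampleMeta]] = {}
    for m in metadata:
        if m.sample_id in sample_set:
            by_patient.setdefault(m.patient_id, []).append(m)
    pairs: List[SamplePairDiff] = []
    for pid in sorted(by_patient):
        members = sorted(by_patient[pid], key=lambda m: m.sample_id)
        for a, b in itertools.combinations(members, 2):
            ptype = "-".join(sorted((a.sample_type, b.sample_type)))
            if ptype not in wanted:
                continue
            d_expr = expr.sample_vector(b.sample_id) - expr.sample_vector(a.sample_id)
            d_cn = np.full(len(genes), np.nan)
            if cn is not None:
                keep = ~(mask_9p | cn_missing)
                kept_genes = [g for g, k in zip(genes, keep) if k]
                idx = cn.gene_index(kept_genes)
                vals = (
                    cn.values[idx][:, cn.sample_index([b.sample_id])[0]]
                    - cn.values[idx][:, cn.sample_index([a.sample_id])[0]]
                )
                d_cn[keep] = vals
            d_type = 0
            if ptype == "normal-primary":
                d_type = _signed_status(
                    a.sample_type == "normal", b.sample_type == "normal"
                )
            elif ptype == "metastasis-primary":
                d_type = _signed_status(
                    a.sample_type == "metastasis", b.sample_type == "metastasis"
                )
            pairs.append(
                SamplePairDiff(
                    patient_id=pid,
                    sample_a=a.sample_id,
                    sample_b=b.sample_id,
                    pair_type=ptype,
                    d_expr=d_expr,
                    d_cn=d_cn,
                    d_purity=float(b.purity - a.purity),
                    d_epi=b.n_epigenetic_drivers() - a.n_epigenetic_drivers(),
                    d_9p=_signed_status(
                        a.driver_status.get("9p_loss", False),
                        b.driver_status.get("9p_loss", False),
                    ),
                    d_wgd=_signed_status(a.wgd, b.wgd),
                    d_type=d_type,
                    rand_binary=int(rng.integers(0, 2)),
                    rand_continuous=float(rng.normal()),
                    wgd_group=f"{int(a.wgd)}{int(b.wgd)}",
                )
            )
    return pairs, genes


# ---------------------------------------------------------------------------
# per-gene mixed models
# ---------------------------------------------------------------------------

@dataclass
class GeneModelResult:
    gene_id: str
    n_pairs: int
    converged: bool
    coefficients: Dict[str, float] = field(default_factory=dict)
    pvalues: Dict[str, float] = field(default_factory=dict)
    fdr: Dict[str, float] = field(default_factory=dict)


def _wgd_vcspec(
    groups: np.ndarray, wgd_groups: np.ndarray
) -> Optional[VCSpec]:
    """Variance component for WGD-status random intercepts, nested in patient.

    Nested approximation of the crossed patient x WGD random structure.
    Returns None when WGD status never varies (component unidentifiable).
    """
    levels = sorted(set(wgd_groups))
    if len(levels) < 2:
        return None
    mats = []
    colnames = []
    for g in pd.unique(groups):
        sub = wgd_groups[groups == g]
        mat = np.column_stack([(sub == lev).astype(float) for lev in levels])
        mats.append(mat)
        colnames.append([f"wgd[{lev}]" for lev in levels])
    return VCSpec(["wgd"], [colnames], [mats])


def fit_gene_models(
    pairs: Sequence[SamplePairDiff],
    genes: Optional[Sequence[str]] = None,
    gene_index: Optional[Mapping[str, int]] = None,
    include_d_type: bool = False,
    reml: bool = True,
) -> List[GeneModelResult]:
    """Fit one mixed model per gene: d_expr ~ covariates, (1 | patient) + (1 | WGD).

    Constant covariates are dropped with a warning; genes whose masked
    d_cn is entirely NaN lose the d_cn term. Non-converging mixed fits
    fall back to fixed-effects OLS and are flagged ``converged=False``.
    BH-FDR is applied per covariate across genes.
    """
    if not pairs:
        raise ArgumentError("no sample pairs supplied")
    patients = np.array([p.patient_id for p in pairs])
    if len(set(patients)) < 2:
        raise ArgumentError("need pairs from >= 2 patients")
    if gene_index is None:
        n_genes_available = pairs[0].d_expr.size
        gene_index = {f"g{i}": i for i in range(n_genes_available)}
    if genes is None:
        genes = list(gene_index)

    base_cols: Dict[str, np.ndarray] = {
        "d_epi": np.array([p.d_epi for p in pairs], dtype=float),
        "d_9p": np.array([p.d_9p for p in pairs], dtype=float),
        "d_purity": np.array([p.d_purity for p in pairs], dtype=float),
        "rand_binary": np.array([p.rand_binary for p in pairs], dtype=float),
        "rand_continuous": np.array([p.rand_continuous for p in pairs], dtype=float),
    }
    if include_d_type:
        base_cols["d_type"] = np.array([p.d_type for p in pairs], dtype=float)
    dropped = [name for name, col in base_cols.items() if np.ptp(col) == 0.0]
    for name in dropped:
        logger.warning("covariate %s constant across pairs; dropped", name)
        del base_cols[name]
    wgd_groups = np.array([p.wgd_group for p in pairs])
    vcspec = _wgd_vcspec(patients, wgd_groups)

    d_expr_mat = np.vstack([p.d_expr for p in pairs])
    d_cn_mat = np.vstack([p.d_cn for p in pairs])

    results: List[GeneModelResult] = []
    for gene in genes:
        gi = gene_index[gene]
        y = d_expr_mat[:, gi]
        cols = dict(base_cols)
        d_cn = d_cn_mat[:, gi]
        if np.all(np.isnan(d_cn)):
            logger.debug("gene %s: d_cn fully masked; term dropped", gene)
        elif np.ptp(d_cn[~np.isnan(d_cn)]) == 0.0:
            logger.debug("gene %s: d_cn constant; term dropped", gene)
        else:
            cols = {"d_cn": np.where(np.isnan(d_cn), 0.0, d_cn), **cols}
        names = list(cols)
        exog = np.column_stack([np.ones(len(pairs))] + [cols[c] for c in names])
        exog_names = ["const"] + names
        coefs, pvals, converged = _fit_mixed_or_ols(
            y, exog, exog_names, patients, vcspec, reml
        )
        results.append(
            GeneModelResult(
                gene_id=gene,
                n_pairs=len(pairs),
                converged=converged,
                coefficients=coefs,
                pvalues=pvals,
            )
        )

    all_covs = sorted({c for r in results for c in r.pvalues})
    for cov in all_covs:
        pvec = np.array([r.pvalues.get(cov, np.nan) for r in results])
        fdr = bh_fdr(pvec)
        for r, q in zip(results, fdr):
            if cov in r.pvalues:
                r.fdr[cov] = float(q)
    return results


def _singleton_groups(groups: np.ndarray) -> bool:
    _, counts = np.unique(groups, return_counts=True)
    return bool(counts.max() == 1)


def _fit_mixed_or_ols(
    y: np.ndarray,
    exog: np.ndarray,
    exog_names: List[str],
    groups: np.ndarray,
    vcspec: Optional[VCSpec],
    reml: bool,
) -> Tuple[Dict[str, float], Dict[str, float], bool]:
    if _singleton_groups(groups):
        # one observation per group: the random intercept is unidentifiable
        # and the mixed model degenerates to OLS by construction
        fit = sm.OLS(y, exog).fit()
        coefs = dict(zip(exog_names, (float(v) for v in fit.params)))
        pvals = dict(zip(exog_names, (float(v) for v in fit.pvalues)))
        return coefs, pvals, True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            if vcspec is not None:
                model = MixedLM(y, exog, groups=groups, exog_vc=vcspec)
            else:
                model = MixedLM(y, exog, groups=groups)
            fit = model.fit(reml=reml, disp=False)
        if not np.all(np.isfinite(fit.params[: len(exog_names)])) or not np.all(
            np.isfinite(fit.pvalues[: len(exog_names)])
        ):
            raise ValueError("non-finite mixed-model estimates")
        coefs = dict(zip(exog_names, (float(v) for v in fit.params[: len(exog_names)])))
        pvals = dict(
            zip(exog_names, (float(v) for v in fit.pvalues[: len(exog_names)]))
        )
        return coefs, pvals, True
    except (ConvergenceWarning, np.linalg.LinAlgError, ValueError, Warning):
        fit = sm.OLS(y, exog).fit()
        coefs = dict(zip(exog_names, (float(v) for v in fit.params)))
        pvals = dict(zip(exog_names, (float(v) for v in fit.pvalues)))
        return coefs, pvals, False


# ---------------------------------------------------------------------------
# I-TED variance decomposition
# ---------------------------------------------------------------------------

ITED_COVARIATE_ORDER = (
    "purity_ith",
    "tumor_size",
    "n_regions",
    "genetic_ith",
    "cn_heterogeneity",
    "stage",
    "subclonal_epigenetic",
    "subclonal_9p_loss",
    "subclonal_14q_loss",
)


@dataclass
class VarianceDecomposition:
    covariates: List[str]
    variance_fraction: Dict[str, float]
    pvalues: Dict[str, float]
    fdr: Dict[str, float]
    total_explained: float


def decompose_ited_variance(
    ited: Sequence[float],
    covariates: pd.DataFrame,
    order: Optional[Sequence[str]] = None,
) -> VarianceDecomposition:
    """Sequential (type-I) sum-of-squares share of each covariate.

    Covariates enter in ``order`` (default: the nine published features
    in their stated listing order when present, otherwise column order).
    Per-term F-tests use the full-model residual mean square, as in a
    classic sequential ANOVA on a linear model; BH-FDR across terms.
    """
    y = np.asarray(ited, dtype=float)
    if order is None:
        known = [c for c in ITED_COVARIATE_ORDER if c in covariates.columns]
        order = known if len(known) == len(covariates.columns) else list(covariates.columns)
    order = list(order)
    x = covariates.loc[:, order].to_numpy(dtype=float)
    n, k = x.shape
    if y.size != n:
        raise ArgumentError("ited and covariates must align")
    if n <= k + 1:
        raise ArgumentError(
            f"{n} patients cannot identify {k} covariates plus intercept"
        )
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise UndefinedStatisticError("I-TED values are constant")

    def rss(n_terms: int) -> float:
        design = np.column_stack([np.ones(n)] + [x[:, : n_terms]]) if n_terms else np.ones((n, 1))
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        return float(resid @ resid)

    rss_path = [rss(j) for j in range(k + 1)]
    seq_ss = np.array([rss_path[j] - rss_path[j + 1] for j in range(k)])
    seq_ss = np.maximum(seq_ss, 0.0)
    dof_resid = n - k - 1
    mse = rss_path[-1] / dof_resid
    if mse <= 0:
        fvals = np.full(k, np.inf)
        pvals = np.zeros(k)
    else:
        fvals = seq_ss / mse
        pvals = scipy.stats.f.sf(fvals, 1, dof_resid)
    fdr = bh_fdr(pvals)
    fractions = seq_ss / sst
    return VarianceDecomposition(
        covariates=order,
        variance_fraction={c: float(f) for c, f in zip(order, fractions)},
        pvalues={c: float(p) for c, p in zip(order, pvals)},
        fdr={c: float(q) for c, q in zip(order, fdr)},
        total_explained=float(1.0 - rss_path[-1] / sst),
    )


def driver_swap_decompositions(
    ited: Sequence[float],
    base_covariates: pd.DataFrame,
    driver_cnas: pd.DataFrame,
) -> Dict[str, VarianceDecomposition]:
    """Refit the I-TED model once per driver CNA (one driver column at a time)."""
    out = {}
    for driver in driver_cnas.columns:
        covs = base_covariates.copy()
        covs[driver] = driver_cnas[driver].to_numpy(dtype=float)
        out[driver] = decompose_ited_variance(ited, covs, order=list(covs.columns))
    return out


# ---------------------------------------------------------------------------
# generic mixed-effects association
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    coefficient: float
    tvalue: float
    pvalue: float
    n: int
    n_groups: int
    method: str  # "lme" or "ols"


def lme_association(
    y: Sequence[float],
    x: Sequence[float],
    groups: Sequence[str],
    covariates: Optional[pd.DataFrame] = None,
    reml: bool = True,
) -> AssociationResult:
    """Slope of ``x`` on ``y`` with a patient random intercept.

    Falls back to OLS (logged) when only one group is available. A
    response with zero variance returns a zero slope with p = 1.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    groups = np.asarray(groups)
    if y.size != x.size or y.size != groups.size:
        raise ArgumentError("y, x and groups must align")
    if y.size < 3:
        raise ArgumentError("need >= 3 observations")
    cov_mat = None
    if covariates is not None and covariates.shape[1] > 0:
        cov_mat = covariates.to_numpy(dtype=float)
    if np.ptp(y) == 0.0:
        return AssociationResult(0.0, 0.0, 1.0, int(y.size), len(set(groups)), "degenerate")
    if np.ptp(x) == 0.0:
        raise ArgumentError("predictor x is constant")
    parts = [np.ones(y.size), x]
    if cov_mat is not None:
        parts.extend(cov_mat.T)
    exog = np.column_stack(parts)
    n_groups = len(pd.unique(groups))
    if n_groups < 2 or _singleton_groups(groups):
        if n_groups < 2:
            logger.warning("single group: mixed model downgraded to OLS")
        fit = sm.OLS(y, exog).fit()
        return AssociationResult(
            float(fit.params[1]), float(fit.tvalues[1]), float(fit.pvalues[1]),
            int(y.size), n_groups, "ols",
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            fit = MixedLM(y, exog, groups=groups).fit(reml=reml, disp=False)
        return AssociationResult(
            float(fit.params[1]), float(fit.tvalues[1]), float(fit.pvalues[1]),
            int(y.size), n_groups, "lme",
        )
    except (ConvergenceWarning, np.linalg.LinAlgError, ValueError, Warning):
        logger.warning("mixed model failed to converge; OLS fallback")
        fit = sm.OLS(y, exog).fit()
        return AssociationResult(
            float(fit.params[1]), float(fit.tvalues[1]), float(fit.pvalues[1]),
            int(y.size), n_groups, "ols",
        )


# ---------------------------------------------------------------------------
# paired driver-pathway tests
# ---------------------------------------------------------------------------

def paired_driver_association(
    scores: pd.DataFrame,
    driver: str,
    metadata: Sequence[SampleMeta],
    sample_types: Sequence[str] = ("primary",),
) -> pd.DataFrame:
    """Within-patient WT vs mutant pathway-score contrast (paired Wilcoxon).

    ``scores`` is sample x pathway. Only patients with at least one WT
    and one mutant sample for ``driver`` enter; per patient, scores are
    averaged within each status group before pairing. Zero-difference
    patients are dropped by the signed-rank convention (count reported);
    an all-zero pathway is reported with p = 1 and flagged.
    """
    wanted = set(sample_types)
    sample_set = set(scores.index)
    per_patient: Dict[str, Dict[str, List[str]]] = {}
    for m in metadata:
        if m.sample_type not in wanted or m.sample_id not in sample_set:
            continue
        status = "mut" if m.driver_status.get(driver, False) else "wt"
        per_patient.setdefault(m.patient_id, {"wt": [], "mut": []})[status].append(
            m.sample_id
        )
    eligible = {
        pid: groups
        for pid, groups in per_patient.items()
        if groups["wt"] and groups["mut"]
    }
    columns = [
        "pathway", "wt_mean", "mut_mean", "n_patients", "n_zero_diff",
        "all_zero", "pvalue", "fdr",
    ]
    if len(eligible) < 2:
        logger.warning(
            "driver %s: %d eligible patient(s); returning empty table",
            driver, len(eligible),
        )
        return pd.DataFrame(columns=columns)
    rows = []
    for pathway in scores.columns:
        wt_means, mut_means = [], []
        for pid in sorted(eligible):
            groups = eligible[pid]
            wt_means.append(float(scores.loc[groups["wt"], pathway].mean()))
            mut_means.append(float(scores.loc[groups["mut"], pathway].mean()))
        diffs = np.asarray(mut_means) - np.asarray(wt_means)
        n_zero = int(np.sum(diffs == 0.0))
        all_zero = bool(np.all(diffs == 0.0))
        if all_zero:
            p = 1.0
        else:
            p = float(
                scipy.stats.wilcoxon(
                    diffs, zero_method="wilcox", alternative="two-sided"
                ).pvalue
            )
        rows.append(
            {
                "pathway": pathway,
                "wt_mean": float(np.mean(wt_means)),
                "mut_mean": float(np.mean(mut_means)),
                "n_patients": len(eligible),
                "n_zero_diff": n_zero,
                "all_zero": all_zero,
                "pvalue": p,
            }
        )
    table = pd.DataFrame(rows, columns=columns[:-1])
    table["fdr"] = bh_fdr(table["pvalue"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# locus eQTL
# ---------------------------------------------------------------------------

def locus_eqtl(
    feature_expr: ExpressionMatrix,
    locus_cn: ExpressionMatrix,
    purity: Mapping[str, float],
    binary_status: Mapping[str, bool],
    groups: Mapping[str, str],
    expressed_fraction: float = 0.70,
) -> pd.DataFrame:
    """Per-feature mixed model: expression ~ locus CN + purity + status, (1|patient).

    Features expressed (value > 0) in strictly less than
    ``expressed_fraction`` of samples are excluded before testing.
    BH-FDR across retained features.
    """
    samples = list(feature_expr.sample_ids)
    if locus_cn.sample_ids != samples or locus_cn.gene_ids != feature_expr.gene_ids:
        raise ArgumentError("feature_expr and locus_cn must share both axes")
    pur = np.array([float(purity[s]) for s in samples])
    status = np.array([float(bool(binary_status[s])) for s in samples])
    grp = np.array([groups[s] for s in samples])
    detected = (feature_expr.values > 0).mean(axis=1)
    keep = detected >= expressed_fraction
    if not keep.any():
        logger.warning("all features fall below the %.0f%% expression filter",
                       100 * expressed_fraction)
        return pd.DataFrame(
            columns=["feature", "expressed_fraction", "cn_coef", "pvalue", "fdr", "method"]
        )
    rows = []
    for fi in np.flatnonzero(keep):
        y = feature_expr.values[fi]
        x = locus_cn.values[fi]
        covs = pd.DataFrame({"purity": pur, "status": status})
        covs = covs.loc[:, [c for c in covs.columns if np.ptp(covs[c].to_numpy()) > 0]]
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            rows.append(
                {
                    "feature": feature_expr.gene_ids[fi],
                    "expressed_fraction": float(detected[fi]),
                    "cn_coef": 0.0,
                    "pvalue": 1.0,
                    "method": "degenerate",
                }
            )
            continue
        res = lme_association(y, x, grp, covariates=covs)
        rows.append(
            {
                "feature": feature_expr.gene_ids[fi],
                "expressed_fraction": float(detected[fi]),
                "cn_coef": res.coefficient,
                "pvalue": res.pvalue,
                "method": res.method,
            }
        )
    table = pd.DataFrame(rows)
    table["fdr"] = bh_fdr(table["pvalue"].to_numpy())
    return table[["feature", "expressed_fraction", "cn_coef", "pvalue", "fdr", "method"]]
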