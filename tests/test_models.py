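import numpy as np
import pandas as pd
import pytest
import scipy.stats

from ithkit.datamodel import ExpressionMatrix, SampleMeta
from ithkit.errors import ArgumentError
from ithkit.models import (
    bh_fdr,
    build_pair_diffs,
    decompose_ited_variance,
    driver_swap_decompositions,
    fit_gene_models,
    lme_association,
    locus_eqtl,
    paired_driver_association,
)
from ithkit.simulate import SimulationConfig, simulate_cohort


# ---------------------------------------------------------------------------
# build_pair_diffs
# ---------------------------------------------------------------------------

def _pair_fixture(sample_ids=("s1", "s2")):
    genes = ["g9p", "gOther"]
    arms = {"g9p": "9p", "gOther": "5q"}
    expr = ExpressionMatrix(
        np.array([[1.0, 2.0], [3.0, 5.0]]), genes, list(sample_ids)
    )
    cn = ExpressionMatrix(
        np.array([[2.0, 1.0], [2.0, 3.0]]), genes, list(sample_ids)
    )
    meta = [
        SampleMeta(sample_ids[0], "pA", "primary", purity=0.5,
                   driver_status={"9p_loss": False, "SETD2": False}),
        SampleMeta(sample_ids[1], "pA", "primary", purity=0.8, wgd=True,
                   driver_status={"9p_loss": True, "SETD2": True}),
    ]
    return expr, cn, arms, meta


class TestBuildPairDiffs:
    def test_9p_loss_in_second_sample(self):
        expr, cn, arms, meta = _pair_fixture()
        pairs, genes = build_pair_diffs(expr, cn, arms, meta)
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.sample_a, p.sample_b) == ("s1", "s2")
        assert p.d_9p == +1
        assert p.d_epi == +1
        assert p.d_wgd == +1
        assert p.d_purity == pytest.approx(0.3)

    def test_9p_gene_masked_other_kept(self):
        expr, cn, arms, meta = _pair_fixture()
        pairs, genes = build_pair_diffs(expr, cn, arms, meta)
        p = pairs[0]
        assert np.isnan(p.d_cn[genes.index("g9p")])
        assert p.d_cn[genes.index("gOther")] == 1.0

    def test_identical_genotypes_zero_fields(self):
        genes = ["g0"]
        arms = {"g0": "5q"}
        expr = ExpressionMatrix(np.array([[1.0, 1.0]]), genes, ["s1", "s2"])
        cn = ExpressionMatrix(np.array([[2.0, 2.0]]), genes, ["s1", "s2"])
        meta = [
            SampleMeta("s1", "pA", "primary", purity=0.6),
            SampleMeta("s2", "pA", "primary", purity=0.6),
        ]
        pairs, _ = build_pair_diffs(expr, cn, arms, meta)
        p = pairs[0]
        assert p.d_epi == p.d_9p == p.d_wgd == p.d_type == 0
        assert p.d_purity == 0.0
        assert p.d_cn[0] == 0.0

    def test_antisymmetry_under_sample_relabeling(self):
        # flipping the lexicographic order of the sample ids negates all d_ fields
        fwd_expr, fwd_cn, arms, fwd_meta = _pair_fixture(("a1", "b2"))
        rev_expr, rev_cn, _, rev_meta = _pair_fixture(("z1", "a2"))
        fwd, _ = build_pair_diffs(fwd_expr, fwd_cn, arms, fwd_meta)
        rev, _ = build_pair_diffs(rev_expr, rev_cn, arms, rev_meta)
        f, r = fwd[0], rev[0]
        assert (f.sample_a, f.sample_b) == ("a1", "b2")
        assert (r.sample_a, r.sample_b) == ("a2", "z1")
        assert r.d_9p == -f.d_9p
        assert r.d_epi == -f.d_epi
        assert r.d_wgd == -f.d_wgd
        assert r.d_purity == pytest.approx(-f.d_purity)
        np.testing.assert_allclose(r.d_expr, -f.d_expr)
        mask = ~np.isnan(f.d_cn)
        np.testing.assert_allclose(r.d_cn[mask], -f.d_cn[mask])

    def test_normal_pair_type_encoding(self):
        genes = ["g0"]
        arms = {"g0": "5q"}
        expr = ExpressionMatrix(np.array([[1.0, 2.0]]), genes, ["s1", "s2"])
        meta = [
            SampleMeta("s1", "pA", "normal"),
            SampleMeta("s2", "pA", "primary"),
        ]
        pairs, _ = build_pair_diffs(
            expr, None, arms, meta, pair_types=("normal-primary",)
        )
        # second sample primary, first normal -> d_type = -1 (normal in first)
        assert pairs[0].pair_type == "normal-primary"
        assert pairs[0].d_type == -1


# ---------------------------------------------------------------------------
# fit_gene_models
# ---------------------------------------------------------------------------

class TestFitGeneModels:
    def test_recovers_known_cn_slope(self, rng):
        cohort = simulate_cohort(
            SimulationConfig(
                n_patients=20, n_genes=140, regions_per_patient=(2, 3),
                polyclonal_fraction=0.0, dosage_slope=1.0,
                driver_trans_effect=0.0, immunosuppressive_shift=0.0,
                drift_sd=0.01, noise_sd=0.03, purity_range=(1.0, 1.0),
                arm_loss_prob=0.5, arm_gain_prob=0.0, driver_mut_prob=0.1,
                candidate_loss_arms=("14q", "3p", "5q", "1p"),
                wgd_prob=0.0, seed=3,
            )
        )
        pairs, genes = build_pair_diffs(
            cohort.expression, cohort.cn, cohort.gene_arms, cohort.metadata, seed=1
        )
        results = fit_gene_models(pairs, genes, {g: i for i, g in enumerate(genes)})
        coefs = np.array(
            [r.coefficients["d_cn"] for r in results if "d_cn" in r.coefficients]
        )
        assert coefs.size >= 50
        assert abs(np.median(coefs) - 1.0) < 0.05
        assert np.mean(np.abs(coefs - 1.0) <= 0.1) >= 0.9

    def test_constant_covariate_dropped(self, caplog):
        cohort = simulate_cohort(
            SimulationConfig(
                n_patients=6, n_genes=40, purity_range=(1.0, 1.0), seed=2
            )
        )
        pairs, genes = build_pair_diffs(
            cohort.expression, cohort.cn, cohort.gene_arms, cohort.metadata
        )
        results = fit_gene_models(pairs, genes[:3], {g: i for i, g in enumerate(genes)})
        assert all("d_purity" not in r.coefficients for r in results)

    def test_fdr_no_smaller_than_p(self):
        cohort = simulate_cohort(
            SimulationConfig(n_patients=8, n_genes=30, seed=6)
        )
        pairs, genes = build_pair_diffs(
            cohort.expression, cohort.cn, cohort.gene_arms, cohort.metadata
        )
        results = fit_gene_models(pairs, genes, {g: i for i, g in enumerate(genes)})
        for r in results:
            for cov, q in r.fdr.items():
                assert q >= r.pvalues[cov] - 1e-12

    def test_requires_two_patients(self):
        with pytest.raises(ArgumentError):
            fit_gene_models([], ["g0"], {"g0": 0})


# ---------------------------------------------------------------------------
# decompose_ited_variance
# ---------------------------------------------------------------------------

class TestVarianceDecomposition:
    def test_single_signal_covariate_dominates(self, rng):
        n = 60
        x = rng.normal(size=n)
        covs = pd.DataFrame(
            {
                "signal": x,
                "noise1": rng.normal(size=n),
                "noise2": rng.normal(size=n),
            }
        )
        y = 2.0 * x + rng.normal(0, 0.05, size=n)
        result = decompose_ited_variance(y, covs, order=list(covs.columns))
        assert result.variance_fraction["signal"] >= 0.9
        assert result.variance_fraction["noise1"] < 0.05
        assert result.fdr["signal"] < 0.05

    def test_orthogonal_design_equals_marginal_r2(self, rng):
        # with exactly orthogonal centered covariates, sequential shares
        # equal the marginal R^2 of per-covariate regressions
        n = 32
        # orthogonalize against the intercept too, so sequential = marginal
        q, _ = np.linalg.qr(
            np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        )
        covs = pd.DataFrame(q[:, 1:4], columns=["a", "b", "c"])
        y = rng.normal(size=n)
        result = decompose_ited_variance(y, covs, order=["a", "b", "c"])
        sst = np.sum((y - y.mean()) ** 2)
        for name in ["a", "b", "c"]:
            x = covs[name].to_numpy()
            slope, intercept = np.polyfit(x, y, 1)
            resid = y - slope * x - intercept
            marginal = 1 - np.sum(resid**2) / sst
            assert result.variance_fraction[name] == pytest.approx(marginal, abs=1e-9)

    def test_fractions_sum_to_total_r2(self, rng):
        n = 40
        covs = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        y = covs["a"] * 0.5 + covs["c"] * 1.5 + rng.normal(size=n)
        result = decompose_ited_variance(y, covs, order=list("abcd"))
        assert sum(result.variance_fraction.values()) == pytest.approx(
            result.total_explained, abs=1e-9
        )
        assert result.total_explained <= 1.0

    def test_affine_rescaling_invariance(self, rng):
        n = 40
        covs = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        y = covs["b"].to_numpy() + rng.normal(size=n)
        base = decompose_ited_variance(y, covs, order=list("abc"))
        scaled = covs.copy()
        scaled["b"] = 100.0 * scaled["b"] - 3.0
        alt = decompose_ited_variance(y, scaled, order=list("abc"))
        for name in "abc":
            assert alt.variance_fraction[name] == pytest.approx(
                base.variance_fraction[name], abs=1e-9
            )

    def test_sign_recovery_from_truth(self, rng):
        n = 80
        genetic = rng.normal(size=n)
        cnh = rng.normal(size=n)
        covs = pd.DataFrame(
            {
                "genetic_ith": genetic,
                "cn_heterogeneity": cnh,
                "noise": rng.normal(size=n),
            }
        )
        y = 0.8 * genetic + 0.5 * cnh + rng.normal(0, 0.3, size=n)
        result = decompose_ited_variance(y, covs, order=list(covs.columns))
        assert result.fdr["genetic_ith"] < 0.05
        assert result.fdr["cn_heterogeneity"] < 0.05
        assert result.pvalues["noise"] > 0.05

    def test_refuses_underdetermined(self, rng):
        covs = pd.DataFrame(rng.normal(size=(4, 4)), columns=list("abcd"))
        with pytest.raises(ArgumentError):
            decompose_ited_variance(rng.normal(size=4), covs, order=list("abcd"))

    def test_driver_swap_refits(self, rng):
        n = 50
        base = pd.DataFrame(rng.normal(size=(n, 2)), columns=["purity_ith", "stage"])
        drivers = pd.DataFrame(
            (rng.random(size=(n, 3)) < 0.3).astype(float),
            columns=["9p_loss", "14q_loss", "3p_loss"],
        )
        y = drivers["9p_loss"].to_numpy() * 0.8 + rng.normal(0, 0.4, size=n)
        swaps = driver_swap_decompositions(y, base, drivers)
        assert set(swaps) == {"9p_loss", "14q_loss", "3p_loss"}
        assert (
            swaps["9p_loss"].variance_fraction["9p_loss"]
            > swaps["3p_loss"].variance_fraction["3p_loss"]
        )


# ---------------------------------------------------------------------------
# lme_association
# ---------------------------------------------------------------------------

class TestLmeAssociation:
    def test_degenerate_constant_response(self):
        result = lme_association(
            [1.0] * 9, [0, 1, 2] * 3, ["a", "a", "a", "b", "b", "b", "c", "c", "c"]
        )
        assert result.coefficient == 0.0
        assert result.pvalue == pytest.approx(1.0)

    def test_single_group_reduces_to_ols(self, rng):
        x = rng.normal(size=30)
        y = 0.7 * x + rng.normal(0, 0.5, size=30)
        result = lme_association(y, x, ["only"] * 30)
        slope, intercept, r, p, se = scipy.stats.linregress(x, y)
        assert result.method == "ols"
        assert result.coefficient == pytest.approx(slope)
        assert result.pvalue == pytest.approx(p)

    def test_positive_slope_detected_in_drift_cohorts(self):
        from ithkit.distances import top_variable_genes, transcriptional_distance
        from ithkit.phylo import sample_clonal_distances

        detected = 0
        n_rep = 10
        for seed in range(n_rep):
            cohort = simulate_cohort(
                SimulationConfig(
                    n_patients=10, n_genes=100, regions_per_patient=(3, 4),
                    clones_per_patient=(4, 6), drift_sd=0.5, noise_sd=0.05,
                    seed=seed + 100,
                )
            )
            genes = top_variable_genes(cohort.expression, 60)
            gi = cohort.expression.gene_index(genes)
            records = sample_clonal_distances(cohort.metadata, cohort.trees)
            y = [
                transcriptional_distance(
                    cohort.expression.sample_vector(r.sample_a),
                    cohort.expression.sample_vector(r.sample_b),
                    gi,
                )
                for r in records
            ]
            x = [float(r.distance) for r in records]
            groups = [r.patient_id for r in records]
            result = lme_association(y, x, groups)
            if result.coefficient > 0 and result.pvalue < 0.05:
                detected += 1
        assert detected >= 9

    def test_constant_predictor_rejected(self):
        with pytest.raises(ArgumentError):
            lme_association([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], list("aabb"))


# ---------------------------------------------------------------------------
# paired driver-pathway association
# ---------------------------------------------------------------------------

def _driver_metadata(n_patients, n_wt=2, n_mut=2, driver="SETD2"):
    meta = []
    for p in range(n_patients):
        for i in range(n_wt):
            meta.append(
                SampleMeta(f"p{p}_wt{i}", f"p{p}", "primary",
                           driver_status={driver: False})
            )
        for i in range(n_mut):
            meta.append(
                SampleMeta(f"p{p}_mut{i}", f"p{p}", "primary",
                           driver_status={driver: True})
            )
    return meta


class TestPairedDriverAssociation:
    def test_identical_scores_flagged_p_one(self):
        meta = _driver_metadata(5)
        scores = pd.DataFrame(
            {"hallmark": np.ones(len(meta))}, index=[m.sample_id for m in meta]
        )
        table = paired_driver_association(scores, "SETD2", meta)
        assert table["all_zero"].iloc[0]
        assert table["pvalue"].iloc[0] == 1.0

    def test_shifted_pathway_detected(self, rng):
        meta = _driver_metadata(20)
        idx = [m.sample_id for m in meta]
        mutant = np.array([m.driver_status["SETD2"] for m in meta], dtype=float)
        scores = pd.DataFrame(
            {
                "shifted": 0.5 * mutant + rng.normal(0, 0.1, len(meta)),
                "flat1": rng.normal(0, 0.1, len(meta)),
                "flat2": rng.normal(0, 0.1, len(meta)),
            },
            index=idx,
        )
        table = paired_driver_association(scores, "SETD2", meta).set_index("pathway")
        assert table.loc["shifted", "fdr"] < 0.05
        assert table.loc["flat1", "fdr"] > 0.05
        assert table.loc["flat2", "fdr"] > 0.05

    def test_group_means_before_pairing(self):
        meta = _driver_metadata(2, n_wt=3, n_mut=2)
        idx = [m.sample_id for m in meta]
        values = {
            "p0_wt0": 1.0, "p0_wt1": 2.0, "p0_wt2": 3.0,
            "p0_mut0": 5.0, "p0_mut1": 7.0,
            "p1_wt0": 0.0, "p1_wt1": 0.0, "p1_wt2": 0.0,
            "p1_mut0": 4.0, "p1_mut1": 4.0,
        }
        scores = pd.DataFrame({"pw": [values[s] for s in idx]}, index=idx)
        table = paired_driver_association(scores, "SETD2", meta)
        # per-patient means: wt (2, 0), mut (6, 4) -> overall means 1 and 5
        assert table["wt_mean"].iloc[0] == pytest.approx(1.0)
        assert table["mut_mean"].iloc[0] == pytest.approx(5.0)

    def test_too_few_patients_empty(self):
        meta = _driver_metadata(1)
        scores = pd.DataFrame(
            {"pw": np.arange(4.0)}, index=[m.sample_id for m in meta]
        )
        table = paired_driver_association(scores, "SETD2", meta)
        assert table.empty


# ---------------------------------------------------------------------------
# locus eQTL
# ---------------------------------------------------------------------------

class TestLocusEqtl:
    def _tables(self, detected_fraction, n_samples=20, rng=None):
        rng = rng or np.random.default_rng(0)
        n_on = int(round(detected_fraction * n_samples))
        expr_row = np.concatenate(
            [rng.uniform(1, 2, n_on), np.zeros(n_samples - n_on)]
        )
        samples = [f"s{i}" for i in range(n_samples)]
        expr = ExpressionMatrix(expr_row[None, :], ["h1"], samples)
        cn = ExpressionMatrix(
            rng.integers(1, 4, n_samples)[None, :].astype(float), ["h1"], samples
        )
        purity = {s: 0.7 for s in samples}
        status = {s: bool(i % 2) for i, s in enumerate(samples)}
        groups = {s: f"p{i // 2}" for i, s in enumerate(samples)}
        return expr, cn, purity, status, groups

    def test_prevalence_filter_strict(self):
        expr, cn, purity, status, groups = self._tables(0.69, 100)
        table = locus_eqtl(expr, cn, purity, status, groups)
        assert table.empty
        expr, cn, purity, status, groups = self._tables(0.70, 100)
        table = locus_eqtl(expr, cn, purity, status, groups)
        assert list(table["feature"]) == ["h1"]

    def test_recovers_cn_slope(self, rng):
        n = 60
        samples = [f"s{i}" for i in range(n)]
        cn_values = rng.integers(1, 4, n).astype(float)
        groups = {s: f"p{i // 3}" for i, s in enumerate(samples)}
        expr_values = 0.8 * cn_values + rng.normal(0, 0.1, n) + 1.0
        expr = ExpressionMatrix(expr_values[None, :], ["h1"], samples)
        cn = ExpressionMatrix(cn_values[None, :], ["h1"], samples)
        purity = {s: float(rng.uniform(0.5, 0.9)) for s in samples}
        status = {s: bool(rng.integers(0, 2)) for s in samples}
        table = locus_eqtl(expr, cn, purity, status, groups)
        assert table["cn_coef"].iloc[0] == pytest.approx(0.8, abs=0.1)
        assert table["fdr"].iloc[0] < 0.05

    def test_constant_feature_degenerate(self):
        n = 20
        samples = [f"s{i}" for i in range(n)]
        expr = ExpressionMatrix(np.full((1, n), 2.0), ["h1"], samples)
        cn = ExpressionMatrix(
            np.arange(1, n + 1, dtype=float)[None, :], ["h1"], samples
        )
        purity = {s: 0.5 for s in samples}
        status = {s: False for s in samples}
        groups = {s: f"p{i // 2}" for i, s in enumerate(samples)}
        table = locus_eqtl(expr, cn, purity, status, groups)
        assert table["cn_coef"].iloc[0] == 0.0
        assert table["pvalue"].iloc[0] == pytest.approx(1.0)


class TestBhFdr:
    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0)

    def test_nan_passthrough(self):
        q = bh_fdr([0.01, np.nan, 0.5])
        assert np.isnan(q[1])
        assert np.isfinite(q[0])
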