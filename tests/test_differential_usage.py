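import numpy as np
import pandas as pd
import pytest

from isopipe.differential_usage import (
    DUDesign,
    adjust_and_summarize,
    build_contrast_counts,
    design_from_table,
    estimate_dispersion,
    genes_by_threshold,
    nb_glm_fit,
    nb_loglik,
    pooled_dispersion,
    run_differential_usage,
    shrinkage_prior,
)
from isopipe.differential_usage import test_feature as du_test_feature
from isopipe.simulate import CountSimConfig, simulate_counts


def make_design(n=3, sf=None):
    samples = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
    condition = ["a"] * n + ["b"] * n
    if sf is None:
        sf = pd.Series(1.0, index=samples)
    return DUDesign(samples, condition, sf)


class TestDesign:
    def test_requires_two_levels(self):
        with pytest.raises(ValueError):
            DUDesign(["s1", "s2"], ["a", "a"], pd.Series(1.0, index=["s1", "s2"]))

    def test_requires_replicates(self):
        with pytest.raises(ValueError):
            DUDesign(
                ["s1", "s2", "s3"], ["a", "a", "b"],
                pd.Series(1.0, index=["s1", "s2", "s3"]),
            )

    def test_indicator_marks_later_level(self):
        d = make_design(2)
        assert list(d.indicator) == [0.0, 0.0, 1.0, 1.0]


class TestNBLoglik:
    def test_matches_scipy(self):
        from scipy.stats import nbinom

        rng = np.random.default_rng(3)
        y = rng.poisson(20, size=12).astype(float)
        mu = rng.uniform(5, 40, size=12)
        alpha = 0.07
        n = 1.0 / alpha
        p = n / (n + mu)
        assert np.isclose(nb_loglik(y, mu, alpha), nbinom.logpmf(y, n, p).sum())


class TestNBGLMFit:
    def test_matches_statsmodels_oracle(self):
        # statsmodels is used here ONLY as an independent oracle
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        n = 40
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
        offset = np.log(rng.uniform(0.5, 2.0, n))
        beta_true = np.array([3.0, 0.8])
        alpha = 0.05
        mu = np.exp(X @ beta_true + offset)
        k = 1.0 / alpha
        y = rng.negative_binomial(k, k / (k + mu)).astype(float)

        beta, mu_hat, llf, converged = nb_glm_fit(y, X, offset, alpha)
        sm_fit = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
        ).fit()
        assert converged
        assert np.allclose(beta, sm_fit.params, atol=1e-6)
        assert np.isclose(llf, sm_fit.llf, atol=1e-6)

    def test_converges_on_small_contrast(self):
        design = make_design(3)
        y = np.array([30, 28, 35, 60, 55, 70, 270, 280, 260, 240, 250, 230], float)
        from isopipe.differential_usage import _design_matrices

        X_full, _, offset = _design_matrices(design)
        _, _, llf, converged = nb_glm_fit(y, X_full, offset, 0.05)
        assert converged and np.isfinite(llf)


class TestDispersion:
    def test_recovers_truth_at_large_n(self):
        rng = np.random.default_rng(21)
        n = 2000
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
        offset = np.zeros(n)
        alpha_true = 0.1
        mu = np.exp(X @ np.array([4.0, 0.5]))
        k = 1.0 / alpha_true
        y = rng.negative_binomial(k, k / (k + mu)).astype(float)
        est = estimate_dispersion(y, X, offset)
        assert 0.08 < est < 0.12

    def test_pooled_near_truth(self):
        rng = np.random.default_rng(22)
        design = make_design(3)
        from isopipe.differential_usage import _design_matrices

        X_full, _, offset = _design_matrices(design)
        alpha_true = 0.05
        k = 1.0 / alpha_true
        counts = []
        for _ in range(150):
            mu = np.exp(np.array([3.4] * 6 + [5.6] * 6))
            counts.append(rng.negative_binomial(k, k / (k + mu)).astype(float))
        est = pooled_dispersion(counts, X_full, offset)
        assert 0.04 < est < 0.06

    def test_map_shrinks_toward_prior(self):
        rng = np.random.default_rng(23)
        design = make_design(3)
        from isopipe.differential_usage import _design_matrices

        X_full, _, offset = _design_matrices(design)
        mu = np.exp(np.array([3.4] * 6 + [5.6] * 6))
        k = 1.0 / 0.05
        y = rng.negative_binomial(k, k / (k + mu)).astype(float)
        raw = estimate_dispersion(y, X_full, offset)
        centre = 0.05
        shrunk = estimate_dispersion(
            y, X_full, offset, prior=(np.log(centre), 0.0625)
        )
        # MAP lies between the raw estimate and the prior centre
        lo, hi = sorted((raw, centre))
        assert lo - 1e-6 <= shrunk <= hi + 1e-6

    def test_prior_variance_floor(self):
        raw = np.full(50, 0.05)
        log_centre, var = shrinkage_prior(raw, n_obs=12, n_params=4, centre=0.05)
        assert np.isclose(log_centre, np.log(0.05))
        assert var >= 0.0625

    def test_prior_fallback_when_all_floored(self):
        raw = np.full(10, 1e-8)
        log_centre, var = shrinkage_prior(raw, n_obs=12, n_params=4)
        assert var == 1.0


class TestContrast:
    def test_rest_floored_at_zero(self):
        contrast = build_contrast_counts(np.array([10, 5]), np.array([8, 20]))
        assert contrast[1].tolist() == [0.0, 15.0]
        assert contrast[0].tolist() == [10.0, 5.0]


class TestFeatureTest:
    def test_detects_strong_shift(self):
        rng = np.random.default_rng(31)
        design = make_design(3)
        k = 1.0 / 0.05
        feat = np.concatenate([
            rng.negative_binomial(k, k / (k + 30.0), 3),
            rng.negative_binomial(k, k / (k + 120.0), 3),
        ])
        rest = rng.negative_binomial(k, k / (k + 270.0), 6)
        res = du_test_feature(np.vstack([feat, rest]).astype(float), design, 0.05)
        assert res.p < 0.01
        assert res.log2fc > 1.0

    def test_label_swap_flips_log2fc_sign(self):
        rng = np.random.default_rng(32)
        k = 1.0 / 0.05
        feat = np.concatenate([
            rng.negative_binomial(k, k / (k + 30.0), 3),
            rng.negative_binomial(k, k / (k + 120.0), 3),
        ]).astype(float)
        rest = rng.negative_binomial(k, k / (k + 270.0), 6).astype(float)
        contrast = np.vstack([feat, rest])
        samples = [f"s{i}" for i in range(6)]
        sf = pd.Series(1.0, index=samples)
        fwd = du_test_feature(contrast, DUDesign(samples, ["a"] * 3 + ["b"] * 3, sf), 0.05)
        rev_contrast = contrast[:, [3, 4, 5, 0, 1, 2]]
        rev = du_test_feature(
            rev_contrast, DUDesign(samples, ["a"] * 3 + ["b"] * 3, sf), 0.05
        )
        assert np.isclose(fwd.log2fc, -rev.log2fc, atol=1e-8)
        assert np.isclose(fwd.p, rev.p, atol=1e-8)


class TestPipeline:
    def test_spike_detected_and_nulls_quiet(self):
        config = CountSimConfig(
            seed=41,
            usage_shift={"null000:F00": 8.0},
            n_null_genes=40,
        )
        matrix, truth = simulate_counts(None, config)
        design = design_from_table(
            pd.DataFrame(
                {
                    "sample_id": matrix.samples,
                    "condition": [s.rstrip("0123456789") for s in matrix.samples],
                }
            ),
            matrix,
        )
        table = run_differential_usage(matrix, design)
        feature_table, gene_table = adjust_and_summarize(table)
        spiked = feature_table.set_index("label").loc["null000:F00"]
        assert spiked["padj"] < 0.05
        assert spiked["log2fc"] > 2.0
        # no more than a couple of the 39 true nulls cross the threshold
        nulls = feature_table[feature_table["label"] != "null000:F00"]
        assert (nulls["padj"] < 0.05).sum() <= 2

        summary = genes_by_threshold(table, thresholds=(0.05,))
        assert summary.loc[0, "genes_with_sig_feature"] >= 1

    def test_low_count_features_filtered(self):
        config = CountSimConfig(seed=42, n_null_genes=5, baseline_usage=0.001)
        matrix, _ = simulate_counts(None, config)
        design = design_from_table(
            pd.DataFrame(
                {
                    "sample_id": matrix.samples,
                    "condition": [s.rstrip("0123456789") for s in matrix.samples],
                }
            ),
            matrix,
        )
        table = run_differential_usage(matrix, design, min_mean_count=6.0)
        assert table.empty

    def test_gene_table_shape(self):
        config = CountSimConfig(seed=43, n_null_genes=10)
        matrix, _ = simulate_counts(None, config)
        design = design_from_table(
            pd.DataFrame(
                {
                    "sample_id": matrix.samples,
                    "condition": [s.rstrip("0123456789") for s in matrix.samples],
                }
            ),
            matrix,
        )
        table = run_differential_usage(matrix, design)
        _, gene_table = adjust_and_summarize(table)
        assert len(gene_table) == 10
        assert set(gene_table.columns) == {
            "gene_id", "n_features", "gene_p", "gene_padj",
            "sig_exonic", "sig_known_junction", "sig_novel_junction",
        }
        assert ((gene_table["gene_p"] >= 0) & (gene_table["gene_p"] <= 1)).all()
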