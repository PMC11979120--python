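"""DE engine: CPM, filter, TMM, MDS, precision weights, fits, moderation,
multiple-testing adjustment and DEG calling, each against an independent
oracle where one exists."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tregsig import de
from tregsig.io import TregsigError

from conftest import (
    holm_oracle,
    make_count_matrix,
    moment_prior_oracle,
    random_nb_counts,
    tmm_oracle,
)


def _series(vals):
    return pd.Series(vals, index=[f"s{i}" for i in range(len(vals))])


class TestComputeCpm:
    def test_simple_scaling(self):
        counts = pd.DataFrame({"s0": [10]}, index=["g"])
        cpm = de.compute_cpm(counts, _series([1_000_000]))
        assert cpm.loc["g", "s0"] == 10.0

    def test_prior_keeps_zero_gene_finite(self):
        counts = pd.DataFrame({"s0": [0]}, index=["g"])
        logcpm = de.compute_cpm(counts, _series([1_000_000]), prior_count=0.5, log=True)
        val = logcpm.loc["g", "s0"]
        assert np.isfinite(val)
        assert val < 0  # well below 1 CPM

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 100, size=(20, 3)),
                              columns=["s0", "s1", "s2"])
        lib = _series([1000, 2000, 1500])
        a = de.compute_cpm(counts, lib)
        b = de.compute_cpm(counts * 2, lib * 2)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_effective_library_errors(self):
        counts = pd.DataFrame({"s0": [1]}, index=["g"])
        with pytest.raises(TregsigError, match="library size"):
            de.compute_cpm(counts, _series([0]))


class TestFilterLowExpression:
    @staticmethod
    def _cm_with_low_libraries(n_low):
        # library size 1e6 so CPM == count; gene 'glow' below 1 CPM in n_low
        # of 6 libraries, filler gene keeps library sizes at 1e6
        low = [0] * n_low + [10] * (6 - n_low)
        filler = [1_000_000 - c for c in low]
        return make_count_matrix(np.array([low, filler]), gene_ids=["glow", "filler"])

    def test_gene_above_cutoff_everywhere_is_kept(self):
        cm = de.filter_low_expression(self._cm_with_low_libraries(0))
        assert "glow" in cm.gene_ids

    def test_low_in_three_of_six_is_removed(self):
        cm = de.filter_low_expression(self._cm_with_low_libraries(3))
        assert "glow" not in cm.gene_ids

    def test_low_in_exactly_two_is_kept(self):
        cm = de.filter_low_expression(self._cm_with_low_libraries(2))
        assert "glow" in cm.gene_ids

    def test_whitelisted_gene_survives(self):
        cm = de.filter_low_expression(self._cm_with_low_libraries(6), keep_genes=["glow"])
        assert "glow" in cm.gene_ids


class TestTmm:
    def test_identical_libraries_give_unit_factors(self):
        counts = np.tile(np.arange(1, 51)[:, None], (1, 2))
        nf = de.tmm_factors(make_count_matrix(counts))
        np.testing.assert_allclose(nf.factors.to_numpy(), [1.0, 1.0])

    def test_doubled_library_gives_unit_factors(self):
        base = np.arange(1, 51)
        counts = np.stack([base, 2 * base], axis=1)
        nf = de.tmm_factors(make_count_matrix(counts))
        np.testing.assert_allclose(nf.factors.to_numpy(), [1.0, 1.0], atol=1e-12)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            counts = random_nb_counts(rng, 100, 6)
            nf = de.tmm_factors(make_count_matrix(counts))
            np.testing.assert_allclose(
                nf.factors.to_numpy(), tmm_oracle(counts), atol=1e-6
            )

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_edger_reference(self, tmp_path):
        """Cross-check against the canonical TMM implementation (edgeR)."""
        rng = np.random.default_rng(42)
        counts = random_nb_counts(rng, 150, 6)
        nf = de.tmm_factors(make_count_matrix(counts))
        path = tmp_path / "counts.tsv"
        np.savetxt(path, counts, fmt="%d", delimiter="\t")
        script = (
            "suppressMessages(library(edgeR));"
            f'x <- as.matrix(read.table("{path}"));'
            'cat(sprintf("%.12f ", calcNormFactors(x, method="TMM")))'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        edger = np.array([float(v) for v in out.stdout.split()])
        np.testing.assert_allclose(nf.factors.to_numpy(), edger, atol=1e-6)


class TestMds:
    def test_identical_columns_have_zero_distance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(600, 1))
        mat = pd.DataFrame(np.hstack([x, x, x + 1.0]), columns=["a", "b", "c"])
        coords = de.mds_embedding(mat, dims=1)
        assert abs(coords.loc["a", "dim1"] - coords.loc["b", "dim1"]) < 1e-8

    def test_collinear_samples_embed_exactly_in_1d(self):
        """Three samples at log-expression offsets 0, c, 2c have pairwise
        distances (c, c, 2c); classical scaling on a line reproduces them."""
        c = 0.7
        base = np.zeros((600, 1))
        mat = pd.DataFrame(
            np.hstack([base, base + c, base + 2 * c]), columns=["a", "b", "c"]
        )
        coords = de.mds_embedding(mat, dims=1)["dim1"]
        d = coords.to_numpy()
        assert abs(abs(d[0] - d[1]) - c) < 1e-8
        assert abs(abs(d[1] - d[2]) - c) < 1e-8
        assert abs(abs(d[0] - d[2]) - 2 * c) < 1e-8

    def test_conditions_separate_when_donor_effects_are_modest(self, small_experiment):
        _, cm, _ = small_experiment
        filtered = de.filter_low_expression(cm)
        nf = de.tmm_factors(filtered)
        logcpm = de.compute_cpm(
            filtered.counts, filtered.library_sizes, nf.factors, prior_count=0.5, log=True
        )
        coords = de.mds_embedding(logcpm, dims=2).to_numpy()
        groups = cm.group_labels().to_numpy()
        dists = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        same = groups[:, None] == groups[None, :]
        off = ~np.eye(len(groups), dtype=bool)
        assert dists[same & off].mean() < dists[~same].mean()

    def test_dims_must_be_below_sample_count(self):
        mat = pd.DataFrame(np.zeros((10, 3)), columns=list("abc"))
        with pytest.raises(TregsigError, match="dims"):
            de.mds_embedding(mat, dims=3)


def _two_group_design(n=6):
    samples = make_count_matrix(np.ones((2, n), dtype=int)).samples
    return de.design_matrix(samples)


class TestVoomWeights:
    def test_weights_positive_and_finite(self):
        rng = np.random.default_rng(3)
        cm = make_count_matrix(random_nb_counts(rng, 300, 6))
        wle = de.voom_weights(cm, de.tmm_factors(cm), _two_group_design())
        w = wle.weights.to_numpy()
        assert np.isfinite(w).all() and (w > 0).all()

    def test_homoskedastic_input_gives_near_constant_weights(self):
        # log-normal intensities with mean-independent log-scale noise: the
        # fitted trend is flat, so weights vary little
        rng = np.random.default_rng(4)
        base = rng.uniform(6, 14, size=500)
        logs = base[:, None] + rng.normal(0, 0.3, size=(500, 6))
        cm = make_count_matrix(np.round(2.0**logs).astype(int))
        wle = de.voom_weights(cm, None, _two_group_design())
        w = wle.weights.to_numpy()
        assert w.std() / w.mean() < 0.2

    def test_weight_increases_with_expression_for_nb_counts(self):
        rng = np.random.default_rng(5)
        cm = make_count_matrix(random_nb_counts(rng, 400, 6))
        wle = de.voom_weights(cm, None, _two_group_design())
        mean_count = cm.counts.mean(axis=1)
        mean_weight = wle.weights.mean(axis=1)
        rho = pd.Series(mean_count).corr(pd.Series(mean_weight), method="spearman")
        assert rho > 0

    def test_more_design_columns_than_samples_errors(self):
        cm = make_count_matrix(np.ones((10, 2), dtype=int))
        design = pd.DataFrame(np.eye(2), index=cm.sample_ids, columns=["a", "b"])
        with pytest.raises(TregsigError, match="more samples"):
            de.voom_weights(cm, None, design)


class TestFitContrast:
    @staticmethod
    def _fixture(seed=6, n_genes=100):
        rng = np.random.default_rng(seed)
        cm = make_count_matrix(random_nb_counts(rng, n_genes, 6))
        design = _two_group_design()
        wle = de.voom_weights(cm, None, design)
        return wle, design

    def test_equal_weights_reduce_to_group_mean_difference(self):
        wle, design = self._fixture()
        wle.weights.iloc[:, :] = 1.0
        contrast = de.contrast_vector(design, "thymus.Treg - thymus.Tconv")
        fit = de.fit_contrast(wle, design, contrast)
        y = wle.log2cpm
        treg = y.loc[:, design["thymus.Treg"] == 1].mean(axis=1)
        tconv = y.loc[:, design["thymus.Tconv"] == 1].mean(axis=1)
        np.testing.assert_allclose(fit["log2fc"], treg - tconv, atol=1e-10)

    def test_zero_contrast_gives_zero_estimates(self):
        wle, design = self._fixture()
        fit = de.fit_contrast(wle, design, np.zeros(2))
        assert (fit["log2fc"] == 0).all()

    def test_matches_direct_normal_equations(self):
        wle, design = self._fixture(seed=7)
        contrast = np.array([1.0, -1.0])
        fit = de.fit_contrast(wle, design, contrast)
        x = design.to_numpy()
        for gene in wle.log2cpm.index[:25]:
            w = np.diag(wle.weights.loc[gene].to_numpy())
            y = wle.log2cpm.loc[gene].to_numpy()
            a = x.T @ w @ x
            beta = np.linalg.solve(a, x.T @ w @ y)
            np.testing.assert_allclose(fit.loc[gene, "log2fc"], contrast @ beta, atol=1e-10)
            np.testing.assert_allclose(
                fit.loc[gene, "u"],
                np.sqrt(contrast @ np.linalg.solve(a, contrast)),
                atol=1e-10,
            )


class TestModeration:
    @staticmethod
    def _fit_frame(seed=8, n=200, df=4.0):
        rng = np.random.default_rng(seed)
        true_var = 0.05 * 8 / rng.chisquare(8, size=n)
        s2 = true_var * rng.chisquare(int(df), size=n) / df
        return pd.DataFrame(
            {
                "log2fc": rng.normal(size=n),
                "u": np.full(n, np.sqrt(2.0 / 3.0)),
                "s2": s2,
                "df": df,
            },
            index=[f"g{i}" for i in range(n)],
        )

    def test_zero_prior_df_recovers_ordinary_t(self):
        fit = self._fit_frame()
        _, res = de.moderate_statistics(fit, prior_df=0.0)
        ordinary = fit["log2fc"] / (np.sqrt(fit["s2"]) * fit["u"])
        np.testing.assert_allclose(res["moderated_t"], ordinary, atol=1e-12)
        assert (res["df_total"] == fit["df"]).all()

    def test_equal_variances_give_infinite_prior_df(self):
        fit = self._fit_frame()
        fit["s2"] = 0.25
        est, res = de.moderate_statistics(fit)
        assert np.isinf(est.prior_df)
        np.testing.assert_allclose(est.posterior_var, 0.25, rtol=1e-12)

    def test_posterior_variance_interpolates(self):
        fit = self._fit_frame(seed=9)
        est, _ = de.moderate_statistics(fit)
        lo = np.minimum(fit["s2"], est.prior_var)
        hi = np.maximum(fit["s2"], est.prior_var)
        assert ((est.posterior_var >= lo - 1e-12) & (est.posterior_var <= hi + 1e-12)).all()

    def test_matches_moment_oracle(self):
        fit = self._fit_frame(seed=10)
        est, _ = de.moderate_statistics(fit)
        d0, s02 = moment_prior_oracle(fit["s2"].to_numpy(), 4.0)
        np.testing.assert_allclose(est.prior_df, d0, rtol=1e-6)
        np.testing.assert_allclose(est.prior_var, s02, rtol=1e-6)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_limma_reference(self, tmp_path):
        fit = self._fit_frame(seed=12)
        est, _ = de.moderate_statistics(fit)
        path = tmp_path / "s2.txt"
        np.savetxt(path, fit["s2"].to_numpy())
        script = (
            "suppressMessages(library(limma));"
            f's2 <- scan("{path}", quiet=TRUE);'
            "f <- fitFDist(s2, df1=4);"
            'cat(sprintf("%.12f %.12f", f$scale, f$df2))'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        scale, df2 = map(float, out.stdout.split())
        np.testing.assert_allclose(est.prior_var, scale, rtol=1e-6)
        np.testing.assert_allclose(est.prior_df, df2, rtol=1e-6)


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(de.adjust_pvalues([0.02], "holm"), [0.02])

    def test_symmetric_triple(self):
        np.testing.assert_allclose(
            de.adjust_pvalues([0.01, 0.01, 0.01], "holm"), [0.03, 0.03, 0.03]
        )

    def test_worked_stepdown_example(self):
        np.testing.assert_allclose(
            de.adjust_pvalues([0.01, 0.04, 0.03], "holm"), [0.03, 0.06, 0.06]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.adjust_pvalues([0.5, 1.2], "holm")

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=15),
        st.integers(min_value=0, max_value=14),
        st.floats(min_value=1.0, max_value=5.0),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_holm_is_monotone_in_each_input(self, pvals, idx, factor):
        """Raising any single raw p never lowers any adjusted p."""
        idx = idx % len(pvals)
        before = de.adjust_pvalues(pvals, "holm")
        bumped = list(pvals)
        bumped[idx] = min(1.0, bumped[idx] * factor + 1e-6)
        after = de.adjust_pvalues(bumped, "holm")
        assert (after >= before - 1e-12).all()

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=12),
           st.randoms(use_true_random=False))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_permutation_equivariance(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        for method in ("holm", "bh"):
            direct = de.adjust_pvalues([pvals[i] for i in perm], method)
            reordered = de.adjust_pvalues(pvals, method)[perm]
            np.testing.assert_allclose(direct, reordered, atol=1e-12)

    def test_matches_bruteforce_holm_on_random_vectors(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 21))
            np.testing.assert_allclose(de.adjust_pvalues(p, "holm"), holm_oracle(p))


class TestCallDegs:
    @pytest.mark.parametrize(
        "log2fc,p_adj,expected",
        [
            (5.93, 1e-10, "up"),  # strong canonical up-regulation call
            (0.9, 1e-5, "stable"),  # below the fold threshold
            (-1.2, 0.2, "stable"),  # fails alpha
            (-1.2, 0.01, "down"),
            (1.0, 0.049, "up"),  # boundary: threshold is inclusive on lfc
        ],
    )
    def test_status_rule(self, log2fc, p_adj, expected):
        frame = pd.DataFrame({"log2fc": [log2fc], "p_adj": [p_adj]}, index=["g"])
        assert de.call_degs(frame)["status"].iloc[0] == expected
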