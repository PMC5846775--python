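"""Moderated linear model, empirical-Bayes shrinkage, BH, pattern classes."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from proteopanel import diffexpr
from proteopanel.containers import ValidationError
from proteopanel.datasets import load_protease_table


def _values(arrays, groups):
    """Build a (proteins x samples) frame plus group labels."""
    mat = np.atleast_2d(np.asarray(arrays, dtype=float))
    sids = [f"S{i}" for i in range(mat.shape[1])]
    df = pd.DataFrame(mat, index=[f"P{i}" for i in range(mat.shape[0])], columns=sids)
    return df, pd.Series(groups, index=sids)


class TestFitGroupModel:
    def test_noiseless_groups(self):
        df, groups = _values(
            [[1, 1, 2, 2, 3, 3]], ["HC", "HC", "IBS", "IBS", "UC", "UC"]
        )
        fit = diffexpr.fit_group_model(df, groups)
        np.testing.assert_allclose(fit.means.loc["P0"], [1, 2, 3])
        assert fit.s2.loc["P0"] == 0.0
        assert fit.df_residual == 3

    def test_constant_offset_equivariance(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(5, 9))
        groups = ["HC"] * 3 + ["IBS"] * 3 + ["UC"] * 3
        df1, g = _values(base, groups)
        df2, _ = _values(base + 7.5, groups)
        f1 = diffexpr.fit_group_model(df1, g)
        f2 = diffexpr.fit_group_model(df2, g)
        np.testing.assert_allclose(f2.means.to_numpy(), f1.means.to_numpy() + 7.5)
        np.testing.assert_allclose(f2.s2, f1.s2)

    def test_pooled_variance_matches_brute_force(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 10))
        groups = ["HC"] * 3 + ["IBS"] * 4 + ["UC"] * 3
        df, g = _values(x, groups)
        fit = diffexpr.fit_group_model(df, g)
        for i in range(20):
            rss = 0.0
            for gname, sl in (("HC", slice(0, 3)), ("IBS", slice(3, 7)), ("UC", slice(7, 10))):
                seg = x[i, sl]
                rss += np.sum((seg - seg.mean()) ** 2)
            assert fit.s2.iloc[i] == pytest.approx(rss / 7, rel=1e-12)

    def test_small_group_rejected(self):
        df, g = _values([[1, 2, 3, 4, 5]], ["HC", "HC", "IBS", "IBS", "UC"])
        with pytest.raises(ValidationError):
            diffexpr.fit_group_model(df, g)


class TestEbayes:
    def test_equal_variances_give_capped_d0(self):
        s2 = pd.Series(np.full(100, 2.5))
        d0, s0_2, s2_mod = diffexpr.ebayes_moderate(s2, df=4)
        assert d0 == 1e6
        assert s0_2 == pytest.approx(2.5, rel=1e-6)
        np.testing.assert_allclose(s2_mod, 2.5, rtol=1e-5)

    def test_d0_zero_means_no_shrinkage(self):
        rng = np.random.default_rng(2)
        s2 = pd.Series(rng.chisquare(4, 50) / 4)
        fit = diffexpr.GroupFit(
            means=pd.DataFrame(np.zeros((50, 3)), columns=["HC", "IBS", "UC"]),
            s2=s2, df_residual=4, group_sizes={"HC": 2, "IBS": 3, "UC": 2},
        )
        mfit = diffexpr.moderate(fit, d0=0)
        pd.testing.assert_series_equal(mfit.s2_moderated, s2)

    def test_hyperparameter_recovery_from_scaled_f_sample(self):
        """5000 variances from the d0=4, s0^2=1 hierarchy: both recovered within 15%."""
        rng = np.random.default_rng(3)
        d0_true, s0_true, d = 4.0, 1.0, 4
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=5000)
        s2 = sigma2 * rng.chisquare(d, size=5000) / d
        d0, s0_2, _ = diffexpr.ebayes_moderate(pd.Series(s2), df=d)
        assert abs(d0 - d0_true) / d0_true < 0.15
        assert abs(s0_2 - s0_true) / s0_true < 0.15

    def test_shrinkage_bracketing(self):
        rng = np.random.default_rng(4)
        s2 = pd.Series(rng.chisquare(3, 200))
        d0, s0_2, s2_mod = diffexpr.ebayes_moderate(s2, df=3)
        lo = np.minimum(s2, s0_2)
        hi = np.maximum(s2, s0_2)
        assert ((s2_mod >= lo - 1e-12) & (s2_mod <= hi + 1e-12)).all()

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValidationError):
            diffexpr.ebayes_moderate(pd.Series(np.zeros(50)), df=3)

    def test_trigamma_inverse_roundtrip(self):
        for y in (0.1, 1.0, 7.3, 150.0):
            x = special.polygamma(1, y)
            assert diffexpr.trigamma_inverse(x) == pytest.approx(y, rel=1e-6)


class TestModeratedTests:
    def _random_fit(self, seed, n_prot=50):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n_prot, 22))
        groups = ["HC"] * 7 + ["IBS"] * 8 + ["UC"] * 7
        df, g = _values(x, groups)
        return df, g, diffexpr.fit_group_model(df, g)

    def test_zero_contrast_gives_t_zero_p_one(self):
        df, g = _values(
            [[1, 1, 1, 1, 5, 6]], ["HC", "HC", "IBS", "IBS", "UC", "UC"]
        )
        fit = diffexpr.fit_group_model(df, g)
        mfit = diffexpr.moderate(fit, d0=0)
        table = diffexpr.moderated_tests(mfit)
        assert table.loc["P0", "log10_ratio_IBS_vs_HC"] == 0.0
        assert table.loc["P0", "p_IBS_vs_HC"] == pytest.approx(1.0)

    def test_classical_anova_equivalence_at_d0_zero(self):
        """With no shrinkage, moderated F p-values equal scipy one-way ANOVA."""
        df, g, fit = self._random_fit(5)
        mfit = diffexpr.moderate(fit, d0=0)
        table = diffexpr.moderated_tests(mfit)
        x = df.to_numpy()
        for i in range(len(df)):
            _, p_ref = stats.f_oneway(x[i, :7], x[i, 7:15], x[i, 15:])
            assert table["p_F"].iloc[i] == pytest.approx(p_ref, abs=1e-10)

    def test_classical_pairwise_equivalence_at_d0_zero(self):
        """Pairwise moderated t at d0=0 equals the pooled-variance contrast t."""
        df, g, fit = self._random_fit(6)
        mfit = diffexpr.moderate(fit, d0=0)
        table = diffexpr.moderated_tests(mfit)
        x = df.to_numpy()
        for i in range(len(df)):
            est = x[i, 7:15].mean() - x[i, :7].mean()
            se = np.sqrt(fit.s2.iloc[i] * (1 / 8 + 1 / 7))
            p_ref = 2 * stats.t.sf(abs(est / se), 19)
            assert table["p_IBS_vs_HC"].iloc[i] == pytest.approx(p_ref, abs=1e-10)

    def test_null_pvalues_uniform(self):
        """Raw p-values of 2000 null proteins pass a KS test at alpha = 0.01."""
        df, g, fit = self._random_fit(7, n_prot=2000)
        mfit = diffexpr.moderate(fit)
        table = diffexpr.moderated_tests(mfit)
        assert stats.kstest(table["p_F"], "uniform").pvalue > 0.01
        frac = (table["p_F"] < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 2000)


class TestLimmaEquivalence:
    """Independent oracle: the Bioconductor moderated-statistics reference."""

    def test_hyperparameters_and_moderated_t_match_reference(self, tmp_path):
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(9)
        x = rng.normal(5, 1, size=(200, 9))
        x[:20, 3:6] += 1.0
        groups = ["HC"] * 3 + ["IBS"] * 3 + ["UC"] * 3
        df, g = _values(x, groups)
        fit = diffexpr.fit_group_model(df, g)
        mfit = diffexpr.moderate(fit)
        table = diffexpr.moderated_tests(mfit)

        mat = tmp_path / "m.tsv"
        df.to_csv(mat, sep="\t")
        rscript = tmp_path / "ref.R"
        rscript.write_text(
            """
suppressMessages(library(limma))
args <- commandArgs(trailingOnly = TRUE)
x <- as.matrix(read.delim(args[1], row.names = 1))
group <- factor(c(rep("HC",3), rep("IBS",3), rep("UC",3)), levels=c("HC","IBS","UC"))
design <- model.matrix(~0 + group)
colnames(design) <- levels(group)
fit <- lmFit(x, design)
cm <- makeContrasts(IBS - HC, levels = design)
fit2 <- eBayes(contrasts.fit(fit, cm))
out <- data.frame(d0 = fit2$df.prior, s02 = fit2$s2.prior,
                  t = fit2$t[,1], p = fit2$p.value[,1])
write.csv(out, args[2], row.names = FALSE)
""")
        out_csv = tmp_path / "ref.csv"
        subprocess.run(
            ["Rscript", str(rscript), str(mat), str(out_csv)],
            check=True, capture_output=True,
        )
        ref = pd.read_csv(out_csv)
        assert mfit.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-5)
        assert mfit.s0_2 == pytest.approx(ref["s02"].iloc[0], rel=1e-5)
        se = np.sqrt(mfit.s2_moderated.to_numpy() * (1 / 3 + 1 / 3))
        t_ours = (fit.means["IBS"] - fit.means["HC"]).to_numpy() / se
        np.testing.assert_allclose(t_ours, ref["t"].to_numpy(), rtol=1e-6)
        np.testing.assert_allclose(
            table["p_IBS_vs_HC"].to_numpy(), ref["p"].to_numpy(), rtol=1e-6
        )


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert diffexpr.bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_step_up_by_hand(self):
        out = diffexpr.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_equal_ps_unchanged(self):
        out = diffexpr.bh_adjust(np.array([0.2, 0.2, 0.2]))
        np.testing.assert_allclose(out, 0.2)

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(8)
        p = np.sort(rng.random(100))
        q = diffexpr.bh_adjust(p)
        assert (q >= p - 1e-15).all()
        assert (np.diff(q) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            diffexpr.bh_adjust(np.array([0.1, 1.5]))


class TestSelectDifferential:
    def test_alpha_one_selects_everything(self):
        table = pd.DataFrame({"adj_p_F": [0.2, 0.9, 0.5]}, index=list("abc"))
        assert set(diffexpr.select_differential(table, alpha=1.0)) == set("abc")

    def test_threshold_is_strict(self):
        table = pd.DataFrame({"adj_p_F": [0.05, 0.049]}, index=list("ab"))
        assert diffexpr.select_differential(table, alpha=0.05) == ["b"]


class TestPatternClassification:
    def test_published_rows_classify_as_annotated(self):
        """Spot checks against the printed protease table annotations."""
        table = load_protease_table()
        assert diffexpr.classify_pattern(table.loc["Q96QL8"]) == "up-IBS-vs-both"
        assert (
            diffexpr.classify_pattern(table.loc["B4DJQ8"])
            == "up-IBS-vs-HC-and-UC-vs-HC"
        )
        assert diffexpr.classify_pattern(table.loc["Q6IBC3"]) == "down-IBS-vs-UC-only"

    def test_partition_counts_of_reference_table(self):
        table = load_protease_table()
        classes = table.apply(diffexpr.classify_pattern, axis=1)
        counts = classes.value_counts()
        assert counts["up-IBS-vs-both"] == 4
        assert counts["up-IBS-vs-HC-and-UC-vs-HC"] == 1
        assert counts["up-IBS-vs-HC-only"] == 3
        assert counts["up-IBS-vs-UC-only"] == 2
        assert counts["down-IBS-vs-HC"] == 4
        assert counts["down-IBS-vs-HC-and-UC"] == 2
        assert counts["down-IBS-vs-UC-only"] == 1
        assert counts.sum() == 17

    def test_no_significance_is_other(self):
        row = pd.Series(
            {
                "log10_ratio_IBS_vs_HC": 0.4, "p_IBS_vs_HC": 0.4,
                "log10_ratio_UC_vs_HC": 0.1, "p_UC_vs_HC": 0.9,
                "log10_ratio_IBS_vs_UC": 0.2, "p_IBS_vs_UC": 0.6,
            }
        )
        assert diffexpr.classify_pattern(row) == "other"
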