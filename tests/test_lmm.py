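"""Mixed model: REML against degenerate OLS, parameter recovery, Type-III
invariances, EMM identities and an independent lmerTest/emmeans oracle."""

import itertools
import subprocess

import numpy as np
import pandas as pd
import pytest

from seednets.lmm import (LmmFormula, anova_type3, build_design,
                          effect_contrasts, emmeans, fit_lmm,
                          pairwise_z_matrix)

FORMULA = LmmFormula("mean_z", ["hemisphere", "fc_map", "region",
                                "fc_map:region"], "participant_id")


def simulate_table(n_part=12, regions=("r1", "r2", "r3", "r4"),
                   maps=("m1", "m2", "m3"), subject_sd=0.5, resid_sd=0.3,
                   seed=0, effects=None):
    rng = np.random.default_rng(seed)
    parts = [f"p{i:02d}" for i in range(n_part)]
    pe = dict(zip(parts, rng.normal(0, subject_sd, n_part)))
    effects = effects or {}
    rows = []
    for p, h, r, m in itertools.product(parts, "LR", regions, maps):
        mu = (0.2 * (h == "R") + effects.get(r, 0.0) + effects.get(m, 0.0)
              + effects.get((r, m), 0.0))
        rows.append(dict(participant_id=p, hemisphere=h, region=r, fc_map=m,
                         mean_z=mu + pe[p] + rng.normal(0, resid_sd)))
    return pd.DataFrame(rows)


class TestDesign:
    def test_sum_coding_columns_sum_to_zero_over_levels(self):
        df = simulate_table(n_part=3)
        X, info = build_design(df, FORMULA.fixed)
        # balanced design: every non-intercept column sums to zero
        assert np.abs(X[:, 1:].sum(axis=0)).max() < 1e-9

    def test_unknown_factor_rejected(self):
        df = simulate_table(n_part=3)
        with pytest.raises(ValueError, match="nope"):
            build_design(df, ["nope"])


class TestFit:
    def test_zero_subject_sd_matches_ols(self):
        df = simulate_table(subject_sd=0.0, seed=1)
        fit = fit_lmm(df, FORMULA)
        X, _ = build_design(df, FORMULA.fixed)
        beta_ols, *_ = np.linalg.lstsq(X, df["mean_z"].to_numpy(), rcond=None)
        assert np.abs(fit.beta - beta_ols).max() < 1e-6

    def test_parameter_recovery_balanced_design(self):
        df = simulate_table(n_part=50, regions=("a", "b"),
                            maps=("x", "y", "z"), subject_sd=1.0,
                            resid_sd=0.5, seed=1,
                            effects={"a": 0.5, "x": 0.3})
        fit = fit_lmm(df, LmmFormula(
            "mean_z", ["hemisphere", "fc_map", "region"], "participant_id"))
        assert fit.tau2 == pytest.approx(1.0, rel=0.35)
        assert fit.sigma2 == pytest.approx(0.25, rel=0.2)
        # hemisphere effect 0.2 -> sum-coded coefficient -0.1 (L level)
        j = fit.info.term_slices["hemisphere"].start
        se = np.sqrt(fit.cov_beta[j, j])
        assert abs(abs(fit.beta[j]) - 0.1) < 3 * se

    def test_duplicating_rows_leaves_estimates(self):
        df = simulate_table(seed=2)
        fit1 = fit_lmm(df, FORMULA)
        fit2 = fit_lmm(pd.concat([df, df], ignore_index=True), FORMULA)
        assert np.abs(fit1.beta - fit2.beta).max() < 1e-6

    def test_singular_design_rejected(self):
        df = simulate_table(seed=3)
        df["dup"] = df["fc_map"]
        with pytest.raises(ValueError, match="singular|levels"):
            fit_lmm(df, LmmFormula("mean_z", ["fc_map", "dup"],
                                   "participant_id"))

    def test_requires_replicated_groups(self):
        df = pd.DataFrame({
            "participant_id": ["p0", "p0", "p1"],
            "hemisphere": ["L", "R", "L"],
            "mean_z": [0.1, 0.2, 0.3],
        })
        with pytest.raises(ValueError, match="2 observations"):
            fit_lmm(df, LmmFormula("mean_z", ["hemisphere"], "participant_id"))


class TestAnova:
    def test_region_relabelling_leaves_interaction_f(self):
        df = simulate_table(seed=4, effects={("r1", "m1"): 0.5})
        f1 = anova_type3(fit_lmm(df, FORMULA))
        relab = {"r1": "zz", "r2": "aa", "r3": "mm", "r4": "bb"}
        df2 = df.assign(region=df["region"].map(relab))
        f2 = anova_type3(fit_lmm(df2, FORMULA))
        a = f1.loc[f1.term == "fc_map:region", "F"].iloc[0]
        b = f2.loc[f2.term == "fc_map:region", "F"].iloc[0]
        assert a == pytest.approx(b, abs=1e-8)

    def test_matches_fixed_effects_anova_when_sd_zero(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = simulate_table(subject_sd=0.0, seed=1,
                            effects={("r2", "m2"): 0.4, "m1": 0.3})
        fit = fit_lmm(df, FORMULA)
        assert fit.boundary  # REML puts the participant variance at zero
        an = anova_type3(fit)
        ols = smf.ols("mean_z ~ C(hemisphere, Sum) + C(fc_map, Sum) "
                      "+ C(region, Sum) + C(fc_map, Sum):C(region, Sum)",
                      data=df).fit()
        an3 = sm.stats.anova_lm(ols, typ=3)
        for term, sm_term in [("hemisphere", "C(hemisphere, Sum)"),
                              ("fc_map", "C(fc_map, Sum)"),
                              ("fc_map:region",
                               "C(fc_map, Sum):C(region, Sum)")]:
            mine = an.loc[an.term == term, "F"].iloc[0]
            theirs = an3.loc[sm_term, "F"]
            assert mine == pytest.approx(theirs, rel=1e-4)
            assert an.loc[an.term == term, "df_den"].iloc[0] == pytest.approx(
                fit.n_obs - fit.n_params)


class TestEmmeans:
    def test_emms_equal_cell_means_in_balanced_design(self):
        df = simulate_table(seed=6)
        fit = fit_lmm(df, FORMULA)
        em = emmeans(fit, ["fc_map", "region"])
        cells = df.groupby(["fc_map", "region"])["mean_z"].mean()
        for _, row in em.iterrows():
            assert row["emmean"] == pytest.approx(
                cells[(row["fc_map"], row["region"])], abs=1e-8)

    def test_effect_contrast_is_level_minus_mean_of_others(self):
        df = simulate_table(seed=7)
        fit = fit_lmm(df, FORMULA)
        em = emmeans(fit, ["fc_map"]).set_index("fc_map")["emmean"]
        con = effect_contrasts(fit, "fc_map")
        for _, row in con.iterrows():
            m = row["fc_map"]
            others = [l for l in em.index if l != m]
            assert row["estimate"] == pytest.approx(
                em[m] - em[others].mean(), abs=1e-10)

    def test_pairwise_matrix_antisymmetric(self):
        df = simulate_table(seed=8)
        fit = fit_lmm(df, FORMULA)
        mats = pairwise_z_matrix(fit, "region", "fc_map")
        for Z in mats.values():
            assert np.abs(Z + Z.T).max() < 1e-10


class TestAgainstLmerTest:
    """Dual-route check: the same table fitted with lmerTest + emmeans."""

    R_CODE = """
suppressMessages({library(lmerTest); library(emmeans)})
df <- read.delim(commandArgs(TRUE)[1])
for (c in c('hemisphere','region','fc_map','participant_id'))
    df[[c]] <- factor(df[[c]])
options(contrasts=c('contr.sum','contr.poly'))
m <- lmer(mean_z ~ hemisphere + fc_map + region + fc_map:region
          + (1|participant_id), data=df)
vc <- as.data.frame(VarCorr(m))
an <- anova(m, type=3)
em <- summary(contrast(emmeans(m, ~fc_map|region), 'eff', adjust='none'))
cat(vc$vcov[1], vc$vcov[2], '\\n')
write.table(data.frame(term=rownames(an), F=an$`F value`,
            dfd=an$DenDF, p=an$`Pr(>F)`), sep='\\t', row.names=FALSE)
write.table(em[, c('contrast','region','t.ratio')], sep='\\t',
            row.names=FALSE)
"""

    def test_matches_reml_anova_and_contrasts(self, tmp_path):
        df = simulate_table(n_part=10, seed=9,
                            effects={("r1", "m1"): 0.4, "m2": -0.2})
        tsv = tmp_path / "table.tsv"
        df.to_csv(tsv, sep="\t", index=False)
        rfile = tmp_path / "oracle.R"
        rfile.write_text(self.R_CODE)
        out = subprocess.run(["Rscript", str(rfile), str(tsv)],
                             capture_output=True, text=True, check=True)
        lines = out.stdout.strip().splitlines()
        tau2_r, sigma2_r = map(float, lines[0].split())

        fit = fit_lmm(df, FORMULA)
        assert fit.tau2 == pytest.approx(tau2_r, rel=1e-4, abs=1e-8)
        assert fit.sigma2 == pytest.approx(sigma2_r, rel=1e-4)

        an = anova_type3(fit).set_index("term")
        header = lines.index('"term"\t"F"\t"dfd"\t"p"')
        for line in lines[header + 1:header + 5]:
            term, F, dfd, p = line.split("\t")
            term = term.strip('"')
            assert an.loc[term, "F"] == pytest.approx(float(F), rel=1e-3)
            assert an.loc[term, "df_den"] == pytest.approx(float(dfd), rel=0.02)

        con = effect_contrasts(fit, "fc_map", by="region")
        chead = lines.index('"contrast"\t"region"\t"t.ratio"')
        for line in lines[chead + 1:]:
            contrast, region, tr = line.split("\t")
            m = contrast.strip('"').split()[0]
            region = region.strip('"')
            mine = con.loc[(con.fc_map == m) & (con.region == region),
                           "z_ratio"].iloc[0]
            assert mine == pytest.approx(float(tr), rel=1e-2)
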