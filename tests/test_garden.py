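"""Variance components: design arithmetic, REML oracles, summaries, PCA."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import refugia as rf

from _oracles import balanced_oneway_anova


class TestExpandDesign:
    def test_full_trial_arithmetic(self):
        design = rf.default_trial_design()
        skeleton, n = rf.expand_design(design)
        assert n == 6450
        assert len(skeleton) == 6450
        skeleton1, n1 = rf.expand_design(design, single_site=True)
        assert n1 == 1290
        assert skeleton1["site"].nunique() == 1

    def test_minimal_design(self):
        design = rf.TrialDesign(("A",), n_sites=1, n_blocks=1, n_trees=1)
        _, n = rf.expand_design(design)
        assert n == 1

    def test_region_labels_propagate(self):
        design = rf.default_trial_design()
        skeleton, _ = rf.expand_design(design)
        assert skeleton["region"].nunique() == 6
        assert set(skeleton.columns) == {
            "region", "provenance", "site", "block", "tree"
        }


def _oneway_table(p=12, n=30, var_prov=2.0, var_resid=1.0, seed=0):
    design = rf.TrialDesign(
        ("A",) * p, n_sites=1, n_blocks=1, n_trees=n,
        traits={"y": rf.TraitSpec({"A": rf.TraitParams(
            mean=10.0, var_prov=var_prov, var_resid=var_resid)},
            single_site=True)},
    )
    return rf.simulate_trial(design, seed=seed)


class TestVarianceModel:
    def test_balanced_oneway_matches_anova_oracle(self):
        table = _oneway_table(seed=1)
        res = rf.fit_variance_model(table, "y")
        groups = [g["value"].to_numpy()
                  for _, g in table.groupby("provenance")]
        sig_p, sig_e = balanced_oneway_anova(groups)
        assert res.params["provenance"] == pytest.approx(sig_p, rel=1e-5)
        assert res.params["residual"] == pytest.approx(sig_e, rel=1e-5)

    def test_constant_response(self):
        table = _oneway_table()
        table["value"] = 3.25
        res = rf.fit_variance_model(table, "y")
        assert res.mu == pytest.approx(3.25)
        assert (res.params == 0).all()

    def test_pure_residual_recovery(self):
        # all non-residual variances zero, large n: estimates concentrate
        table = _oneway_table(p=40, n=40, var_prov=0.0, var_resid=1.0, seed=2)
        res = rf.fit_variance_model(table, "y")
        df = len(table) - 1
        assert abs(res.params["residual"] - 1.0) < 4 * np.sqrt(2 / df) + 0.01
        assert res.params["provenance"] < 0.02

    def test_location_and_scale_equivariance(self):
        design = rf.TrialDesign(
            ("A",) * 10, n_sites=5, n_blocks=4, n_trees=4,
            traits={"y": rf.TraitSpec({"A": rf.TraitParams(
                mean=5.0, var_prov=0.4, var_site=0.6, var_prov_site=0.2,
                var_block=0.3, var_prov_block=0.2, var_resid=1.0)})},
        )
        table = rf.simulate_trial(design, seed=3)
        base = rf.fit_variance_model(table, "y")
        shifted = table.copy()
        shifted["value"] = shifted["value"] + 100.0
        res_shift = rf.fit_variance_model(shifted, "y")
        assert res_shift.mu == pytest.approx(base.mu + 100.0, abs=1e-6)
        pd.testing.assert_series_equal(res_shift.params, base.params,
                                       rtol=1e-4, atol=1e-8)
        scaled = table.copy()
        scaled["value"] = scaled["value"] * 3.0
        res_scale = rf.fit_variance_model(scaled, "y")
        pd.testing.assert_series_equal(res_scale.params, base.params * 9.0,
                                       rtol=2e-3, atol=1e-8)

    def test_single_site_flag_drops_site_terms(self):
        design = rf.default_trial_design()
        table = rf.simulate_trial(design.subset_region("Minnesota"), seed=4)
        res = rf.fit_variance_model(table, "bud_break")
        assert set(res.params.index) == {
            "provenance", "block", "provenance_x_block", "residual"
        }
        res_h = rf.fit_variance_model(table, "height")
        assert "site" in res_h.params.index
        assert "provenance_x_site" in res_h.params.index

    def test_degenerate_no_replication_rejected(self):
        design = rf.TrialDesign(("A",) * 4, n_sites=2, n_blocks=2, n_trees=1)
        skeleton, _ = rf.expand_design(design)
        skeleton["trait"] = "y"
        skeleton["value"] = np.random.default_rng(0).normal(size=len(skeleton))
        with pytest.raises(ValueError, match="replication"):
            rf.fit_variance_model(skeleton, "y")

    def test_matches_lme4_on_unbalanced_data(self, tmp_path):
        """Independent cross-check: R lme4 REML on the same records."""
        design = rf.TrialDesign(
            ("MN",) * 5, n_sites=3, n_blocks=4, n_trees=4,
            traits={"height": rf.TraitSpec({"MN": rf.TraitParams(
                mean=8.0, var_prov=0.2, var_site=0.4, var_prov_site=0.1,
                var_block=0.15, var_prov_block=0.1, var_resid=0.9)})},
        )
        table = rf.simulate_trial(design, seed=11)
        table = table.sample(frac=0.85, random_state=5).reset_index(drop=True)
        res = rf.fit_variance_model(table, "height")
        csv = tmp_path / "vc.csv"
        table.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$P <- factor(d$provenance); d$S <- factor(d$site)
            d$B <- factor(d$block)
            m <- lmer(value ~ 1 + (1|P) + (1|S) + (1|P:S) + (1|S:B) +
                      (1|P:S:B), data=d, REML=TRUE)
            vc <- as.data.frame(VarCorr(m))
            for (i in seq_len(nrow(vc)))
                cat(vc$grp[i], vc$vcov[i], "\\n")
            cat("mu", fixef(m)[1], "\\n")
        """)
        out = subprocess.run(["Rscript", "-"], input=script, timeout=300,
                             capture_output=True, text=True, check=True)
        ref = {}
        for line in out.stdout.strip().splitlines():
            parts = line.split()
            ref[parts[0]] = float(parts[1])
        mapping = {
            "provenance": "P", "site": "S", "provenance_x_site": "P:S",
            "block_in_site": "S:B", "provenance_x_block": "P:S:B",
            "residual": "Residual",
        }
        for mine, theirs in mapping.items():
            assert res.params[mine] == pytest.approx(
                ref[theirs], rel=2e-3, abs=2e-4
            ), mine
        assert res.mu == pytest.approx(ref["mu"], abs=1e-4)

    def test_parameter_recovery_and_interval_coverage(self):
        """Repeated simulation of the single-region five-site trial:
        unbiased residual component, calibrated Wald intervals for the
        well-replicated components."""
        gen = rf.TraitParams(mean=8.0, var_prov=0.15, var_site=0.5,
                             var_prov_site=0.05, var_block=0.10,
                             var_prov_block=0.10, var_resid=0.94)
        design = rf.TrialDesign(
            ("MN",) * 8,
            traits={"height": rf.TraitSpec({"MN": gen})},
        )
        truth = gen.variances(multi_site=True)
        n_rep = 120
        est = {k: [] for k in truth}
        cover = {k: 0 for k in truth}
        defined = {k: 0 for k in truth}
        for seed in range(n_rep):
            table = rf.simulate_trial(design, seed=seed)
            res = rf.fit_variance_model(table, "height")
            for k, true_val in truth.items():
                est[k].append(res.params[k])
                se = res.bse[k]
                if np.isfinite(se):
                    defined[k] += 1
                    if abs(res.params[k] - true_val) <= 1.96 * se:
                        cover[k] += 1
        # residual: high-df, should be tightly unbiased and calibrated
        resid = np.array(est["residual"])
        mc_se = resid.std(ddof=1) / np.sqrt(n_rep)
        assert abs(resid.mean() - 0.94) <= 3 * mc_se
        assert cover["residual"] / defined["residual"] >= 0.90
        # many-level interaction component: near-nominal coverage too
        assert cover["provenance_x_block"] / defined["provenance_x_block"] \
            >= 0.85
        # every component unbiased within Monte-Carlo error
        for k, true_val in truth.items():
            arr = np.array(est[k])
            assert abs(arr.mean() - true_val) <= \
                4 * arr.std(ddof=1) / np.sqrt(n_rep) + 1e-3, k


class TestRegionTraitTable:
    def test_fit_count_and_layout(self):
        table = rf.simulate_trial(rf.default_trial_design(), seed=0)
        summary, fits = rf.region_trait_table(table)
        assert len(fits) == 18
        assert summary.attrs["n_fits"] == 18
        assert len(summary) == 6
        for trait in ("height", "bud_break", "leaf_senescence"):
            assert trait in summary.columns
            assert f"{trait}_se" in summary.columns

    def test_missing_combination_reported_as_gap(self):
        table = rf.simulate_trial(rf.default_trial_design(), seed=0)
        table = table[~((table["region"] == "Minnesota")
                        & (table["trait"] == "bud_break"))]
        summary, _ = rf.region_trait_table(table)
        row = summary[summary["region"] == "Minnesota"].iloc[0]
        assert np.isnan(row["bud_break"])
        assert ("Minnesota", "bud_break") in summary.attrs["missing"]

    def test_residual_gradient_rank_recovery(self):
        resids = {"r1": 1.0, "r2": 2.0, "r3": 4.0, "r4": 8.0,
                  "r5": 16.0, "r6": 32.0}
        regions = tuple(r for r in resids for _ in range(7))
        traits = {"y": rf.TraitSpec(
            {r: rf.TraitParams(mean=0.0, var_prov=1.0, var_block=0.5,
                               var_prov_block=0.5, var_resid=v)
             for r, v in resids.items()}, single_site=True)}
        design = rf.TrialDesign(regions, n_blocks=6, n_trees=5, traits=traits)
        for seed in range(3):
            table = rf.simulate_trial(design, seed=seed)
            summary, _ = rf.region_trait_table(table)
            ordered = summary.set_index("region").loc[list(resids)]
            assert ordered["y"].is_monotonic_increasing

    def test_single_combination_matches_direct_fit(self):
        design = rf.default_trial_design().subset_region("Minnesota")
        table = rf.simulate_trial(design, seed=5)
        summary, fits = rf.region_trait_table(
            table, regions=["Minnesota"], traits=["height"]
        )
        direct = rf.fit_variance_model(table, "height")
        assert summary.iloc[0]["height"] == pytest.approx(
            direct.residual_variance
        )
        assert len(fits) == 1


class TestProvenanceSummaries:
    def test_balanced_means_and_shape(self):
        table = rf.simulate_trial(rf.default_trial_design(), seed=6)
        matrix = rf.provenance_summaries(table)
        assert matrix.shape == (43, 7)  # height at 5 sites + 2 phenology
        # balanced design: provenance mean is the simple mean
        h3 = table[(table["trait"] == "height") & (table["site"] == 3)]
        direct = h3.groupby("provenance")["value"].mean()
        pd.testing.assert_series_equal(
            matrix["height@3"], direct, check_names=False
        )

    def test_known_effects_recovered(self):
        p = 30
        effects = np.linspace(-2, 2, p)
        design = rf.TrialDesign(
            ("A",) * p, n_sites=1, n_blocks=8, n_trees=8,
            traits={"y": rf.TraitSpec({"A": rf.TraitParams(
                mean=0.0, var_resid=0.5)}, single_site=True)},
        )
        table = rf.simulate_trial(design, seed=7)
        table["value"] += effects[table["provenance"].to_numpy() - 1]
        matrix = rf.provenance_summaries(table)
        se = np.sqrt(0.5 / 64)
        assert np.abs(matrix["y"].to_numpy() - effects).max() < 4 * se


class TestPCA:
    def test_perfect_correlation_single_component(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        matrix = pd.DataFrame({"a": x, "b": 2 * x + 5})
        result = rf.pca(matrix)
        assert result.explained_fraction[0] == pytest.approx(1.0)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        matrix = pd.DataFrame(rng.normal(size=(40, 6)))
        L = rf.pca(matrix).loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_eigenvalue_oracle_small_matrix(self):
        rng = np.random.default_rng(2)
        matrix = pd.DataFrame(rng.normal(size=(5, 3)), columns=list("abc"))
        result = rf.pca(matrix, standardize=True)
        corr = np.corrcoef(matrix.to_numpy(), rowvar=False)
        eig = np.sort(np.linalg.eigh(corr)[0])[::-1]
        np.testing.assert_allclose(result.explained_variance, eig[:len(
            result.explained_variance)], atol=1e-10)

    def test_total_variance_conserved(self):
        rng = np.random.default_rng(3)
        matrix = pd.DataFrame(rng.normal(size=(50, 5)))
        result = rf.pca(matrix)
        assert result.explained_variance.sum() == pytest.approx(5.0)
        assert result.explained_fraction.sum() == pytest.approx(1.0)

    def test_zero_variance_column_named_in_error(self):
        matrix = pd.DataFrame({"ok": [1.0, 2, 3], "flat": [4.0, 4, 4]})
        with pytest.raises(ValueError, match="flat"):
            rf.pca(matrix)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(4)
        matrix = pd.DataFrame(rng.normal(size=(20, 4)))
        a = rf.pca(matrix).loadings
        b = rf.pca(matrix).loadings
        pd.testing.assert_frame_equal(a, b)
        for col in a.columns:
            assert a[col].to_numpy()[np.abs(a[col]).argmax()] > 0
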