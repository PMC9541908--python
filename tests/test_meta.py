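"""Multilevel REML meta-analysis: closed-form reductions, oracle checks,
heterogeneity partition, moderator machinery."""

import json
import shutil
import subprocess
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from artmeta.meta import (
    MetaDataset,
    MultilevelMetaRegression,
    build_covariance,
    fit_reml,
    i2_partition,
    level_means,
    meta_regression,
    sensitivity_suite,
    sneaker_frequency_models,
)
from artmeta.simulate import SimulationConfig, simulate_effects, simulate_tree

# --------------------------------------------------------------------------
# independent REML oracle (direct inverse / slogdet; no package internals)


def reml_loglik_oracle(y, X, sigma):
    k, p = X.shape
    sign, ld_s = np.linalg.slogdet(sigma)
    assert sign > 0
    si = np.linalg.inv(sigma)
    xtsx = X.T @ si @ X
    sign, ld_x = np.linalg.slogdet(xtsx)
    assert sign > 0
    beta = np.linalg.solve(xtsx, X.T @ si @ y)
    r = y - X @ beta
    return -0.5 * ((k - p) * np.log(2 * np.pi) + ld_s + ld_x + r @ si @ r)


def assemble_sigma_oracle(df, A_labels, A, sigma2, rho):
    """Loop-based covariance assembly straight from the model definition."""
    k = len(df)
    sp = df["species"].to_numpy()
    st = df["study_id"].to_numpy()
    ex = df["experiment_id"].to_numpy()
    v = df["var"].to_numpy(float)
    out = np.zeros((k, k))
    idx = {lab: i for i, lab in enumerate(A_labels)}
    for i in range(k):
        for j in range(k):
            out[i, j] += sigma2["phylogeny"] * A[idx[sp[i]], idx[sp[j]]]
            out[i, j] += sigma2["species"] * (sp[i] == sp[j])
            out[i, j] += sigma2["study"] * (st[i] == st[j])
            if i == j:
                out[i, j] += sigma2["observation"] + v[i]
            elif ex[i] == ex[j]:
                out[i, j] += rho * np.sqrt(v[i] * v[j])
    return out


def small_dataset_for_oracle(seed, k=12, n_species=5):
    cfg = SimulationConfig(seed=seed, n_species=n_species, n_effects=k)
    tree = simulate_tree(n_species, seed)
    return simulate_effects(cfg, tree)


class TestClosedFormReductions:
    def test_all_zero_components_give_weighted_mean(self):
        for seed in range(5):
            ds = small_dataset_for_oracle(seed, k=15, n_species=6)
            zeros = {"phylogeny": 0.0, "species": 0.0, "study": 0.0, "observation": 0.0}
            est = MultilevelMetaRegression(
                phylo_corr=ds.phylo_corr(), rho=0.0, fixed_sigma2=zeros
            ).fit(ds.effects, ds.effects["d"])
            y = ds.effects["d"].to_numpy()
            w = 1.0 / ds.effects["var"].to_numpy()
            assert est.beta_["intercept"] == pytest.approx((w * y).sum() / w.sum(), abs=1e-10)

    def test_two_equal_effects_pool_to_their_value(self, small_tree):
        df = pd.DataFrame(
            {
                "d": [0.5, 0.5],
                "var": [0.1, 0.1],
                "species": ["sp001", "sp002"],
                "study_id": ["s1", "s2"],
                "experiment_id": ["e1", "e2"],
            }
        )
        zeros = {"species": 0.0, "study": 0.0, "observation": 0.0}
        est = MultilevelMetaRegression(rho=0.0, fixed_sigma2=zeros).fit(df, df["d"])
        assert est.beta_["intercept"] == pytest.approx(0.5, abs=1e-12)


class TestRemlOracle:
    def test_optimum_beats_grid_search(self):
        """REML optimizer vs a brute-force grid over the variance components."""
        grid = np.arange(0.0, 0.51, 0.05)
        for seed in (2, 9, 23):
            ds = small_dataset_for_oracle(seed)
            A = ds.phylo_corr()
            est = fit_reml(ds)
            X = np.ones((ds.k, 1))
            y = ds.effects["d"].to_numpy()
            best = -np.inf
            for s_p in grid:
                for s_s in grid:
                    for s_t in grid:
                        for s_o in grid:
                            sig = assemble_sigma_oracle(
                                ds.effects,
                                A.labels,
                                A.matrix,
                                {
                                    "phylogeny": s_p,
                                    "species": s_s,
                                    "study": s_t,
                                    "observation": s_o,
                                },
                                ds.rho,
                            )
                            best = max(best, reml_loglik_oracle(y, X, sig))
            assert est.loglik_reml_ >= best - 1e-4

    def test_loglik_matches_oracle_at_fitted_components(self):
        ds = small_dataset_for_oracle(31, k=12)
        est = fit_reml(ds)
        A = ds.phylo_corr()
        sig = assemble_sigma_oracle(ds.effects, A.labels, A.matrix, est.sigma2_, ds.rho)
        ll = reml_loglik_oracle(ds.effects["d"].to_numpy(), np.ones((ds.k, 1)), sig)
        assert est.loglik_reml_ == pytest.approx(ll, abs=1e-6)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_reml_matches_metafor(tmp_path, small_dataset):
    """Independent cross-check against the reference multilevel meta-analysis
    implementation (metafor's rma.mv) on the same data and covariance."""
    ds = small_dataset
    ds.effects.to_csv(tmp_path / "eff.csv", index=False)
    A = ds.phylo_corr()
    pd.DataFrame(A.matrix, index=A.labels, columns=A.labels).to_csv(tmp_path / "A.csv")
    script = tmp_path / "check.R"
    script.write_text(
        """
suppressMessages({library(metafor); library(jsonlite)})
args <- commandArgs(trailingOnly=TRUE)
d <- read.csv(args[1])
A <- as.matrix(read.csv(args[2], row.names=1)); colnames(A) <- rownames(A)
d$phylo <- d$species
V <- diag(d$var)
for (i in 1:nrow(d)) for (j in 1:nrow(d))
  if (i != j && d$experiment_id[i] == d$experiment_id[j]) V[i,j] <- 0.5*sqrt(d$var[i]*d$var[j])
m <- rma.mv(d, V=V, random=list(~1|phylo, ~1|species, ~1|study_id, ~1|observation_id),
            R=list(phylo=A), data=d, method='REML')
cat(toJSON(list(beta=as.numeric(coef(m)), se=m$se, sigma2=m$sigma2), digits=10))
""",
    )
    res = subprocess.run(
        ["Rscript", str(script), str(tmp_path / "eff.csv"), str(tmp_path / "A.csv")],
        capture_output=True,
        text=True,
        timeout=300,
    )
    assert res.returncode == 0, res.stderr
    ref = json.loads(res.stdout)
    est = fit_reml(ds)
    assert est.beta_["intercept"] == pytest.approx(ref["beta"][0], abs=2e-4)
    assert est.se_["intercept"] == pytest.approx(ref["se"][0], rel=2e-3)
    for mine, theirs in zip(
        [est.sigma2_[key] for key in ("phylogeny", "species", "study", "observation")],
        ref["sigma2"],
    ):
        assert mine == pytest.approx(theirs, abs=2e-3)


class TestCovarianceAssembly:
    def test_diagonal_when_independent(self, small_dataset):
        df = small_dataset.effects.head(6).copy()
        df["experiment_id"] = [f"u{i}" for i in range(6)]
        comps, V = build_covariance(df, None, rho=0.5)
        np.testing.assert_allclose(V, np.diag(df["var"]))

    def test_shared_experiment_off_diagonal(self):
        df = pd.DataFrame(
            {
                "var": [0.2, 0.2],
                "species": ["a", "b"],
                "study_id": ["s", "s"],
                "experiment_id": ["e", "e"],
            }
        )
        _, V = build_covariance(df, None, rho=0.5)
        assert V[0, 1] == pytest.approx(0.1)

    def test_sigma_psd_for_random_configs(self, small_dataset, rng):
        comps, V = build_covariance(
            small_dataset.effects, small_dataset.phylo_corr(), rho=0.5
        )
        for _ in range(5):
            s2 = rng.uniform(0, 0.5, size=len(comps))
            sigma = V + sum(s * C for s, C in zip(s2, comps.values()))
            assert np.linalg.eigvalsh(sigma).min() > 0


class TestI2:
    def test_zero_components_zero_i2(self):
        total, part = i2_partition({"species": 0.0, "study": 0.0}, np.full(10, 0.3))
        assert total == 0.0

    def test_equal_weights_single_component_fifty_percent(self):
        v = np.full(20, 0.25)
        total, part = i2_partition({"species": 0.25}, v)
        assert total == pytest.approx(50.0)
        assert part["species"] == pytest.approx(50.0)

    def test_partition_sums_to_total(self, small_dataset):
        est = fit_reml(small_dataset)
        assert sum(est.i2_partition_.values()) == pytest.approx(est.i2_total_, abs=1e-9)
        assert all(val >= 0 for val in est.i2_partition_.values())


class TestModeratorRegression:
    def test_null_two_level_moderator_small_qm(self, small_dataset, rng):
        eff = small_dataset.effects.copy()
        eff["grp"] = rng.choice(["a", "b"], size=len(eff))
        ds = replace(small_dataset, effects=eff)
        est = meta_regression(ds, "grp", min_category_size=1)
        assert est.qm_df_ == 1
        assert est.r2_marginal_ < 0.25

    def test_injected_level_shift_detected_and_permutation_destroys_it(self, small_dataset, rng):
        eff = small_dataset.effects.copy()
        grp = rng.choice(["a", "b"], size=len(eff))
        eff["grp"] = grp
        eff["d"] = eff["d"] + np.where(grp == "b", 2.0, 0.0)
        ds = replace(small_dataset, effects=eff)
        est = meta_regression(ds, "grp", min_category_size=1)
        assert est.qm_p_ < 0.001
        assert est.r2_marginal_ > 0.3
        hits = 0
        for p in range(12):
            perm = eff.copy()
            perm["grp"] = rng.permutation(perm["grp"].to_numpy())
            perm_est = meta_regression(replace(ds, effects=perm), "grp", min_category_size=1)
            hits += perm_est.qm_p_ < 0.05
        assert hits <= 3

    def test_continuous_slope_recovery(self):
        cfg = SimulationConfig(
            seed=77, n_effects=250, moderator_effects={"sneaker_freq": 1.5}
        )
        tree = simulate_tree(cfg.n_species, 77)
        ds = simulate_effects(cfg, tree)
        est = meta_regression(ds, "sneaker_freq")
        assert est.ci_low_["sneaker_freq"] < 1.5 < est.ci_high_["sneaker_freq"]
        assert est.beta_["sneaker_freq"] == pytest.approx(1.5, abs=1.0)

    def test_small_categories_excluded(self, small_dataset, rng):
        eff = small_dataset.effects.copy()
        grp = np.array(["common"] * len(eff))
        grp[:3] = "rare"
        eff["grp"] = grp
        ds = replace(small_dataset, effects=eff)
        with pytest.raises(ValueError, match="single usable level"):
            meta_regression(ds, "grp", min_category_size=5)

    def test_level_means_match_no_intercept_fit(self, small_dataset, rng):
        eff = small_dataset.effects.copy()
        eff["grp"] = rng.choice(["a", "b"], size=len(eff))
        ds = replace(small_dataset, effects=eff)
        lm = level_means(ds, "grp", min_category_size=1)
        assert set(lm["level"]) == {"a", "b"}
        assert (lm["k"] >= 1).all()
        est = MultilevelMetaRegression(
            moderators=["grp"], drop_intercept=True, phylo_corr=ds.phylo_corr(), rho=ds.rho
        ).fit(ds.effects.assign(grp=eff["grp"]), ds.effects["d"])
        for _, row in lm.iterrows():
            assert row["mean_d"] == pytest.approx(est.beta_[f"grp[{row['level']}]"], abs=1e-8)


class TestSneakerFrequency:
    def test_concave_effect_detected(self):
        rows = []
        rng = np.random.default_rng(5)
        cfg = SimulationConfig(seed=5, n_effects=200)
        tree = simulate_tree(cfg.n_species, 5)
        ds = simulate_effects(cfg, tree)
        eff = ds.effects.copy()
        f = rng.uniform(0, 1, size=len(eff))  # spread over the full range
        eff["sneaker_freq"] = f
        eff["d"] = eff["d"] + 4 * f * (1 - f)  # hump-shaped
        out = sneaker_frequency_models(replace(ds, effects=eff))
        assert out["quadratic"].beta_["sneaker_freq_sq"] < 0
        assert out["quadratic_p"] < 0.05

    def test_flat_effect_null(self, small_dataset):
        out = sneaker_frequency_models(small_dataset)
        assert out["linear"].ci_low_["sneaker_freq"] < 0 < out["linear"].ci_high_["sneaker_freq"]

    def test_needs_three_distinct_frequencies(self, small_dataset):
        eff = small_dataset.effects.copy()
        eff["sneaker_freq"] = 0.3
        with pytest.raises(ValueError, match="distinct"):
            sneaker_frequency_models(replace(small_dataset, effects=eff))


class TestSensitivity:
    def test_no_directionless_variant_is_base(self, small_dataset):
        out = sensitivity_suite(small_dataset)
        base = out.loc[out["variant"] == "base"].iloc[0]
        nod = out.loc[out["variant"] == "no_directionless"].iloc[0]
        assert nod["mean_d"] == base["mean_d"]
        assert nod["k"] == base["k"]

    def test_rho_variants_identical_without_shared_experiments(self, small_dataset):
        eff = small_dataset.effects.copy()
        eff["experiment_id"] = [f"solo{i}" for i in range(len(eff))]
        out = sensitivity_suite(replace(small_dataset, effects=eff))
        rho_rows = out[out["variant"].str.startswith("rho=")]
        assert rho_rows["mean_d"].nunique() == 1

    def test_ci_width_grows_with_rho_under_shared_experiments(self):
        cfg = SimulationConfig(seed=13, n_effects=120, rho_true=0.6, max_experiment_size=4,
                               effects_per_study=(3, 5))
        tree = simulate_tree(cfg.n_species, 13)
        ds = simulate_effects(cfg, tree)
        out = sensitivity_suite(ds)
        widths = {
            row["variant"]: row["ci_high"] - row["ci_low"]
            for _, row in out.iterrows()
            if row["variant"].startswith("rho=")
        }
        assert widths["rho=0.75"] >= widths["rho=0.25"] - 1e-3

    def test_species_exclusion_variant(self, small_dataset):
        out = sensitivity_suite(small_dataset, exclude_species=[small_dataset.species_list[0]])
        row = out.loc[out["variant"] == "species_excluded"].iloc[0]
        assert row["k"] < small_dataset.k


class TestEstimatorApi:
    def test_get_params_clone_and_predict(self, small_dataset):
        est = MultilevelMetaRegression(rho=0.25, phylo_corr=small_dataset.phylo_corr())
        params = est.get_params()
        assert params["rho"] == 0.25
        cloned = clone(est)
        assert cloned.get_params()["rho"] == 0.25
        cloned.fit(small_dataset.effects, small_dataset.effects["d"])
        pred = cloned.predict(small_dataset.effects)
        np.testing.assert_allclose(pred, cloned.beta_["intercept"])

    def test_validation_errors(self, small_dataset):
        est = MultilevelMetaRegression()
        with pytest.raises(ValueError, match="var"):
            est.fit(pd.DataFrame({"species": ["a", "b"], "study_id": ["s", "t"]}), [0.1, 0.2])
        df = small_dataset.effects.head(3)
        with pytest.raises(ValueError, match="cannot support|rank deficient"):
            MultilevelMetaRegression(
                moderators=["taxon_group", "pub_year", "sneaker_freq"], drop_intercept=False
            ).fit(df, df["d"])

    def test_dataset_validation(self, small_tree):
        with pytest.raises(ValueError, match="missing from tree"):
            MetaDataset(
                pd.DataFrame(
                    {
                        "d": [0.1, 0.2],
                        "var": [0.1, 0.1],
                        "species": ["nope", "sp001"],
                        "study_id": ["s", "t"],
                    }
                ),
                tree=small_tree,
            )
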