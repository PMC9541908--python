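"""Phylogenetic multilevel random-effects meta-analysis.

The marginal model for k effect sizes y with known sampling variances v is

    y ~ N(X beta, Sigma(theta)),
    Sigma = s2_phylo Z_A A Z_A' + s2_species Z_s Z_s' + s2_study Z_t Z_t'
            + s2_obs I [+ s2_exper Z_e Z_e'] + V,

where A is the species correlation matrix from the tree, the Z's map effects
to species / study / experiment levels, and V carries the sampling
(co)variances: diagonal v_i, off-diagonal rho*sqrt(v_i v_j) for effects from
the same experiment (the same sample of males).  Variance components are
estimated by REML on the log scale (Nelder-Mead, then a quasi-Newton polish);
beta is the GLS estimate at the optimum with normal Wald intervals.

Reported alongside the coefficients: the Q_M omnibus Wald test on the
moderator coefficients, total I-squared and its partition across the random
factors, and marginal R-squared (variance of the fixed-effect predictions
over total variance).

:class:`MultilevelMetaRegression` is a scikit-learn style estimator
(``fit(X, y)``, ``get_params``, trailing-underscore attributes); the
module-level functions (:func:`fit_reml`, :func:`meta_regression`, ...) are
thin wrappers that drive it from a :class:`MetaDataset`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator

from .effects import EffectSize
from .phylo import PhyloCovariance, grafen_transform, prune, unit_branch_lengths, vcv_from_tree

__all__ = [
    "MetaDataset",
    "MultilevelMetaRegression",
    "build_covariance",
    "fit_reml",
    "i2_partition",
    "meta_regression",
    "level_means",
    "sneaker_frequency_models",
    "sensitivity_suite",
]

EFFECT_COLUMNS = [
    "observation_id",
    "study_id",
    "experiment_id",
    "species",
    "trait_category",
    "measurement",
    "d",
    "var",
    "directionless",
    "taxon_group",
    "fert_mode",
    "tactic_type",
    "sneaker_freq",
    "pub_year",
]

_STRUCT_COLS = ("var", "species", "study_id")


# ---------------------------------------------------------------------------
# dataset container


@dataclass
class MetaDataset:
    """Effect-size table + tree + within-experiment correlation, bound for fitting."""

    effects: pd.DataFrame
    tree: object | None = None
    rho: float = 0.5
    grafen_rho: float = 1.0

    def __post_init__(self) -> None:
        df = self.effects.reset_index(drop=True)
        missing = {"d", "var", "species", "study_id"} - set(df.columns)
        if missing:
            raise ValueError(f"effects table missing columns: {sorted(missing)}")
        if len(df) < 2:
            raise ValueError("need at least two effect sizes")
        if (df["var"] <= 0).any():
            raise ValueError("all sampling variances must be positive")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.tree is not None:
            tips = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
            absent = set(df["species"]) - tips
            if absent:
                raise ValueError(f"species missing from tree: {sorted(absent)}")
        self.effects = df

    @classmethod
    def from_effect_sizes(cls, effects: list[EffectSize], tree=None, rho: float = 0.5):
        rows = []
        for e in effects:
            rows.append(
                {
                    "observation_id": e.observation_id,
                    "study_id": e.study_id,
                    "experiment_id": e.experiment_id,
                    "species": e.species,
                    "trait_category": e.trait_category,
                    "measurement": e.measurement,
                    "d": e.d,
                    "var": e.var,
                    "directionless": e.directionless,
                    **e.moderators,
                }
            )
        return cls(pd.DataFrame(rows), tree=tree, rho=rho)

    @property
    def k(self) -> int:
        return len(self.effects)

    @property
    def species_list(self) -> list[str]:
        return sorted(self.effects["species"].unique())

    def phylo_corr(self) -> PhyloCovariance | None:
        """Species correlation matrix: prune -> unit branch lengths -> Grafen -> VCV."""
        if self.tree is None:
            return None
        sub = prune(self.tree, set(self.species_list))
        if len(self.species_list) == 1:
            return PhyloCovariance(self.species_list, np.eye(1))
        sub = grafen_transform(unit_branch_lengths(sub), rho=self.grafen_rho)
        return vcv_from_tree(sub)

    def subset(self, mask) -> "MetaDataset":
        sub = self.effects.loc[mask].reset_index(drop=True)
        return replace(self, effects=sub)


# ---------------------------------------------------------------------------
# covariance assembly


def build_covariance(
    X: pd.DataFrame,
    phylo_corr: PhyloCovariance | None,
    rho: float,
    include_experiment: bool = False,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Component matrices C_m (unit variance each) and the sampling matrix V.

    Sigma(theta) = sum_m sigma2_m * C_m + V.  V has v_i on the diagonal and
    rho*sqrt(v_i v_j) between effects sharing a (non-empty) experiment_id.
    """
    k = len(X)
    sp = X["species"].to_numpy()
    comps: dict[str, np.ndarray] = {}
    if phylo_corr is not None:
        idx = np.array([phylo_corr.labels.index(s) for s in sp])
        comps["phylogeny"] = phylo_corr.matrix[np.ix_(idx, idx)]
    comps["species"] = (sp[:, None] == sp[None, :]).astype(float)
    st = X["study_id"].to_numpy()
    comps["study"] = (st[:, None] == st[None, :]).astype(float)
    comps["observation"] = np.eye(k)

    v = X["var"].to_numpy(dtype=float)
    V = np.diag(v)
    if "experiment_id" in X.columns:
        ex = X["experiment_id"].fillna("").astype(str).to_numpy()
        valid = ex != ""
        same = (ex[:, None] == ex[None, :]) & valid[:, None] & valid[None, :]
        np.fill_diagonal(same, False)
        if rho != 0.0 and same.any():
            sqv = np.sqrt(v)
            V = V + np.where(same, rho * np.outer(sqv, sqv), 0.0)
        if include_experiment:
            comps["experiment"] = np.where(
                (ex[:, None] == ex[None, :]) & valid[:, None] & valid[None, :], 1.0, 0.0
            )
            np.fill_diagonal(comps["experiment"], 1.0)
    return comps, V


def i2_partition(sigma2: dict[str, float], v: np.ndarray) -> tuple[float, dict[str, float]]:
    """Heterogeneity partition: I2_level = 100 * s2_level / (sum s2 + s2_typ),
    with the typical sampling variance s2_typ = ((k-1) sum w) / ((sum w)^2 -
    sum w^2), w = 1/v."""
    v = np.asarray(v, dtype=float)
    k = len(v)
    if k < 2:
        raise ValueError("need at least two effects for I2")
    w = 1.0 / v
    s2_typ = (k - 1) * w.sum() / (w.sum() ** 2 - (w**2).sum())
    total_het = sum(sigma2.values())
    denom = total_het + s2_typ
    partition = {name: float(100.0 * s2 / denom) for name, s2 in sigma2.items()}
    return float(100.0 * total_het / denom), partition


# ---------------------------------------------------------------------------
# REML core


def _reml_nll_factory(y, X, stack, V):
    """Restricted negative log-likelihood as a function of the variance
    components sigma2 (natural scale)."""
    k, p = X.shape
    const = (k - p) * np.log(2.0 * np.pi)

    def nll(s2: np.ndarray) -> float:
        sigma = V + np.tensordot(s2, stack, axes=1) if len(s2) else V
        try:
            c, low = cho_factor(sigma, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return 1e10
        logdet_sigma = 2.0 * np.log(np.diag(c)).sum()
        six = cho_solve((c, low), X, check_finite=False)
        siy = cho_solve((c, low), y, check_finite=False)
        xtsx = X.T @ six
        sign, logdet_x = np.linalg.slogdet(xtsx)
        if sign <= 0:
            return 1e10
        xtsy = X.T @ siy
        beta = np.linalg.solve(xtsx, xtsy)
        quad = float(y @ siy - beta @ xtsy)
        return 0.5 * (logdet_sigma + logdet_x + quad + const)

    return nll


def _gls_at(y, X, sigma):
    c, low = cho_factor(sigma, lower=True, check_finite=False)
    six = cho_solve((c, low), X, check_finite=False)
    xtsx = X.T @ six
    cov_beta = np.linalg.inv(xtsx)
    beta = cov_beta @ (X.T @ cho_solve((c, low), y, check_finite=False))
    return beta, cov_beta


class MultilevelMetaRegression(BaseEstimator):
    """Multilevel random-effects meta-regression with phylogenetic correlation.

    Parameters
    ----------
    moderators : list of str, optional
        Columns of X entering the fixed-effect design.  Numeric columns enter
        as-is; object/categorical columns are dummy-coded (first level as
        reference when an intercept is present).
    phylo_corr : PhyloCovariance, optional
        Species correlation matrix; adds a phylogenetic random effect over the
        species index.  Without it the model has species/study/observation
        components only.
    rho : float, default 0.5
        Assumed correlation between sampling errors of effects from the same
        experiment (same sample of males).
    include_experiment_re : bool, default False
        Add an experiment-level random intercept on top of the rho-correlated
        sampling matrix.
    drop_intercept : bool, default False
        Fit without intercept (per-level means for a categorical moderator).
    fixed_sigma2 : dict, optional
        Variance components to hold fixed (e.g. all zero for the GLS/common-
        effect reduction) instead of estimating them.
    n_restarts : int, default 1
        Extra Nelder-Mead starts beyond the moment-based one; the best optimum
        is kept and polished with L-BFGS-B.
    ci_level : float, default 0.95
        Coverage of the normal Wald intervals on beta.

    Attributes (after ``fit``)
    --------------------------
    beta_, se_, ci_low_, ci_high_ : pd.Series indexed by coefficient name
    sigma2_ : dict of REML variance components
    loglik_reml_ : restricted log-likelihood at the optimum
    qm_, qm_df_, qm_p_ : omnibus moderator Wald test (intercept excluded)
    i2_total_, i2_partition_ : heterogeneity percentages
    r2_marginal_ : proportion of variance explained by the moderators
    """

    def __init__(
        self,
        moderators=None,
        phylo_corr=None,
        rho=0.5,
        include_experiment_re=False,
        drop_intercept=False,
        fixed_sigma2=None,
        n_restarts=1,
        maxiter=2000,
        ci_level=0.95,
        use_t=False,
    ):
        self.moderators = moderators
        self.phylo_corr = phylo_corr
        self.rho = rho
        self.include_experiment_re = include_experiment_re
        self.drop_intercept = drop_intercept
        self.fixed_sigma2 = fixed_sigma2
        self.n_restarts = n_restarts
        self.maxiter = maxiter
        self.ci_level = ci_level
        self.use_t = use_t

    # -- design ------------------------------------------------------------

    def _build_design(self, X: pd.DataFrame, levels_map=None):
        cols, names = [], []
        fit_mode = levels_map is None
        levels_map = {} if fit_mode else levels_map
        if not self.drop_intercept:
            cols.append(np.ones(len(X)))
            names.append("intercept")
        for m in self.moderators or []:
            s = X[m]
            if pd.api.types.is_numeric_dtype(s):
                if s.isna().any():
                    raise ValueError(f"moderator {m!r} has missing values")
                cols.append(s.to_numpy(dtype=float))
                names.append(m)
            else:
                if fit_mode:
                    levels_map[m] = sorted(s.astype(str).unique())
                levels = levels_map[m]
                use = levels[1:] if not self.drop_intercept else levels
                arr = s.astype(str).to_numpy()
                for lev in use:
                    cols.append((arr == lev).astype(float))
                    names.append(f"{m}[{lev}]")
        if not cols:
            raise ValueError("empty fixed-effect design (no intercept, no moderators)")
        design = np.column_stack(cols)
        if fit_mode and np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("fixed-effect design is rank deficient")
        return design, names, levels_map

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        X = pd.DataFrame(X).reset_index(drop=True)
        y = np.asarray(y, dtype=float)
        for col in _STRUCT_COLS:
            if col not in X.columns:
                raise ValueError(f"X must carry a {col!r} column")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        comps, V = build_covariance(X, self.phylo_corr, self.rho, self.include_experiment_re)
        design, names, levels_map = self._build_design(X)
        k, p = design.shape
        if k <= p:
            raise ValueError(f"k={k} effects cannot support {p} fixed-effect columns")

        fixed = dict(self.fixed_sigma2 or {})
        unknown = set(fixed) - set(comps)
        if unknown:
            raise ValueError(f"fixed_sigma2 names unknown components: {sorted(unknown)}")
        free = [name for name in comps if name not in fixed]
        base = V + sum(fixed[name] * comps[name] for name in fixed)
        stack = np.stack([comps[name] for name in free]) if free else np.empty((0, k, k))
        nll = _reml_nll_factory(y, design, stack, base)

        if free:
            nll_log = lambda x: nll(np.exp(x))  # noqa: E731 - log-scale view
            tau0 = max(float(np.var(y) - X["var"].mean()), 1e-3)
            starts = [np.log(np.full(len(free), tau0 / len(free)))]
            rng = np.random.default_rng(0)
            for _ in range(max(0, self.n_restarts - 1)):
                starts.append(np.log(tau0) + rng.uniform(-3.0, 1.0, size=len(free)))
            best = None
            for s0 in starts:
                res = optimize.minimize(
                    nll_log,
                    s0,
                    method="Nelder-Mead",
                    options={"maxiter": self.maxiter, "xatol": 1e-6, "fatol": 1e-10},
                )
                if best is None or res.fun < best.fun:
                    best = res
            # Polish on the natural scale: boundary components reach exactly 0
            # and flat log-scale directions regain curvature.
            theta, fun = np.exp(best.x), best.fun
            polish = optimize.minimize(
                nll, theta, method="L-BFGS-B", bounds=[(0.0, None)] * len(free)
            )
            if np.isfinite(polish.fun) and polish.fun <= fun:
                theta, fun = polish.x, polish.fun
            if not np.isfinite(fun) or fun >= 1e10:
                raise RuntimeError("REML optimization failed to find a finite optimum")
            self.converged_ = True
            self.loglik_reml_ = -float(fun)
        else:
            theta = np.array([])
            self.converged_ = True
            self.loglik_reml_ = -float(nll(theta))

        sigma2 = dict(fixed)
        sigma2.update({name: float(t) for name, t in zip(free, theta)})
        # order components canonically
        self.sigma2_ = {name: max(sigma2[name], 0.0) for name in comps}

        sigma = base + np.tensordot(theta, stack, axes=1) if free else base
        beta, cov_beta = _gls_at(y, design, sigma)
        se = np.sqrt(np.diag(cov_beta))
        # Default: normal Wald intervals and a chi-square Q_M (the standard
        # toolchain default).  use_t switches to t/F references with k - p
        # degrees of freedom, which restores near-nominal moderator-test
        # calibration at small k.
        if self.use_t:
            z = stats.t.ppf(0.5 + self.ci_level / 2.0, k - p)
        else:
            z = stats.norm.ppf(0.5 + self.ci_level / 2.0)
        self.beta_ = pd.Series(beta, index=names)
        self.se_ = pd.Series(se, index=names)
        self.ci_low_ = self.beta_ - z * self.se_
        self.ci_high_ = self.beta_ + z * self.se_
        self.cov_beta_ = pd.DataFrame(cov_beta, index=names, columns=names)
        self.k_ = k
        self.X_names_ = names
        self._levels_map = levels_map

        tested = [i for i, name in enumerate(names) if name != "intercept"]
        if tested:
            bm = beta[tested]
            cm = cov_beta[np.ix_(tested, tested)]
            qm = float(bm @ np.linalg.solve(cm, bm))
            self.qm_, self.qm_df_ = qm, len(tested)
            if self.use_t:
                self.qm_p_ = float(stats.f.sf(qm / len(tested), len(tested), k - p))
            else:
                self.qm_p_ = float(stats.chi2.sf(qm, len(tested)))
        else:
            self.qm_, self.qm_df_, self.qm_p_ = np.nan, 0, np.nan

        self.i2_total_, self.i2_partition_ = i2_partition(
            self.sigma2_, X["var"].to_numpy(dtype=float)
        )
        fitted = design @ beta
        var_fixed = float(np.var(fitted)) if tested else 0.0
        total = var_fixed + sum(self.sigma2_.values())
        self.r2_marginal_ = var_fixed / total if total > 0 else 0.0
        return self

    def predict(self, X):
        design, _, _ = self._build_design(pd.DataFrame(X), levels_map=self._levels_map)
        return design @ self.beta_.to_numpy()

    # -- reporting ---------------------------------------------------------

    def significant_(self, name: str = None) -> bool:
        """CI-excludes-zero rule for one coefficient (default: the first)."""
        name = name or self.X_names_[0]
        return bool(self.ci_low_[name] > 0 or self.ci_high_[name] < 0)

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "beta": self.beta_,
                "se": self.se_,
                "ci_low": self.ci_low_,
                "ci_high": self.ci_high_,
            }
        )
        out.attrs.update(
            k=self.k_,
            QM=self.qm_,
            QM_df=self.qm_df_,
            QM_p=self.qm_p_,
            I2_total=self.i2_total_,
            R2_marginal=self.r2_marginal_,
        )
        return out


# ---------------------------------------------------------------------------
# dataset-level wrappers


def _estimator_for(dataset: MetaDataset, **kwargs) -> MultilevelMetaRegression:
    kwargs.setdefault("phylo_corr", dataset.phylo_corr())
    kwargs.setdefault("rho", dataset.rho)
    return MultilevelMetaRegression(**kwargs)


def fit_reml(dataset: MetaDataset, moderators=None, **kwargs) -> MultilevelMetaRegression:
    """Fit the multilevel model on a dataset (intercept-only by default)."""
    est = _estimator_for(dataset, moderators=moderators, **kwargs)
    return est.fit(dataset.effects, dataset.effects["d"])


def _moderator_rows(dataset: MetaDataset, moderator: str, min_category_size: int):
    df = dataset.effects
    if moderator not in df.columns:
        raise ValueError(f"moderator {moderator!r} not in effects table")
    present = df[moderator].notna()
    if pd.api.types.is_object_dtype(df[moderator]) or isinstance(
        df[moderator].dtype, pd.CategoricalDtype
    ):
        present &= df[moderator].astype(str).str.len() > 0
        counts = df.loc[present, moderator].value_counts()
        keep_levels = counts[counts >= min_category_size].index
        present &= df[moderator].isin(keep_levels)
        if present.sum() and df.loc[present, moderator].nunique() < 2:
            raise ValueError(f"moderator {moderator!r} has a single usable level")
    sub = dataset.subset(present)
    return sub


def meta_regression(
    dataset: MetaDataset,
    moderator: str,
    min_category_size: int = 5,
    **kwargs,
) -> MultilevelMetaRegression:
    """One-moderator meta-regression (Q_M, marginal R2).

    Rows with a missing moderator are dropped; categorical levels with fewer
    than ``min_category_size`` effects are excluded before fitting.
    """
    sub = _moderator_rows(dataset, moderator, min_category_size)
    est = _estimator_for(sub, moderators=[moderator], **kwargs)
    return est.fit(sub.effects, sub.effects["d"])


def level_means(
    dataset: MetaDataset, moderator: str, min_category_size: int = 5, **kwargs
) -> pd.DataFrame:
    """Per-level mean effects: the same model refit without intercept."""
    sub = _moderator_rows(dataset, moderator, min_category_size)
    est = _estimator_for(sub, moderators=[moderator], drop_intercept=True, **kwargs)
    est.fit(sub.effects, sub.effects["d"])
    counts = sub.effects[moderator].astype(str).value_counts()
    rows = []
    for name in est.X_names_:
        level = name.split("[", 1)[1][:-1] if "[" in name else name
        rows.append(
            {
                "level": level,
                "k": int(counts.get(level, 0)),
                "mean_d": est.beta_[name],
                "ci_low": est.ci_low_[name],
                "ci_high": est.ci_high_[name],
            }
        )
    return pd.DataFrame(rows)


def sneaker_frequency_models(dataset: MetaDataset, **kwargs) -> dict:
    """Quadratic-then-linear sneaker-frequency meta-regressions.

    The quadratic model (freq + freq^2) is fitted first and the curvature
    term's z-test reported; the linear model is fitted alongside.  Frequencies
    enter as proportions in [0, 1].
    """
    df = dataset.effects
    present = df["sneaker_freq"].notna()
    sub = dataset.subset(present)
    freq = sub.effects["sneaker_freq"].astype(float)
    if freq.nunique() < 3:
        raise ValueError("need >= 3 distinct sneaker frequencies for the quadratic model")
    eff = sub.effects.copy()
    eff["sneaker_freq"] = freq
    eff["sneaker_freq_sq"] = freq**2
    sub_q = replace(sub, effects=eff)
    quad = _estimator_for(sub_q, moderators=["sneaker_freq", "sneaker_freq_sq"], **kwargs)
    quad.fit(sub_q.effects, sub_q.effects["d"])
    z_quad = quad.beta_["sneaker_freq_sq"] / quad.se_["sneaker_freq_sq"]
    linear = _estimator_for(sub_q, moderators=["sneaker_freq"], **kwargs)
    linear.fit(sub_q.effects, sub_q.effects["d"])
    return {
        "quadratic": quad,
        "linear": linear,
        "quadratic_z": float(z_quad),
        "quadratic_p": float(2.0 * stats.norm.sf(abs(z_quad))),
        "quadratic_significant": bool(quad.significant_("sneaker_freq_sq")),
    }


def sensitivity_suite(
    dataset: MetaDataset,
    rhos=(0.25, 0.5, 0.75),
    exclude_species: list[str] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Intercept-only refits under the standard robustness variants.

    Variants: the base fit; directionless zeros removed; each within-
    experiment correlation rho in ``rhos``; caller-specified species removed.
    Variants leaving fewer than two effects are skipped with a warning.
    """
    rows = []

    def _try(label, ds, **kw):
        try:
            if ds.k < 2:
                raise ValueError("fewer than two effects")
            est = fit_reml(ds, **{**kwargs, **kw})
            rows.append(
                {
                    "variant": label,
                    "k": est.k_,
                    "mean_d": est.beta_["intercept"],
                    "ci_low": est.ci_low_["intercept"],
                    "ci_high": est.ci_high_["intercept"],
                    "i2_total": est.i2_total_,
                }
            )
        except (ValueError, RuntimeError) as err:
            warnings.warn(f"sensitivity variant {label!r} skipped: {err}")

    _try("base", dataset)
    if "directionless" in dataset.effects.columns:
        mask = ~dataset.effects["directionless"].fillna(False).astype(bool)
        if mask.all():
            base = next(r for r in rows if r["variant"] == "base")
            rows.append({**base, "variant": "no_directionless"})
        else:
            _try("no_directionless", dataset.subset(mask))
    for rho in rhos:
        _try(f"rho={rho}", replace(dataset, rho=rho))
    if exclude_species:
        mask = ~dataset.effects["species"].isin(exclude_species)
        _try("species_excluded", dataset.subset(mask))
    return pd.DataFrame(rows)
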